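import numpy as np
import pytest

from trispectrakan.synthetic_data import SynthCorpusConfig, synth_corpus


@pytest.fixture(scope="session")
def tiny_corpus(tmp_path_factory):
    """Small synthetic corpus: 1 patient per class, short recordings."""
    root = tmp_path_factory.mktemp("tiny_corpus")
    cfg = SynthCorpusConfig(n_patients_per_class=1,
                            recording_duration_s=(10.0, 14.0), seed=7)
    index = synth_corpus(cfg, outdir=root)
    return root, index


@pytest.fixture(scope="session")
def six_second_segment():
    """A deterministic 6-s, 22,050 Hz test signal (tone + noise)."""
    rng = np.random.default_rng(42)
    t = np.arange(132300) / 22050.0
    return 0.3 * np.sin(2 * np.pi * 440.0 * t) + 0.05 * rng.standard_normal(len(t))
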