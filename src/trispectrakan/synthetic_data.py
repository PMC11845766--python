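"""Seeded synthetic lung-sound corpora in the ICBHI on-disk layout.

Each recording is a train of parametric breath cycles: band-limited
(100-1800 Hz) noise shaped by a raised-cosine inhale/exhale envelope and a
per-class spectral tilt, with optional adventitious sounds —

* crackles: short (<= 15 ms) damped-sinusoid transients, count drawn
  Poisson per cycle;
* wheezes: a sustained tone plus one harmonic inside a class-specific
  frequency band, present with a per-cycle probability.

Annotation flags record what was actually inserted, so parsed annotations
are exact ground truth.  Audio is synthesized at the stethoscope-native
4 kHz and later upsampled by the preprocessing pipeline.  The archetypes
are engineered test fixtures with clinically inspired contrasts (wheezy
obstructive classes, crackle-rich infectious classes, a clean healthy
class); they are not physiological airway models.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.signal import butter, sosfilt

from . import icbhi_io
from .icbhi_io import CycleAnnotation, DatasetIndex, LABELS

__all__ = [
    "ClassArchetype", "SynthCorpusConfig", "DEFAULT_ARCHETYPES",
    "gen_breath_cycle", "synth_recording", "synth_corpus",
]


@dataclass(frozen=True)
class ClassArchetype:
    """Generative parameters for one diagnosis class."""

    label: str
    cycle_duration_s: tuple[float, float]   # mean, sd
    crackle_rate: float                     # expected crackles per cycle
    wheeze_prob: float                      # probability per cycle
    wheeze_f0_hz: tuple[float, float]       # fundamental frequency band
    noise_tilt_db_per_oct: float            # spectral slope of breath noise
    amplitude: float = 0.08                 # rms target of the cycle

    def __post_init__(self) -> None:
        if not 0.0 <= self.wheeze_prob <= 1.0:
            raise ValueError("wheeze_prob must be in [0, 1]")
        if self.crackle_rate < 0:
            raise ValueError("crackle_rate must be >= 0")
        if self.wheeze_f0_hz[0] <= 0:
            raise ValueError("wheeze frequencies must be positive")


#: Default archetypes: distinct wheeze bands, crackle rates and spectral
#: tilts per class so the six classes are acoustically separable.
DEFAULT_ARCHETYPES: dict[str, ClassArchetype] = {
    "Bronchiectasis": ClassArchetype("Bronchiectasis", (3.0, 0.5), 5.0, 0.10,
                                     (150.0, 250.0), -4.0),
    "Bronchiolitis": ClassArchetype("Bronchiolitis", (2.2, 0.4), 1.5, 0.60,
                                    (550.0, 750.0), -3.0),
    "COPD": ClassArchetype("COPD", (4.5, 0.8), 0.3, 0.90,
                           (200.0, 350.0), -2.0),
    "Healthy": ClassArchetype("Healthy", (2.8, 0.4), 0.0, 0.0,
                              (400.0, 401.0), -5.0),
    "Pneumonia": ClassArchetype("Pneumonia", (3.2, 0.5), 3.5, 0.20,
                                (400.0, 500.0), -6.0),
    "URTI": ClassArchetype("URTI", (2.0, 0.3), 0.7, 0.35,
                           (350.0, 450.0), -1.0),
}


@dataclass(frozen=True)
class SynthCorpusConfig:
    """Corpus-level knobs; defaults give ~240 six-second segments."""

    n_patients_per_class: int = 2
    recordings_per_patient: int = 1
    recording_duration_s: tuple[float, float] = (60.0, 80.0)
    sample_rate: int = 4000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients_per_class < 1 or self.recordings_per_patient < 1:
            raise ValueError("counts must be positive")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")


def _envelope(n: int, rate: int, rng: np.random.Generator) -> np.ndarray:
    """Raised-cosine inhale attack and exhale decay over the cycle."""
    t = np.linspace(0.0, 1.0, n)
    split = rng.uniform(0.35, 0.5)  # inhale fraction
    env = np.empty(n)
    up = t <= split
    env[up] = 0.5 * (1.0 - np.cos(np.pi * t[up] / split))
    env[~up] = 0.5 * (1.0 + np.cos(np.pi * (t[~up] - split) / (1.0 - split)))
    return 0.15 + 0.85 * env


def _tilted_noise(n: int, rate: int, tilt_db_per_oct: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Band-limited (100-1800 Hz) white noise with a spectral tilt."""
    white = rng.standard_normal(n)
    sos = butter(4, [100.0, min(1800.0, 0.45 * rate)], btype="bandpass",
                 fs=rate, output="sos")
    band = sosfilt(sos, white)
    spec = np.fft.rfft(band)
    f = np.fft.rfftfreq(n, 1.0 / rate)
    gain = np.ones_like(f)
    nz = f > 0
    gain[nz] = (f[nz] / 300.0) ** (tilt_db_per_oct / 6.0206)
    return np.fft.irfft(spec * gain, n=n)


def _crackle(rate: int, rng: np.random.Generator) -> np.ndarray:
    """Damped sinusoid transient, <= 15 ms."""
    dur = rng.uniform(0.008, 0.015)
    n = max(8, int(dur * rate))
    t = np.arange(n) / rate
    f = rng.uniform(250.0, 650.0)
    tau = rng.uniform(0.002, 0.004)
    return np.exp(-t / tau) * np.sin(2 * np.pi * f * t)


def gen_breath_cycle(rng: np.random.Generator, archetype: ClassArchetype,
                     rate: int) -> tuple[np.ndarray, CycleAnnotation]:
    """One breath cycle; the annotation reflects the sounds actually added."""
    mean, sd = archetype.cycle_duration_s
    dur = float(np.clip(rng.normal(mean, sd), 1.0, 8.0))
    n = int(dur * rate)
    env = _envelope(n, rate, rng)
    x = _tilted_noise(n, rate, archetype.noise_tilt_db_per_oct, rng) * env

    n_crackles = int(rng.poisson(archetype.crackle_rate))
    for _ in range(n_crackles):
        burst = _crackle(rate, rng)
        pos = rng.integers(0, max(1, n - len(burst)))
        amp = rng.uniform(2.0, 4.0) * np.abs(x).mean()
        x[pos:pos + len(burst)] += amp * burst[:n - pos]

    has_wheeze = bool(rng.random() < archetype.wheeze_prob)
    if has_wheeze:
        f0 = rng.uniform(*archetype.wheeze_f0_hz)
        t = np.arange(n) / rate
        tone = np.sin(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))
        tone += 0.3 * np.sin(2 * np.pi * 2 * f0 * t)
        x += 1.5 * np.abs(x).std() * tone * env

    rms = np.sqrt(np.mean(x ** 2))
    if rms > 0:
        x *= archetype.amplitude / rms
    ann = CycleAnnotation(0.0, dur, crackle=n_crackles > 0, wheeze=has_wheeze)
    return x, ann


def synth_recording(rng: np.random.Generator, archetype: ClassArchetype,
                    duration_s: float, rate: int
                    ) -> tuple[np.ndarray, list[CycleAnnotation]]:
    """Tile breath cycles with short pauses until the duration is filled."""
    n_total = int(duration_s * rate)
    mean_cycle = archetype.cycle_duration_s[0]
    if duration_s < mean_cycle + 1.0:
        raise ValueError("recording too short for one breath cycle")
    out = np.zeros(n_total)
    anns: list[CycleAnnotation] = []
    pos = int(rng.uniform(0.1, 0.4) * rate)
    while True:
        cycle, ann = gen_breath_cycle(rng, archetype, rate)
        if pos + len(cycle) > n_total:
            break
        out[pos:pos + len(cycle)] = cycle
        start = pos / rate
        anns.append(replace(ann, start_s=start, end_s=start + ann.end_s))
        pos += len(cycle) + int(rng.uniform(0.2, 0.6) * rate)
    out += 0.002 * rng.standard_normal(n_total)  # sensor noise floor
    return np.clip(out, -1.0, 1.0), anns


_LOCATIONS = ("Al", "Ar", "Pl", "Pr", "Tc", "Ll")


def synth_corpus(cfg: SynthCorpusConfig,
                 archetypes: dict[str, ClassArchetype] | None = None,
                 outdir: Path | str = ".") -> DatasetIndex:
    """Write a full corpus (wav + txt + diagnosis table); return its index.

    Per-recording random substreams are derived from the seed by counter,
    so regeneration with the same config is byte-identical.
    """
    archetypes = dict(DEFAULT_ARCHETYPES if archetypes is None else archetypes)
    missing = set(LABELS) - set(archetypes)
    if missing:
        raise ValueError(f"archetypes missing for {sorted(missing)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    diag_lines = []
    counter = 0
    pid = 101
    for label in LABELS:
        arch = archetypes[label]
        for _ in range(cfg.n_patients_per_class):
            diag_lines.append(f"{pid},{label}\n")
            for rec_i in range(cfg.recordings_per_patient):
                rng = np.random.default_rng([cfg.seed, counter])
                counter += 1
                dur = rng.uniform(*cfg.recording_duration_s)
                samples, anns = synth_recording(rng, arch, dur, cfg.sample_rate)
                loc = _LOCATIONS[counter % len(_LOCATIONS)]
                stem = f"{pid}_{rec_i + 1}b1_{loc}_sc_Synth"
                icbhi_io.write_wav(outdir / f"{stem}.wav", samples, cfg.sample_rate)
                (outdir / f"{stem}.txt").write_text(
                    icbhi_io.write_annotation_file(anns))
            pid += 1
    (outdir / "patient_diagnosis.csv").write_text("".join(diag_lines))
    return icbhi_io.index_dataset(outdir)
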