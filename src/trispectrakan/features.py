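"""Spectral features per standardized segment: MFCC, chroma, mel spectrogram.

All three share one STFT geometry (n_fft 2048, hop 512, Hann window,
centered frames with reflect padding), which maps a 6-s, 22,050 Hz segment
to exactly 259 frames: ``1 + floor(132300 / 512)``.

* MFCC: power STFT -> 128-band Slaney mel filterbank -> log-power (dB) ->
  orthonormal DCT-II over the mel axis, first 20 coefficients.
* Chroma: power STFT folded into 12 pitch classes (C = 0) by rounding each
  bin's pitch to the nearest semitone, then per-frame max-normalized.
* Mel spectrogram: mel power in dB with an 80 dB floor below the maximum.

Each matrix is finally z-scored per segment (zero mean, unit variance)
before entering the model; a trailing channel axis is appended when
features are stacked into model inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.fft import dct, rfft
from scipy.signal import get_window

from .preprocessing import TARGET_RATE

__all__ = [
    "StftSpec", "FeatureTriple", "stft_frame_count", "compute_mfcc",
    "compute_chroma", "compute_melspec", "extract_feature_triple",
    "triples_to_model_inputs", "zscore",
]

_DB_FLOOR = 80.0
_AMIN = 1e-10


@dataclass(frozen=True)
class StftSpec:
    """STFT geometry shared by the three feature extractors."""

    n_fft: int = 2048
    hop: int = 512
    centered: bool = True
    window: str = "hann"

    def __post_init__(self) -> None:
        if not 0 < self.hop <= self.n_fft:
            raise ValueError("require 0 < hop <= n_fft")


@dataclass
class FeatureTriple:
    """The three per-segment spectral matrices plus the shared frame count."""

    mfcc: np.ndarray    # (20, T)
    chroma: np.ndarray  # (12, T)
    mspec: np.ndarray   # (128, T)
    label: int = -1

    @property
    def n_frames(self) -> int:
        return self.mfcc.shape[1]


def stft_frame_count(n_samples: int, hop: int, centered: bool,
                     n_fft: int = 2048) -> int:
    """Number of STFT frames for a signal of ``n_samples``."""
    if n_samples < 1 or hop < 1 or n_fft < 1:
        raise ValueError("arguments must be positive")
    if centered:
        return 1 + n_samples // hop
    if n_samples < n_fft:
        raise ValueError("uncentered framing needs n_samples >= n_fft")
    return 1 + (n_samples - n_fft) // hop


def _power_stft(y: np.ndarray, spec: StftSpec) -> np.ndarray:
    """Power spectrogram |STFT|^2, shape (1 + n_fft/2, T)."""
    y = np.asarray(y, dtype=np.float64)
    if y.size == 0:
        raise ValueError("cannot compute STFT of an empty segment")
    n_fft, hop = spec.n_fft, spec.hop
    if spec.centered:
        pad = n_fft // 2
        y = np.pad(y, pad, mode="reflect" if len(y) > pad else "constant")
        t = 1 + (len(y) - 2 * (n_fft // 2)) // hop  # == 1 + n_samples // hop
    else:
        t = 1 + (len(y) - n_fft) // hop
    frames = sliding_window_view(y, n_fft)[::hop][:t]
    win = get_window(spec.window, n_fft, fftbins=True)
    spectrum = rfft(frames * win, axis=1)
    return (np.abs(spectrum) ** 2).T


def _hz_to_mel(f):
    """Slaney mel scale: linear below 1 kHz, logarithmic above."""
    f = np.asarray(f, dtype=np.float64)
    mel = f / (200.0 / 3.0)
    log_region = f >= 1000.0
    mel = np.where(log_region,
                   15.0 + np.log(np.maximum(f, 1e-12) / 1000.0) / (np.log(6.4) / 27.0),
                   mel)
    return mel


def _mel_to_hz(m):
    m = np.asarray(m, dtype=np.float64)
    f = m * (200.0 / 3.0)
    return np.where(m >= 15.0, 1000.0 * np.exp((np.log(6.4) / 27.0) * (m - 15.0)), f)


def mel_filterbank(sr: int, n_fft: int, n_mels: int,
                   fmin: float = 0.0, fmax: float | None = None) -> np.ndarray:
    """Area-normalized triangular mel filterbank, shape (n_mels, 1+n_fft/2)."""
    fmax = sr / 2.0 if fmax is None else fmax
    fft_freqs = np.arange(1 + n_fft // 2) * sr / n_fft
    mel_pts = _mel_to_hz(np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_mels + 2))
    fb = np.zeros((n_mels, len(fft_freqs)))
    for i in range(n_mels):
        lo, ctr, hi = mel_pts[i], mel_pts[i + 1], mel_pts[i + 2]
        up = (fft_freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - fft_freqs) / max(hi - ctr, 1e-12)
        fb[i] = np.maximum(0.0, np.minimum(up, down))
        fb[i] *= 2.0 / (hi - lo)  # Slaney area normalization
    return fb


def _power_to_db(s: np.ndarray, floor_db: float | None = _DB_FLOOR) -> np.ndarray:
    db = 10.0 * np.log10(np.maximum(s, _AMIN))
    if floor_db is not None:
        db = np.maximum(db, db.max() - floor_db)
    return db


def compute_melspec(segment: np.ndarray, spec: StftSpec = StftSpec(),
                    n_mels: int = 128, sr: int = TARGET_RATE) -> np.ndarray:
    """Mel power spectrogram in dB with an 80 dB floor below the maximum."""
    power = _power_stft(segment, spec)
    mel = mel_filterbank(sr, spec.n_fft, n_mels) @ power
    return _power_to_db(mel)


def compute_mfcc(segment: np.ndarray, spec: StftSpec = StftSpec(),
                 n_mfcc: int = 20, sr: int = TARGET_RATE) -> np.ndarray:
    """First ``n_mfcc`` mel-frequency cepstral coefficients per frame."""
    power = _power_stft(segment, spec)
    mel = mel_filterbank(sr, spec.n_fft, 128) @ power
    log_mel = _power_to_db(mel, floor_db=None)
    return dct(log_mel, type=2, axis=0, norm="ortho")[:n_mfcc]


def compute_chroma(segment: np.ndarray, spec: StftSpec = StftSpec(),
                   sr: int = TARGET_RATE) -> np.ndarray:
    """12-bin pitch-class energy profile per frame, max-normalized.

    Each FFT bin above 16 Hz contributes its power to the pitch class of
    its rounded semitone (C = 0).  All-zero frames stay all-zero.
    """
    power = _power_stft(segment, spec)
    freqs = np.arange(power.shape[0]) * sr / spec.n_fft
    valid = freqs > 16.0
    midi = 69.0 + 12.0 * np.log2(np.where(valid, freqs, 440.0) / 440.0)
    pc = np.mod(np.round(midi).astype(int), 12)
    chroma = np.zeros((12, power.shape[1]))
    np.add.at(chroma, pc[valid], power[valid])
    peak = chroma.max(axis=0, keepdims=True)
    return np.divide(chroma, peak, out=np.zeros_like(chroma), where=peak > 0)


def zscore(m: np.ndarray) -> np.ndarray:
    """Per-matrix standardization; constant matrices map to zeros."""
    sd = m.std()
    return (m - m.mean()) / (sd if sd > 1e-12 else 1.0)


def extract_feature_triple(segment, spec: StftSpec = StftSpec(),
                           normalize: bool = True) -> FeatureTriple:
    """Compute the MFCC / chroma / mel-spectrogram triple for one segment.

    Accepts an :class:`~trispectrakan.preprocessing.AudioSegment` or a bare
    sample array at 22,050 Hz.
    """
    label = getattr(segment, "label", -1)
    samples = getattr(segment, "samples", segment)
    mfcc = compute_mfcc(samples, spec)
    chroma = compute_chroma(samples, spec)
    mspec = compute_melspec(samples, spec)
    for name, mat in (("mfcc", mfcc), ("chroma", chroma), ("mspec", mspec)):
        if not np.all(np.isfinite(mat)):
            raise ValueError(f"non-finite values in {name}")
    if normalize:
        mfcc, chroma, mspec = zscore(mfcc), zscore(chroma), zscore(mspec)
    return FeatureTriple(mfcc=mfcc, chroma=chroma, mspec=mspec, label=label)


def triples_to_model_inputs(triples: list[FeatureTriple],
                            dtype=np.float32):
    """Stack triples into the three model input arrays plus the label vector.

    Returns ``([mfcc, chroma, mspec], labels)`` where each array has shape
    (N, height, T, 1) — the channel axis is appended last.
    """
    xs = [
        np.stack([t.mfcc for t in triples])[..., None].astype(dtype),
        np.stack([t.chroma for t in triples])[..., None].astype(dtype),
        np.stack([t.mspec for t in triples])[..., None].astype(dtype),
    ]
    y = np.array([t.label for t in triples], dtype=np.int64)
    return xs, y
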