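"""Standardize raw recordings into fixed-length mono segments.

Pipeline per recording: resample to 22,050 Hz, slice one segment per
annotated respiratory cycle, then zero-pad or trim each slice to exactly
six seconds (132,300 samples).  Padding appends silence after the cycle;
trimming keeps the first six seconds, where the inspiratory onset lies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import resample_poly

from .icbhi_io import CycleAnnotation, RecordingMeta, LABEL_TO_INDEX

logger = logging.getLogger(__name__)

TARGET_RATE = 22050
TARGET_SECONDS = 6.0
SEGMENT_SAMPLES = int(TARGET_RATE * TARGET_SECONDS)  # 132,300

__all__ = [
    "AudioSegment", "resample_audio", "slice_cycle", "fix_length",
    "preprocess_recording", "TARGET_RATE", "TARGET_SECONDS", "SEGMENT_SAMPLES",
]


@dataclass
class AudioSegment:
    """One standardized 6-s, 22,050 Hz mono segment with its class label."""

    samples: np.ndarray
    rate: int
    label: int
    source: RecordingMeta | None = None
    cycle_index: int = 0


def resample_audio(samples: np.ndarray, src_rate: int, target_rate: int) -> np.ndarray:
    """Band-limited polyphase resampling; identity when rates match."""
    samples = np.asarray(samples, dtype=np.float64)
    if samples.size == 0:
        raise ValueError("cannot resample empty audio")
    if src_rate <= 0 or target_rate <= 0:
        raise ValueError("sample rates must be positive")
    if src_rate == target_rate:
        return samples
    g = math.gcd(int(src_rate), int(target_rate))
    return resample_poly(samples, target_rate // g, src_rate // g)


def slice_cycle(samples: np.ndarray, rate: int, ann: CycleAnnotation) -> np.ndarray:
    """Extract samples[floor(start*rate) : floor(end*rate)], clamped to length.

    A cycle whose end runs past the recording is clamped with a warning;
    a cycle starting at or beyond the end of the recording is an error.
    """
    start = int(math.floor(ann.start_s * rate))
    end = int(math.floor(ann.end_s * rate))
    if start >= len(samples):
        raise ValueError(
            f"cycle start {ann.start_s:.3f}s beyond recording end "
            f"({len(samples) / rate:.3f}s)")
    if end > len(samples):
        logger.warning("cycle end %.3fs beyond recording end %.3fs; clamping",
                       ann.end_s, len(samples) / rate)
        end = len(samples)
    return samples[start:end]


def fix_length(segment: np.ndarray, rate: int, target_s: float = TARGET_SECONDS) -> np.ndarray:
    """Right-pad with zeros or trim to exactly ``rate * target_s`` samples."""
    segment = np.asarray(segment)
    if segment.size == 0:
        raise ValueError("cannot fix length of an empty segment")
    n = int(round(rate * target_s))
    if len(segment) >= n:
        return segment[:n]
    out = np.zeros(n, dtype=segment.dtype)
    out[:len(segment)] = segment
    return out


def preprocess_recording(samples: np.ndarray, src_rate: int,
                         annotations: list[CycleAnnotation],
                         meta: RecordingMeta) -> list[AudioSegment]:
    """One standardized segment per annotated cycle, order preserved."""
    if not annotations:
        logger.warning("recording %s has no annotated cycles",
                       meta.recording_token if meta else "?")
        return []
    resampled = resample_audio(samples, src_rate, TARGET_RATE)
    label = LABEL_TO_INDEX[meta.diagnosis] if meta and meta.diagnosis else -1
    segments = []
    for i, ann in enumerate(annotations):
        piece = slice_cycle(resampled, TARGET_RATE, ann)
        segments.append(AudioSegment(
            samples=fix_length(piece, TARGET_RATE),
            rate=TARGET_RATE, label=label, source=meta, cycle_index=i))
    return segments


def preprocess_index(index) -> list[AudioSegment]:
    """Run :func:`preprocess_recording` over every record of a DatasetIndex."""
    from .icbhi_io import read_wav
    segments: list[AudioSegment] = []
    for rec in index.records:
        samples, rate = read_wav(rec.audio_path)
        segments.extend(preprocess_recording(samples, rate, rec.cycles, rec.meta))
    return segments
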