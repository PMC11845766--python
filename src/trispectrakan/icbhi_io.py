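"""Reader/writer for lung-sound corpora in the ICBHI-2017 on-disk layout.

A corpus directory holds paired files per recording:

* ``<pid>_<token>_<location>_<mode>_<equipment>.wav`` — PCM audio;
* a same-stem ``.txt`` with one respiratory cycle per line
  (start s, end s, crackle flag, wheeze flag, tab-separated);
* one two-column diagnosis table (``patient id -> diagnosis``) covering
  the patients, CSV or TSV.

The six diagnosis labels are fixed; class indices follow alphabetical
order so they are deterministic across corpora.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.io import wavfile

logger = logging.getLogger(__name__)

#: Closed label set, alphabetical; index in this tuple is the class index.
LABELS: tuple[str, ...] = (
    "Bronchiectasis", "Bronchiolitis", "COPD", "Healthy", "Pneumonia", "URTI")

LABEL_TO_INDEX = {lab: i for i, lab in enumerate(LABELS)}
_CANONICAL = {lab.lower(): lab for lab in LABELS}


class ParseError(ValueError):
    """Malformed annotation, filename, or diagnosis-table content."""


@dataclass(frozen=True)
class CycleAnnotation:
    """One annotated respiratory cycle."""

    start_s: float
    end_s: float
    crackle: bool
    wheeze: bool

    def __post_init__(self) -> None:
        if not (np.isfinite(self.start_s) and np.isfinite(self.end_s)):
            raise ValueError("cycle times must be finite")
        if self.start_s < 0:
            raise ValueError("cycle start must be >= 0")
        if self.end_s <= self.start_s:
            raise ValueError("cycle end must be after start")


@dataclass
class RecordingMeta:
    """Per-recording metadata parsed from the ICBHI filename convention."""

    patient_id: int
    recording_token: str
    chest_location: str
    acquisition_mode: str
    equipment: str
    diagnosis: str | None = None

    def __post_init__(self) -> None:
        if self.patient_id < 0:
            raise ValueError("patient_id must be >= 0")
        if self.diagnosis is not None and self.diagnosis not in LABELS:
            raise ValueError(f"unknown diagnosis {self.diagnosis!r}")


@dataclass
class RecordingRecord:
    audio_path: Path
    annotation_path: Path
    meta: RecordingMeta
    cycles: list[CycleAnnotation]


@dataclass
class DatasetIndex:
    """Ordered collection of recordings with parsed annotations."""

    records: list[RecordingRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def summary(self) -> dict:
        n_cycles = sum(len(r.cycles) for r in self.records)
        n_crackle = sum(c.crackle for r in self.records for c in r.cycles)
        n_wheeze = sum(c.wheeze for r in self.records for c in r.cycles)
        n_both = sum(c.crackle and c.wheeze for r in self.records for c in r.cycles)
        per_class = {lab: 0 for lab in LABELS}
        for r in self.records:
            per_class[r.meta.diagnosis] += 1
        return {
            "n_recordings": len(self.records),
            "n_cycles": n_cycles,
            "n_crackle_cycles": n_crackle,
            "n_wheeze_cycles": n_wheeze,
            "n_both_cycles": n_both,
            "per_class_recordings": per_class,
        }

    def to_jsonl(self, path: Path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(json.dumps({
                    "audio": str(r.audio_path),
                    "annotation": str(r.annotation_path),
                    "meta": asdict(r.meta),
                    "cycles": [asdict(c) for c in r.cycles],
                }) + "\n")


def parse_cycle_annotations(text: str) -> list[CycleAnnotation]:
    """Parse annotation-file contents into cycles, order preserved.

    Each non-empty line must carry four whitespace-separated fields:
    start seconds, end seconds, crackle flag (0/1), wheeze flag (0/1).
    """
    cycles: list[CycleAnnotation] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) != 4:
            raise ParseError(
                f"expected 4 fields at line {lineno}, got {len(fields)}")
        try:
            start, end = float(fields[0]), float(fields[1])
        except ValueError as exc:
            raise ParseError(f"non-numeric time at line {lineno}") from exc
        if fields[2] not in ("0", "1") or fields[3] not in ("0", "1"):
            raise ParseError(f"flags must be 0 or 1 at line {lineno}")
        if end <= start:
            raise ParseError(f"end before start at line {lineno}")
        if start < 0 or not (np.isfinite(start) and np.isfinite(end)):
            raise ParseError(f"invalid times at line {lineno}")
        cycles.append(CycleAnnotation(start, end, fields[2] == "1", fields[3] == "1"))
    return cycles


def write_annotation_file(cycles: list[CycleAnnotation]) -> str:
    """Inverse of :func:`parse_cycle_annotations` (times at 3 decimals)."""
    lines = []
    for c in cycles:
        if c.end_s <= c.start_s:
            raise ValueError("cycle end must be after start")
        lines.append(f"{c.start_s:.3f}\t{c.end_s:.3f}\t{int(c.crackle)}\t{int(c.wheeze)}\n")
    return "".join(lines)


def parse_recording_filename(name: str) -> RecordingMeta:
    """Parse ``pid_token_location_mode_equipment.wav`` (diagnosis unset)."""
    stem = Path(name).name
    if stem.lower().endswith(".wav"):
        stem = stem[:-4]
    tokens = stem.split("_")
    if len(tokens) != 5:
        raise ParseError(
            f"{name!r}: expected 5 underscore-separated tokens, got {len(tokens)}")
    try:
        pid = int(tokens[0])
    except ValueError as exc:
        raise ParseError(f"{name!r}: patient id {tokens[0]!r} not an integer") from exc
    return RecordingMeta(pid, tokens[1], tokens[2], tokens[3], tokens[4])


def load_diagnosis_table(text: str) -> dict[int, str]:
    """Parse a two-column ``patient_id -> diagnosis`` table (tab or comma)."""
    table: dict[int, str] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        sep = "," if "," in line else "\t"
        fields = [f.strip() for f in line.split(sep)]
        if len(fields) != 2:
            raise ParseError(f"expected 2 columns at line {lineno}")
        try:
            pid = int(fields[0])
        except ValueError as exc:
            raise ParseError(f"non-integer patient id at line {lineno}") from exc
        label = _CANONICAL.get(fields[1].lower())
        if label is None:
            raise ParseError(f"unknown label {fields[1]!r} at line {lineno}")
        if pid in table and table[pid] != label:
            raise ParseError(f"conflicting labels for patient {pid}")
        table[pid] = label
    return table


def read_wav(path: Path) -> tuple[np.ndarray, int]:
    """Load PCM audio as float64 in [-1, 1]; stereo keeps channel 0."""
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        if data.dtype == np.uint8:
            samples = (data.astype(np.float64) - 128.0) / 128.0
        else:
            samples = data.astype(np.float64) / (float(info.max) + 1.0)
    else:
        samples = data.astype(np.float64)
    return samples, int(rate)


def write_wav(path: Path, samples: np.ndarray, rate: int) -> None:
    """Write float samples in [-1, 1] as 16-bit PCM."""
    pcm = np.clip(samples, -1.0, 1.0)
    wavfile.write(path, rate, np.round(pcm * 32767.0).astype(np.int16))


def _find_diagnosis_table(root: Path) -> Path | None:
    candidates = sorted(root.glob("*.csv")) + sorted(root.glob("*.tsv"))
    named = [p for p in candidates if "diagnosis" in p.name.lower()]
    if named:
        return named[0]
    return candidates[0] if candidates else None


def index_dataset(root: Path) -> DatasetIndex:
    """Index a corpus directory; skips unusable recordings with a warning.

    Raises if the directory yields zero usable records or lacks a
    diagnosis table.
    """
    root = Path(root)
    table_path = _find_diagnosis_table(root)
    if table_path is None:
        raise FileNotFoundError(f"no diagnosis table (csv/tsv) under {root}")
    diagnosis = load_diagnosis_table(table_path.read_text())

    index = DatasetIndex()
    for wav_path in sorted(root.glob("*.wav")):
        ann_path = wav_path.with_suffix(".txt")
        try:
            meta = parse_recording_filename(wav_path.name)
        except ParseError as exc:
            logger.warning("skipping %s: %s", wav_path.name, exc)
            continue
        if not ann_path.exists():
            logger.warning("skipping %s: no annotation file", wav_path.name)
            continue
        if meta.patient_id not in diagnosis:
            logger.warning("skipping %s: patient %d not in diagnosis table",
                           wav_path.name, meta.patient_id)
            continue
        try:
            cycles = parse_cycle_annotations(ann_path.read_text())
        except ParseError as exc:
            logger.warning("skipping %s: %s", wav_path.name, exc)
            continue
        try:
            read_wav(wav_path)
        except Exception as exc:  # corrupt audio
            logger.warning("skipping %s: unreadable audio (%s)", wav_path.name, exc)
            continue
        meta.diagnosis = diagnosis[meta.patient_id]
        index.records.append(RecordingRecord(wav_path, ann_path, meta, cycles))

    if not index.records:
        raise ParseError(f"no usable records under {root}")
    logger.info("indexed corpus: %s", index.summary())
    return index
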