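"""Core BCG signal handling: records, segments, manifests, normalization.

A recording is a single-channel amplitude series (arbitrary units) stored
as plain one-column UTF-8 text, one sample per line, with optional
``#``-prefixed comment lines.  A JSON manifest carries subject identity,
class label and sampling rate for each file.  Segmentation cuts a record
into consecutive, non-overlapping fixed-length windows anchored at sample
0 (the trailing remainder is discarded), and z-scoring uses the
population (1/N) variance so that re-normalizing is the identity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

LABEL_CONTROL = 0
LABEL_HYPERTENSIVE = 1
LABEL_NAMES = {LABEL_CONTROL: "control", LABEL_HYPERTENSIVE: "hypertensive"}
LABEL_CODES = {v: k for k, v in LABEL_NAMES.items()}

ZSCORE_TOL = 1e-9


class SignalError(ValueError):
    """Malformed or degenerate signal data."""


class ParseError(SignalError):
    """Unreadable signal file; carries the offending line number."""

    def __init__(self, path, line_number: int, content: str):
        self.line_number = line_number
        super().__init__(
            f"{path}: line {line_number}: not a numeric amplitude: {content!r}")


class DegenerateSignalError(SignalError):
    """Zero-variance input that cannot be z-scored."""


def coerce_label(label) -> int | None:
    """Accept 0/1 or the names 'control'/'hypertensive'; None passes through."""
    if label is None:
        return None
    if isinstance(label, str):
        try:
            return LABEL_CODES[label]
        except KeyError:
            raise SignalError(f"unknown label {label!r}; expected one of {sorted(LABEL_CODES)}")
    label = int(label)
    if label not in LABEL_NAMES:
        raise SignalError(f"label must be 0 (control) or 1 (hypertensive), got {label}")
    return label


@dataclass
class BcgRecord:
    """A continuous single-channel BCG recording."""

    samples: np.ndarray
    sampling_rate: float = 100.0
    subject_id: str = ""
    label: int | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise SignalError("record samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise SignalError("record contains non-finite samples")
        if self.sampling_rate <= 0:
            raise SignalError("sampling_rate must be positive")
        self.label = coerce_label(self.label)

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class BcgSegment:
    """A fixed-length window of a recording, the unit of processing."""

    samples: np.ndarray
    sampling_rate: float = 100.0
    subject_id: str = ""
    segment_index: int = 0
    label: int | None = None
    normalized: bool = False

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise SignalError("segment samples must be one-dimensional")
        self.label = coerce_label(self.label)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def segment_id(self) -> str:
        return f"{self.subject_id}/{self.segment_index}"


@dataclass
class ManifestEntry:
    path: str
    subject_id: str
    label: int | None
    sampling_rate: float = 100.0


@dataclass
class DatasetManifest:
    entries: list[ManifestEntry] = field(default_factory=list)
    provenance: str = ""
    seed: int | None = None

    def __post_init__(self):
        by_subject = {}
        for e in self.entries:
            e.label = coerce_label(e.label)
            prev = by_subject.setdefault(e.subject_id, e.label)
            if prev != e.label:
                raise SignalError(
                    f"subject {e.subject_id!r} appears with conflicting labels")

    def save(self, path) -> None:
        payload = {
            "provenance": self.provenance,
            "seed": self.seed,
            "entries": [
                {"path": e.path, "subject_id": e.subject_id,
                 "label": None if e.label is None else LABEL_NAMES[e.label],
                 "sampling_rate": e.sampling_rate}
                for e in self.entries
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path) -> "DatasetManifest":
        raw = json.loads(Path(path).read_text())
        if isinstance(raw, list):  # bare entry array is also accepted
            raw = {"entries": raw}
        entries = [ManifestEntry(e["path"], e["subject_id"], e.get("label"),
                                 float(e.get("sampling_rate", 100.0)))
                   for e in raw["entries"]]
        return cls(entries, raw.get("provenance", ""), raw.get("seed"))


def read_record(path, entry: ManifestEntry | None = None) -> BcgRecord:
    """Read a one-amplitude-per-line signal file, applying manifest metadata."""
    path = Path(path)
    values: list[float] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            try:
                values.append(float(stripped))
            except ValueError:
                raise ParseError(path, lineno, stripped) from None
    if not values:
        raise SignalError(f"{path}: empty record (no data lines)")
    if entry is None:
        return BcgRecord(np.array(values))
    return BcgRecord(np.array(values), sampling_rate=entry.sampling_rate,
                     subject_id=entry.subject_id, label=entry.label)


def write_record(path, record: BcgRecord, header: str | None = None) -> None:
    """Write a record as one amplitude per line (repr preserves the float exactly)."""
    lines = []
    if header:
        lines.extend("# " + h for h in header.splitlines())
    lines.extend(repr(float(v)) for v in record.samples)
    Path(path).write_text("\n".join(lines) + "\n")


def zscore_normalize(segment: BcgSegment) -> BcgSegment:
    """Return a copy shifted/scaled to mean 0 and population sd 1."""
    x = segment.samples
    if x.size < 2:
        raise SignalError("z-scoring needs at least 2 samples")
    sd = x.std()  # population (1/N) convention
    if sd == 0.0:
        raise DegenerateSignalError(
            f"segment {segment.segment_id}: zero variance, cannot z-score")
    z = (x - x.mean()) / sd
    return replace(segment, samples=z, normalized=True)


def segment_record(record: BcgRecord, segment_seconds: float = 10.0) -> list[BcgSegment]:
    """Cut into consecutive non-overlapping windows from sample 0.

    The window length ``segment_seconds * sampling_rate`` must be a
    positive integer; the trailing remainder is discarded.
    """
    win_f = segment_seconds * record.sampling_rate
    win = int(round(win_f))
    if win <= 0 or abs(win_f - win) > 1e-9:
        raise SignalError(
            f"segment_seconds * sampling_rate = {win_f} is not a positive integer")
    n = len(record) // win
    return [
        BcgSegment(record.samples[i * win:(i + 1) * win].copy(),
                   sampling_rate=record.sampling_rate,
                   subject_id=record.subject_id, segment_index=i,
                   label=record.label)
        for i in range(n)
    ]
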