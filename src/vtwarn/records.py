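"""Annotated R-R interval records: data model, text I/O, cleaning, windowing.

An implantable cardioverter-defibrillator (ICD) buffer holds up to 2048
consecutive R-R intervals, each annotated as a normal sinus beat (``N``), a
premature ventricular/ectopic beat (``V``) or a compensatory pause (``P``).
A record is either a routine download ("regular" rhythm) or the buffer that
immediately preceded an appropriate shock ("pre_appropriate_shock", anchored
at the arrhythmia onset).

Only normal-to-normal (N-N) intervals enter heart-rate-variability analysis:
:func:`filter_ectopic_beats` removes annotated ectopy plus timing outliers,
:func:`check_inclusion` enforces the >=1700-normal-beat inclusion rule, and
:func:`extract_pre_event_window` trims the pre-event horizon (5 minutes or
10 seconds) off the end of the record and returns the last *m* intervals.
"""

from __future__ import annotations

import os
from collections import deque
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Beat",
    "RRRecord",
    "Cohort",
    "RRValidationError",
    "RRParseError",
    "WindowTooShortError",
    "read_rr_file",
    "write_rr_file",
    "read_cohort",
    "write_cohort",
    "filter_ectopic_beats",
    "check_inclusion",
    "extract_pre_event_window",
    "VALID_LABELS",
    "RHYTHM_CLASSES",
    "REGULAR",
    "PRE_SHOCK",
    "MAX_BEATS",
    "MIN_NORMAL_BEATS",
    "HORIZON_SECONDS",
    "DEFAULT_WINDOW_M",
]

VALID_LABELS = ("N", "V", "P")
REGULAR = "regular"
PRE_SHOCK = "pre_appropriate_shock"
RHYTHM_CLASSES = (REGULAR, PRE_SHOCK)

#: Device buffer depth (intervals) of the shock-only single-chamber ICD.
MAX_BEATS = 2048
#: Minimum number of surviving normal beats for a record to be analyzed.
MIN_NORMAL_BEATS = 1700
#: Warning horizons: seconds trimmed off the end of each record.
HORIZON_SECONDS = {"five_minute": 300.0, "ten_second": 10.0}
#: Default analysis window length (intervals) per horizon.
DEFAULT_WINDOW_M = {"five_minute": 1000, "ten_second": 1600}

_MAX_INTERVAL_S = 4.0

# Ectopy timing rule: an N interval deviating more than this fraction from the
# running median of the previous _MEDIAN_MEMORY accepted intervals is removed
# together with the beat that follows it (treated as its compensatory pause).
_TIMING_TOLERANCE = 0.20
_MEDIAN_MEMORY = 5


class RRValidationError(ValueError):
    """A record, beat or argument violates a documented invariant."""


class RRParseError(RRValidationError):
    """A record file could not be parsed; the message names the line."""


class WindowTooShortError(RRValidationError):
    """Fewer than *m* intervals remain after the pre-event horizon trim."""


@dataclass(frozen=True)
class Beat:
    """One R-R interval (seconds since the previous beat) with its annotation."""

    interval: float
    label: str = "N"

    def __post_init__(self) -> None:
        if not (0.0 < self.interval < _MAX_INTERVAL_S):
            raise RRValidationError(
                f"beat interval {self.interval!r} s outside (0, {_MAX_INTERVAL_S})"
            )
        if self.label not in VALID_LABELS:
            raise RRValidationError(f"unknown beat label {self.label!r}")


@dataclass
class RRRecord:
    """An ordered, annotated tachogram with patient/rhythm metadata.

    Intervals and labels are held as numpy arrays; :attr:`beats` materializes
    :class:`Beat` objects on demand for small-scale inspection.
    """

    patient_id: str
    record_id: str
    rhythm_class: str
    intervals: np.ndarray
    labels: np.ndarray
    event_anchored: bool = False

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        self.labels = np.asarray(self.labels, dtype="U1")
        if self.intervals.ndim != 1 or self.labels.shape != self.intervals.shape:
            raise RRValidationError("intervals and labels must be 1-D and aligned")
        if self.intervals.size > MAX_BEATS:
            raise RRValidationError(
                f"{self.intervals.size} beats exceeds the {MAX_BEATS}-interval device buffer"
            )
        if self.intervals.size and (
            self.intervals.min() <= 0.0 or self.intervals.max() >= _MAX_INTERVAL_S
        ):
            raise RRValidationError("interval outside (0, 4.0) s")
        if not np.isin(self.labels, VALID_LABELS).all():
            bad = set(self.labels) - set(VALID_LABELS)
            raise RRValidationError(f"unknown beat labels {sorted(bad)}")
        if self.rhythm_class not in RHYTHM_CLASSES:
            raise RRValidationError(f"unknown rhythm_class {self.rhythm_class!r}")
        if self.rhythm_class == PRE_SHOCK and not self.event_anchored:
            raise RRValidationError("pre_appropriate_shock records must be event_anchored")
        if not self.patient_id:
            raise RRValidationError("patient_id must be non-empty")

    @classmethod
    def from_beats(
        cls,
        patient_id: str,
        record_id: str,
        rhythm_class: str,
        beats: Iterable[Beat],
        event_anchored: bool = False,
    ) -> "RRRecord":
        beats = list(beats)
        return cls(
            patient_id=patient_id,
            record_id=record_id,
            rhythm_class=rhythm_class,
            intervals=np.array([b.interval for b in beats], dtype=float),
            labels=np.array([b.label for b in beats], dtype="U1"),
            event_anchored=event_anchored,
        )

    @property
    def beats(self) -> tuple[Beat, ...]:
        return tuple(
            Beat(float(i), str(l)) for i, l in zip(self.intervals, self.labels)
        )

    @property
    def n_beats(self) -> int:
        return int(self.intervals.size)

    @property
    def times(self) -> np.ndarray:
        """Cumulative end-times t_j = sum_{i<=j} interval_i (strictly increasing)."""
        return np.cumsum(self.intervals)

    @property
    def duration(self) -> float:
        return float(self.intervals.sum())

    def n_normal(self) -> int:
        return int(np.count_nonzero(self.labels == "N"))

    def __eq__(self, other: object) -> bool:  # array fields need explicit handling
        if not isinstance(other, RRRecord):
            return NotImplemented
        return (
            self.patient_id == other.patient_id
            and self.record_id == other.record_id
            and self.rhythm_class == other.rhythm_class
            and self.event_anchored == other.event_anchored
            and np.array_equal(self.intervals, other.intervals)
            and np.array_equal(self.labels, other.labels)
        )


@dataclass
class Cohort:
    """A collection of records plus free-text provenance (seed or manifest)."""

    records: list[RRRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.record_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise RRValidationError("record_ids within a cohort must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def by_class(self, rhythm_class: str) -> list[RRRecord]:
        return [r for r in self.records if r.rhythm_class == rhythm_class]


# ---------------------------------------------------------------------------
# Text I/O
#
# Dialect: UTF-8, "# key: value" header lines (patient_id, record_id,
# rhythm_class, optionally event_anchored), then one "interval_ms<TAB>label"
# body line per beat with intervals stored as integer milliseconds.
# ---------------------------------------------------------------------------


def read_rr_file(path: str | os.PathLike) -> RRRecord:
    """Parse one R-R record file; raises :class:`RRParseError` with a line number."""
    path = Path(path)
    header: dict[str, str] = {}
    intervals: list[float] = []
    labels: list[str] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                try:
                    key, value = line[1:].split(":", 1)
                except ValueError:
                    raise RRParseError(f"{path}:{lineno}: malformed header line {line!r}")
                header[key.strip()] = value.strip()
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise RRParseError(
                    f"{path}:{lineno}: expected 'interval_ms<TAB>label', got {line!r}"
                )
            try:
                ms = int(parts[0])
            except ValueError:
                raise RRParseError(f"{path}:{lineno}: non-integer interval {parts[0]!r}")
            if not (0 < ms < _MAX_INTERVAL_S * 1000):
                raise RRValidationError(
                    f"{path}:{lineno}: interval {ms} ms outside (0, 4000)"
                )
            if parts[1] not in VALID_LABELS:
                raise RRValidationError(f"{path}:{lineno}: unknown label {parts[1]!r}")
            intervals.append(ms / 1000.0)
            labels.append(parts[1])
    for key in ("patient_id", "record_id", "rhythm_class"):
        if key not in header:
            raise RRParseError(f"{path}: missing required header '# {key}: ...'")
    return RRRecord(
        patient_id=header["patient_id"],
        record_id=header["record_id"],
        rhythm_class=header["rhythm_class"],
        intervals=np.array(intervals, dtype=float),
        labels=np.array(labels, dtype="U1"),
        event_anchored=header.get("event_anchored", "false").lower() == "true",
    )


def write_rr_file(record: RRRecord, path: str | os.PathLike) -> None:
    """Write *record* in the dialect :func:`read_rr_file` parses (1 ms resolution)."""
    path = Path(path)
    ms = np.rint(record.intervals * 1000.0).astype(int)
    lines = [
        f"# patient_id: {record.patient_id}",
        f"# record_id: {record.record_id}",
        f"# rhythm_class: {record.rhythm_class}",
        f"# event_anchored: {str(record.event_anchored).lower()}",
    ]
    lines.extend(f"{m}\t{l}" for m, l in zip(ms, record.labels))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_cohort(source: str | os.PathLike) -> Cohort:
    """Read a cohort from a manifest file (one record path per line) or a directory.

    Directories are scanned non-recursively for ``*.rr`` files.
    """
    source = Path(source)
    if source.is_dir():
        paths = sorted(source.glob("*.rr"))
        provenance = f"directory {source}"
    else:
        base = source.parent
        paths = []
        for line in source.read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if line and not line.startswith("#"):
                p = Path(line)
                paths.append(p if p.is_absolute() else base / p)
        provenance = f"manifest {source}"
    return Cohort(records=[read_rr_file(p) for p in paths], provenance=provenance)


def write_cohort(cohort: Cohort, out_dir: str | os.PathLike) -> Path:
    """Write every record as ``<record_id>.rr`` plus a ``manifest.txt``; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = []
    for rec in cohort.records:
        name = f"{rec.record_id}.rr"
        write_rr_file(rec, out_dir / name)
        names.append(name)
    manifest = out_dir / "manifest.txt"
    manifest.write_text("\n".join(names) + "\n", encoding="utf-8")
    return manifest


# ---------------------------------------------------------------------------
# Cleaning, inclusion, windowing
# ---------------------------------------------------------------------------


def filter_ectopic_beats(record: RRRecord) -> RRRecord:
    """Remove ectopic beats and compensatory pauses; returns an all-N record.

    Two rules, applied in a single ordered pass:

    * label rule — beats annotated ``V`` or ``P`` are dropped;
    * timing rule — an ``N`` interval deviating by more than 20% from the
      running median of the previous 5 accepted intervals is dropped together
      with the immediately following beat (its presumed compensatory pause).
      The rule arms once 5 intervals have been accepted.

    Idempotent: filtering a filtered record is the identity.
    """
    if record.n_beats == 0:
        raise RRValidationError("cannot filter an empty record")
    keep = np.zeros(record.n_beats, dtype=bool)
    recent: deque[float] = deque(maxlen=_MEDIAN_MEMORY)
    skip_next = False
    for i, (interval, label) in enumerate(zip(record.intervals, record.labels)):
        if skip_next:
            skip_next = False
            continue
        if label != "N":
            continue
        if len(recent) == _MEDIAN_MEMORY:
            med = sorted(recent)[2]  # median of the 5 most recent accepted
            if abs(interval - med) > _TIMING_TOLERANCE * med:
                skip_next = True
                continue
        keep[i] = True
        recent.append(float(interval))
    return replace(
        record, intervals=record.intervals[keep], labels=record.labels[keep]
    )


def check_inclusion(record: RRRecord) -> bool:
    """True iff >= 1700 normal beats survive :func:`filter_ectopic_beats`."""
    return filter_ectopic_beats(record).n_normal() >= MIN_NORMAL_BEATS


def extract_pre_event_window(
    record: RRRecord, horizon: str, m: int | None = None
) -> np.ndarray:
    """Trim the pre-event horizon off the record end, then take the last *m* intervals.

    All intervals whose cumulative end-time falls within ``HORIZON_SECONDS[horizon]``
    of the final beat time are dropped; the last *m* surviving intervals are
    returned in order. Regular (non-anchored) records are trimmed identically
    relative to the record end so both classes see the same transformation.
    """
    if horizon not in HORIZON_SECONDS:
        raise RRValidationError(
            f"unknown horizon {horizon!r}; expected one of {sorted(HORIZON_SECONDS)}"
        )
    if m is None:
        m = DEFAULT_WINDOW_M[horizon]
    t = record.times
    if t.size == 0:
        raise WindowTooShortError(f"{record.record_id}: empty record")
    cutoff = t[-1] - HORIZON_SECONDS[horizon]
    # tolerance absorbs cumulative-sum rounding at the boundary
    remaining = record.intervals[t <= cutoff + 1e-9]
    if remaining.size < m:
        raise WindowTooShortError(
            f"{record.record_id}: only {remaining.size} intervals remain after the "
            f"{horizon} trim; {m} required"
        )
    return remaining[-m:].copy()
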