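"""Data model and file I/O for raw acceleration recordings and interval labels.

Conventions used throughout the package:

* samples are 0-indexed; sample ``i`` of a recording occupies time
  ``i / rate_hz`` seconds from the start of the recording;
* all intervals are half-open ``[start_s, stop_s)`` in seconds on the
  recording's own time axis;
* acceleration is stored in gravity units (g), axis order
  (x = vertical, y = mediolateral, z = anteroposterior).

Recordings are exchanged as a plain CSV (header ``x,y,z``, one row per
sample) plus a JSON or YAML metadata sidecar; wear/non-wear labels as a
CSV with header ``participant_id,start_s,stop_s,label``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

WEAR = "wear"
NONWEAR = "nonwear"

_LABELS = frozenset({WEAR, NONWEAR})


class ValidationError(ValueError):
    """Raised when an input file or in-memory object violates the data model."""


@dataclass
class AccelRecording:
    """A uniform-rate triaxial acceleration trace in gravity units.

    Parameters
    ----------
    participant_id
        Identifier of the person (or simulated participant) who wore the device.
    rate_hz
        Sampling rate in samples per second; the reference device records at
        100 Hz but any positive rate is accepted.
    start_epoch_s
        Wall-clock start of the recording in epoch seconds (informational;
        all processing uses the recording's own time axis).
    samples
        ``(N, 3)`` float array of acceleration in g.
    dynamic_range_g
        Absolute bound on valid sample values (device dynamic range, default
        +/- 8 g).
    """

    participant_id: str
    rate_hz: float
    start_epoch_s: float
    samples: np.ndarray
    dynamic_range_g: float = 8.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValidationError(
                f"samples must be an (N, 3) matrix, got shape {self.samples.shape}"
            )
        if self.samples.shape[0] < 1:
            raise ValidationError("recording must contain at least one sample")
        if not self.rate_hz > 0:
            raise ValidationError(f"rate_hz must be positive, got {self.rate_hz}")
        if not np.all(np.isfinite(self.samples)):
            bad = int(np.argwhere(~np.isfinite(self.samples).all(axis=1))[0, 0])
            raise ValidationError(f"non-finite sample value in row {bad}")
        peak = float(np.abs(self.samples).max())
        if peak > self.dynamic_range_g:
            bad = int(np.argwhere(np.abs(self.samples).max(axis=1) > self.dynamic_range_g)[0, 0])
            raise ValidationError(
                f"row {bad} exceeds dynamic range of +/-{self.dynamic_range_g} g"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz


@dataclass(frozen=True)
class Interval:
    """Half-open time span ``[start_s, stop_s)`` in seconds from recording start."""

    start_s: float
    stop_s: float

    def __post_init__(self) -> None:
        if self.start_s < 0:
            raise ValidationError(f"interval start must be >= 0, got {self.start_s}")
        if not self.stop_s > self.start_s:
            raise ValidationError(
                f"interval stop ({self.stop_s}) must exceed start ({self.start_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.stop_s - self.start_s

    def overlap_s(self, other: "Interval") -> float:
        return max(0.0, min(self.stop_s, other.stop_s) - max(self.start_s, other.start_s))


@dataclass(frozen=True)
class LabeledInterval:
    """An interval carrying a wear/non-wear label (and optionally its owner)."""

    interval: Interval
    label: str
    participant_id: str | None = None

    def __post_init__(self) -> None:
        if self.label not in _LABELS:
            raise ValidationError(
                f"label must be one of {sorted(_LABELS)}, got {self.label!r}"
            )


def _read_sidecar(meta_path: str | Path) -> dict:
    meta_path = Path(meta_path)
    text = meta_path.read_text()
    if meta_path.suffix.lower() in {".yml", ".yaml"}:
        return yaml.safe_load(text)
    return json.loads(text)


def read_recording(path: str | Path, meta_path: str | Path) -> AccelRecording:
    """Read a recording CSV (header ``x,y,z``, values in g) plus its sidecar.

    The sidecar (JSON or YAML, by file extension) must declare
    ``participant_id``, ``rate_hz`` and ``start_epoch_s``; ``dynamic_range_g``
    is optional and defaults to 8 g.
    """
    meta = _read_sidecar(meta_path)
    for key in ("participant_id", "rate_hz", "start_epoch_s"):
        if key not in meta:
            raise ValidationError(f"metadata sidecar missing required key {key!r}")
    frame = pd.read_csv(path)
    missing = [c for c in ("x", "y", "z") if c not in frame.columns]
    if missing:
        raise ValidationError(f"recording CSV missing column(s) {missing}")
    cols = []
    for c in ("x", "y", "z"):
        numeric = pd.to_numeric(frame[c], errors="coerce")
        bad = numeric.isna() & frame[c].notna()
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise ValidationError(f"non-numeric value in column {c!r}, row {row}")
        if numeric.isna().any():
            row = int(np.argmax(numeric.isna().to_numpy()))
            raise ValidationError(f"missing value in column {c!r}, row {row}")
        cols.append(numeric.to_numpy(dtype=float))
    return AccelRecording(
        participant_id=str(meta["participant_id"]),
        rate_hz=float(meta["rate_hz"]),
        start_epoch_s=float(meta["start_epoch_s"]),
        samples=np.column_stack(cols),
        dynamic_range_g=float(meta.get("dynamic_range_g", 8.0)),
    )


def write_recording(rec: AccelRecording, path: str | Path, meta_path: str | Path) -> None:
    """Write a recording as CSV + JSON sidecar, lossless to 6 decimal digits of g."""
    path, meta_path = Path(path), Path(meta_path)
    frame = pd.DataFrame(rec.samples, columns=["x", "y", "z"])
    frame.to_csv(path, index=False, float_format="%.6f")
    meta = {
        "participant_id": rec.participant_id,
        "rate_hz": rec.rate_hz,
        "start_epoch_s": rec.start_epoch_s,
        "dynamic_range_g": rec.dynamic_range_g,
    }
    meta_path.write_text(json.dumps(meta, indent=2) + "\n")


def _check_no_overlap(records: Sequence[LabeledInterval]) -> None:
    by_pid: dict[str | None, list[LabeledInterval]] = {}
    for li in records:
        by_pid.setdefault(li.participant_id, []).append(li)
    for pid, group in by_pid.items():
        ordered = sorted(group, key=lambda li: li.interval.start_s)
        for a, b in zip(ordered, ordered[1:]):
            if b.interval.start_s < a.interval.stop_s:
                raise ValidationError(
                    f"overlapping intervals for participant {pid!r}: "
                    f"[{a.interval.start_s}, {a.interval.stop_s}) and "
                    f"[{b.interval.start_s}, {b.interval.stop_s})"
                )


def read_intervals(path: str | Path) -> list[LabeledInterval]:
    """Read a labelled-interval CSV; validates labels and same-participant overlap."""
    frame = pd.read_csv(path)
    required = ["participant_id", "start_s", "stop_s", "label"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValidationError(f"interval CSV missing column(s) {missing}")
    out = [
        LabeledInterval(
            interval=Interval(float(r.start_s), float(r.stop_s)),
            label=str(r.label),
            participant_id=str(r.participant_id),
        )
        for r in frame.itertuples(index=False)
    ]
    _check_no_overlap(out)
    return out


def write_intervals(intervals: Iterable[LabeledInterval], path: str | Path) -> None:
    """Write labelled intervals as CSV, sorted by participant then start time."""
    rows = sorted(
        intervals, key=lambda li: (li.participant_id or "", li.interval.start_s)
    )
    _check_no_overlap(rows)
    frame = pd.DataFrame(
        {
            "participant_id": [li.participant_id or "" for li in rows],
            "start_s": [li.interval.start_s for li in rows],
            "stop_s": [li.interval.stop_s for li in rows],
            "label": [li.label for li in rows],
        }
    )
    frame.to_csv(path, index=False)


def intervals_to_seconds(intervals: Sequence[Interval], duration_s: int) -> np.ndarray:
    """Rasterize intervals to a per-second 0/1 vector of length ``duration_s``.

    Second ``t`` (the span ``[t, t+1)``) is marked 1 when the intervals cover
    at least 0.5 s of it.  Intervals must lie within ``[0, duration_s]``.
    """
    duration_s = int(duration_s)
    if duration_s < 1:
        raise ValidationError(f"duration_s must be >= 1, got {duration_s}")
    coverage = np.zeros(duration_s, dtype=float)
    for iv in intervals:
        if iv.stop_s > duration_s:
            raise ValidationError(
                f"interval [{iv.start_s}, {iv.stop_s}) exceeds duration {duration_s}"
            )
        lo = int(np.floor(iv.start_s))
        hi = int(np.ceil(iv.stop_s))
        for t in range(lo, hi):
            coverage[t] += max(0.0, min(iv.stop_s, t + 1) - max(iv.start_s, t))
    return (coverage >= 0.5).astype(np.uint8)
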