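"""Interval-based non-wear detection baselines: XYZ, VMU and the HEES family.

All three require quiescence to persist for a fixed minimum interval
(15-135 min), so any non-wear episode shorter than the interval is
structurally undetectable — the limitation the interval-free pipeline in
:mod:`nonwear.pipeline` removes.

* XYZ: maximal runs of 1-min bins whose per-axis SDs are all below a
  threshold, kept when the run reaches the interval length.
* VMU: same run logic, but quiescence is judged on the SD of the
  per-sample vector magnitude within each bin.
* HEES: sliding long windows (GGIR convention); a window is non-wear when
  at least 2 of 3 axes are low-SD (< 13 mg) or at least 2 of 3 are
  low-range (< 50 mg); qualifying windows are unioned.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np

from .episodes import _bin_sds
from .signal_io import AccelRecording, Interval

XYZ_SD_MENU_G = (0.004, 0.005, 0.006, 0.007)
INTERVAL_MENU_MIN = (15, 30, 45, 60, 75, 90, 105, 120)


def _runs_to_intervals(
    quiescent: np.ndarray, bin_s: float, min_bins: int
) -> list[Interval]:
    """Maximal True-runs of length >= min_bins, as time intervals."""
    out: list[Interval] = []
    start: int | None = None
    for k, q in enumerate(quiescent):
        if q and start is None:
            start = k
        elif not q and start is not None:
            if k - start >= min_bins:
                out.append(Interval(start * bin_s, k * bin_s))
            start = None
    if start is not None and len(quiescent) - start >= min_bins:
        out.append(Interval(start * bin_s, len(quiescent) * bin_s))
    return out


def _check_menu(sd_threshold_g: float, interval_min: int) -> None:
    if not any(np.isclose(sd_threshold_g, v) for v in XYZ_SD_MENU_G):
        warnings.warn(
            f"SD threshold {sd_threshold_g} g outside the standard menu "
            f"{XYZ_SD_MENU_G}", stacklevel=3,
        )
    if interval_min not in INTERVAL_MENU_MIN:
        warnings.warn(
            f"interval {interval_min} min outside the standard menu "
            f"{INTERVAL_MENU_MIN}", stacklevel=3,
        )


def xyz_nonwear(
    rec: AccelRecording,
    sd_threshold_g: float = 0.004,
    interval_min: int = 90,
) -> list[Interval]:
    """Per-axis SD baseline: 1-min bins, all three axes below threshold,
    runs shorter than ``interval_min`` discarded."""
    _check_menu(sd_threshold_g, interval_min)
    quiescent = (_bin_sds(rec, 60.0) <= sd_threshold_g).all(axis=1)
    return _runs_to_intervals(quiescent, 60.0, interval_min)


def vmu_series(rec: AccelRecording) -> np.ndarray:
    """Per-sample vector magnitude sqrt(x^2 + y^2 + z^2), length N."""
    return np.linalg.norm(rec.samples, axis=1)


def vmu_nonwear(
    rec: AccelRecording,
    sd_threshold_g: float = 0.004,
    interval_min: int = 105,
) -> list[Interval]:
    """Vector-magnitude baseline: quiescence judged on the SD of the VMU
    series within each 1-min bin."""
    _check_menu(sd_threshold_g, interval_min)
    vmu = vmu_series(rec)
    n_per_bin = int(round(60.0 * rec.rate_hz))
    n_bins = vmu.shape[0] // n_per_bin
    sds = vmu[: n_bins * n_per_bin].reshape(n_bins, n_per_bin).std(axis=1, ddof=0)
    return _runs_to_intervals(sds <= sd_threshold_g, 60.0, interval_min)


def hees_nonwear(
    rec: AccelRecording,
    window_min: int = 60,
    step_min: int = 1,
    sd_threshold_mg: float = 13.0,
    range_threshold_mg: float = 50.0,
    min_axes: int = 2,
) -> list[Interval]:
    """HEES-style sliding-window detector (GGIR convention).

    A ``window_min``-minute window starting every ``step_min`` minutes is
    non-wear when at least ``min_axes`` axes have SD below
    ``sd_threshold_mg`` or at least ``min_axes`` axes have value range below
    ``range_threshold_mg``.  Qualifying windows are unioned into merged
    intervals.
    """
    if window_min < step_min:
        raise ValueError("window_min must be >= step_min")
    win_n = int(round(window_min * 60.0 * rec.rate_hz))
    step_n = int(round(step_min * 60.0 * rec.rate_hz))
    sd_thr = sd_threshold_mg / 1000.0
    rng_thr = range_threshold_mg / 1000.0
    hits: list[Interval] = []
    for i0 in range(0, rec.n_samples - win_n + 1, step_n):
        block = rec.samples[i0 : i0 + win_n]
        sd_ok = (block.std(axis=0, ddof=0) < sd_thr).sum() >= min_axes
        range_ok = ((block.max(axis=0) - block.min(axis=0)) < rng_thr).sum() >= min_axes
        if sd_ok or range_ok:
            start = i0 / rec.rate_hz
            hits.append(Interval(start, start + window_min * 60.0))
    return merge_intervals(hits)


def merge_intervals(intervals: Sequence[Interval]) -> list[Interval]:
    """Union of intervals: sorted, overlapping/touching spans coalesced."""
    if not intervals:
        return []
    ordered = sorted(intervals, key=lambda iv: iv.start_s)
    out = [ordered[0]]
    for iv in ordered[1:]:
        if iv.start_s <= out[-1].stop_s:
            if iv.stop_s > out[-1].stop_s:
                out[-1] = Interval(out[-1].start_s, iv.stop_s)
        else:
            out.append(iv)
    return out
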