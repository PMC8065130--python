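"""Candidate non-wear episode detection, merging, and 1-s edge refinement.

A candidate non-wear episode is a contiguous span of the recording in which
all three acceleration axes are quiescent: each 1-min interval has a
per-axis standard deviation at or below 4 mg (0.004 g), which sits just
above the noise floor of the reference device.  Candidates arise both
during true non-wear time and during sleep or sedentary behaviour; telling
those apart is the classifier's job, not this module's.

Processing order is fixed: detect on a 1-min grid, merge bordering
episodes separated by short artificial-movement gaps, then refine each
episode's edges outward in 1-s steps.  No re-merge happens after
refinement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .signal_io import AccelRecording, Interval

#: Quiescence threshold: 4 mg, just above the reference device's noise floor.
DEFAULT_SD_THRESHOLD_G = 0.004
#: Detection grid: tumbling 1-min bins aligned to recording start.
DEFAULT_BIN_S = 60


@dataclass(frozen=True)
class CandidateEpisode:
    """A below-threshold span, at minute or (after refinement) second resolution.

    ``merged_from`` counts how many minute-grid episodes were coalesced into
    this one (1 for an unmerged episode).
    """

    interval: Interval
    edge_resolution: str = "minute"  # "minute" | "second"
    merged_from: int = 1


def _slice_indices(rate_hz: float, start_s: float, stop_s: float, n: int) -> tuple[int, int]:
    """Sample-index range [i0, i1) holding samples with start_s <= i/rate < stop_s."""
    i0 = int(np.ceil(start_s * rate_hz - 1e-9))
    i1 = int(np.ceil(stop_s * rate_hz - 1e-9))
    return max(0, i0), min(n, i1)


def interval_sd(rec: AccelRecording, start_s: float, stop_s: float) -> np.ndarray:
    """Per-axis population standard deviation (divisor N) over ``[start_s, stop_s)``.

    The slice holds every sample ``i`` with ``start_s <= i / rate_hz < stop_s``
    and must contain at least two samples.
    """
    i0, i1 = _slice_indices(rec.rate_hz, start_s, stop_s, rec.n_samples)
    if i1 - i0 < 2:
        raise ValueError(
            f"interval [{start_s}, {stop_s}) holds {i1 - i0} sample(s); need >= 2"
        )
    return rec.samples[i0:i1].std(axis=0, ddof=0)


def _bin_sds(rec: AccelRecording, bin_s: float) -> np.ndarray:
    """Per-axis SD of each complete tumbling bin; shape (n_bins, 3)."""
    n_per_bin = int(round(bin_s * rec.rate_hz))
    n_bins = rec.n_samples // n_per_bin
    trimmed = rec.samples[: n_bins * n_per_bin].reshape(n_bins, n_per_bin, 3)
    return trimmed.std(axis=1, ddof=0)


def detect_candidates(
    rec: AccelRecording,
    sd_threshold_g: float = DEFAULT_SD_THRESHOLD_G,
    bin_s: float = DEFAULT_BIN_S,
) -> list[CandidateEpisode]:
    """Detect candidate episodes as maximal runs of quiescent 1-min bins.

    Bins tumble (non-overlapping) and are aligned to t=0; a bin is quiescent
    iff all three per-axis SDs are <= ``sd_threshold_g``.  A trailing partial
    bin is ignored (it remains reachable by :func:`refine_edges`).
    """
    if rec.duration_s < bin_s:
        warnings.warn(
            f"recording shorter than one {bin_s}-s bin; no detection possible",
            stacklevel=2,
        )
        return []
    quiescent = (_bin_sds(rec, bin_s) <= sd_threshold_g).all(axis=1)
    episodes: list[CandidateEpisode] = []
    run_start: int | None = None
    for k, q in enumerate(quiescent):
        if q and run_start is None:
            run_start = k
        elif not q and run_start is not None:
            episodes.append(
                CandidateEpisode(Interval(run_start * bin_s, k * bin_s))
            )
            run_start = None
    if run_start is not None:
        episodes.append(
            CandidateEpisode(Interval(run_start * bin_s, len(quiescent) * bin_s))
        )
    return episodes


def merge_bordering(
    episodes: list[CandidateEpisode], merge_min: int = 5
) -> list[CandidateEpisode]:
    """Coalesce consecutive episodes no more than ``merge_min`` minutes apart.

    Single left-to-right pass; the gap comparison is inclusive
    (gap <= merge_min * 60 s).  Idempotent on its own output.
    """
    for a, b in zip(episodes, episodes[1:]):
        if b.interval.start_s < a.interval.stop_s:
            raise ValueError("episodes must be sorted and non-overlapping")
    max_gap_s = merge_min * 60.0
    merged: list[CandidateEpisode] = []
    for ep in episodes:
        if merged and ep.interval.start_s - merged[-1].interval.stop_s <= max_gap_s:
            prev = merged[-1]
            merged[-1] = CandidateEpisode(
                Interval(prev.interval.start_s, ep.interval.stop_s),
                edge_resolution=prev.edge_resolution,
                merged_from=prev.merged_from + ep.merged_from,
            )
        else:
            merged.append(ep)
    return merged


def refine_edges(
    rec: AccelRecording,
    episode: CandidateEpisode,
    sd_threshold_g: float = DEFAULT_SD_THRESHOLD_G,
    step_s: float = 1.0,
) -> CandidateEpisode:
    """Extend an episode's edges outward in 1-s steps while quiescent.

    A backward pass from the start adds the preceding ``step_s`` block as long
    as all three per-axis SDs of that block stay <= ``sd_threshold_g``; a
    symmetric forward pass extends the stop.  Extension halts at the first
    failing block or at a recording boundary.  The episode never shrinks.
    """
    start = episode.interval.start_s
    while start - step_s >= 0:
        sd = interval_sd(rec, start - step_s, start)
        if np.all(sd <= sd_threshold_g):
            start -= step_s
        else:
            break
    if 0 < start < step_s:  # partial leading block
        i0, i1 = _slice_indices(rec.rate_hz, 0.0, start, rec.n_samples)
        if i1 - i0 >= 2 and np.all(interval_sd(rec, 0.0, start) <= sd_threshold_g):
            start = 0.0
    stop = episode.interval.stop_s
    duration = rec.duration_s
    while stop + step_s <= duration:
        sd = interval_sd(rec, stop, stop + step_s)
        if np.all(sd <= sd_threshold_g):
            stop += step_s
        else:
            break
    if stop < duration < stop + step_s:  # partial trailing block
        i0, i1 = _slice_indices(rec.rate_hz, stop, duration, rec.n_samples)
        if i1 - i0 >= 2 and np.all(interval_sd(rec, stop, duration) <= sd_threshold_g):
            stop = duration
    return replace(
        episode, interval=Interval(start, stop), edge_resolution="second"
    )
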