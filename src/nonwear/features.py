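"""Raw-signal windows around candidate episodes: extraction, labels, splits.

The classifier never sees the quiescent episode itself — only the ``w``
seconds of raw signal immediately *preceding* its start and immediately
*following* its stop, where the removal/attachment motion (if any) lives.
Windows are raw slices of the recording: no filtering or other
pre-processing is applied.  Start and stop windows of one episode always
share the episode's label; no distinction is made between removal and
attachment events.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .episodes import CandidateEpisode
from .signal_io import AccelRecording, LabeledInterval, NONWEAR, ValidationError

WINDOW_S_RANGE = (2, 10)
SPLITS = ("train", "val", "test")


@dataclass
class FeatureWindow:
    """A ``(window_s * rate_hz) x 3`` raw-signal slice beside one episode."""

    matrix: np.ndarray
    side: str  # "preceding" | "following"
    episode_ref: str
    label: int | None = None  # 0 = wear, 1 = nonwear


@dataclass
class FeatureDataset:
    windows: list[FeatureWindow]
    split_assignments: list[str] | None = None  # parallel to windows

    def __len__(self) -> int:
        return len(self.windows)

    def subset(self, split: str) -> "FeatureDataset":
        if self.split_assignments is None:
            raise ValueError("dataset has no split assignments")
        picked = [
            w for w, s in zip(self.windows, self.split_assignments) if s == split
        ]
        return FeatureDataset(windows=picked)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Stack windows into (B, rows, 3) X and (B,) y arrays."""
        X = np.stack([w.matrix for w in self.windows])
        y = np.array([w.label for w in self.windows], dtype=float)
        return X, y


def extract_windows(
    rec: AccelRecording,
    episode: CandidateEpisode,
    window_s: float = 3,
    episode_ref: str | None = None,
) -> tuple[FeatureWindow | None, FeatureWindow | None]:
    """Extract the preceding and following windows of one refined episode.

    The preceding window covers ``[t_start - w, t_start)`` and the following
    window ``[t_stop, t_stop + w)``; a side is ``None`` when the window would
    cross a recording boundary.  Row count is ``round(window_s * rate_hz)``.
    """
    if not WINDOW_S_RANGE[0] <= window_s <= WINDOW_S_RANGE[1]:
        raise ValidationError(
            f"window_s must be in [{WINDOW_S_RANGE[0]}, {WINDOW_S_RANGE[1]}], "
            f"got {window_s}"
        )
    ref = episode_ref or f"ep@{episode.interval.start_s:g}"
    n_rows = int(round(window_s * rec.rate_hz))
    t_start, t_stop = episode.interval.start_s, episode.interval.stop_s

    preceding: FeatureWindow | None = None
    i1 = int(round(t_start * rec.rate_hz))
    i0 = i1 - n_rows
    if i0 >= 0:
        preceding = FeatureWindow(rec.samples[i0:i1].copy(), "preceding", ref)

    following: FeatureWindow | None = None
    j0 = int(round(t_stop * rec.rate_hz))
    j1 = j0 + n_rows
    if j1 <= rec.n_samples:
        following = FeatureWindow(rec.samples[j0:j1].copy(), "following", ref)
    return preceding, following


def label_candidates(
    episodes: Sequence[CandidateEpisode],
    truth: Sequence[LabeledInterval],
    min_overlap_frac: float = 0.5,
) -> dict[int, int]:
    """Label each episode 1 (non-wear) or 0 (wear) against ground truth.

    An episode is non-wear when more than ``min_overlap_frac`` of its time
    lies inside true non-wear intervals; both of its windows inherit the
    label.  ``truth`` must tile the episode's span.
    """
    out: dict[int, int] = {}
    for k, ep in enumerate(episodes):
        covered = sum(ep.interval.overlap_s(li.interval) for li in truth)
        if covered < ep.interval.duration_s - 1e-9:
            raise ValidationError(
                f"episode [{ep.interval.start_s}, {ep.interval.stop_s}) is not "
                "fully covered by truth intervals"
            )
        nonwear_s = sum(
            ep.interval.overlap_s(li.interval)
            for li in truth
            if li.label == NONWEAR
        )
        out[k] = int(nonwear_s / ep.interval.duration_s > min_overlap_frac)
    return out


def balance_upsample(ds: FeatureDataset, seed: int) -> FeatureDataset:
    """Equalize class counts by random duplication of the minority class.

    Intended for the training split only; duplicates are drawn uniformly with
    replacement and matrices are never modified.
    """
    labels = np.array([w.label for w in ds.windows])
    if any(l is None for l in labels):
        raise ValueError("all windows must be labelled before balancing")
    pos = [w for w in ds.windows if w.label == 1]
    neg = [w for w in ds.windows if w.label == 0]
    if not pos or not neg:
        raise ValueError("both classes must be present to balance")
    minority, majority = (pos, neg) if len(pos) < len(neg) else (neg, pos)
    if len(minority) == len(majority):
        return FeatureDataset(windows=list(ds.windows))
    rng = np.random.default_rng(seed)
    extra_idx = rng.integers(len(minority), size=len(majority) - len(minority))
    extras = [replace(minority[i]) for i in extra_idx]
    return FeatureDataset(windows=list(ds.windows) + extras)


def split_dataset(
    ds: FeatureDataset,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
    unit: str = "window",
    participant_of=None,
) -> FeatureDataset:
    """Assign windows to train/val/test splits (default 60/20/20).

    ``unit="window"`` shuffles windows stratified by label; counts match the
    fractions to within one item per stratum.  ``unit="participant"`` keeps
    all windows of one participant in one split (``participant_of`` maps a
    window to its participant id) to prevent leakage across people.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    if len(ds.windows) < 3:
        raise ValueError("need at least 3 windows to split")
    rng = np.random.default_rng(seed)
    assignments = [""] * len(ds.windows)

    def assign(indices: list[int]) -> None:
        indices = list(indices)
        rng.shuffle(indices)
        n = len(indices)
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        for pos, idx in enumerate(indices):
            if pos < n_train:
                assignments[idx] = "train"
            elif pos < n_train + n_val:
                assignments[idx] = "val"
            else:
                assignments[idx] = "test"

    if unit == "window":
        for lab in (0, 1):
            assign([k for k, w in enumerate(ds.windows) if w.label == lab])
        unlabelled = [k for k, w in enumerate(ds.windows) if w.label is None]
        if unlabelled:
            assign(unlabelled)
    elif unit == "participant":
        if participant_of is None:
            raise ValueError("participant-level split needs participant_of")
        pids = sorted({participant_of(w) for w in ds.windows})
        order = list(pids)
        rng.shuffle(order)
        n = len(order)
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        split_of = {}
        for pos, pid in enumerate(order):
            split_of[pid] = (
                "train" if pos < n_train else "val" if pos < n_train + n_val else "test"
            )
        for k, w in enumerate(ds.windows):
            assignments[k] = split_of[participant_of(w)]
    else:
        raise ValueError(f"unknown split unit {unit!r}")
    return FeatureDataset(windows=list(ds.windows), split_assignments=assignments)


def save_dataset(ds: FeatureDataset, h5_path: str | Path, manifest_path: str | Path) -> None:
    """Persist matrices to HDF5 and window metadata to a CSV manifest."""
    with h5py.File(h5_path, "w") as f:
        for k, w in enumerate(ds.windows):
            f.create_dataset(f"window_{k:06d}", data=w.matrix)
    pd.DataFrame(
        {
            "window_index": range(len(ds.windows)),
            "episode_ref": [w.episode_ref for w in ds.windows],
            "side": [w.side for w in ds.windows],
            "label": [w.label if w.label is not None else "" for w in ds.windows],
            "split": (
                ds.split_assignments
                if ds.split_assignments is not None
                else [""] * len(ds.windows)
            ),
        }
    ).to_csv(manifest_path, index=False)


def load_dataset(h5_path: str | Path, manifest_path: str | Path) -> FeatureDataset:
    manifest = pd.read_csv(manifest_path, keep_default_na=False)
    windows: list[FeatureWindow] = []
    with h5py.File(h5_path, "r") as f:
        for row in manifest.itertuples(index=False):
            label = None if row.label == "" else int(float(row.label))
            windows.append(
                FeatureWindow(
                    matrix=f[f"window_{int(row.window_index):06d}"][()],
                    side=row.side,
                    episode_ref=row.episode_ref,
                    label=label,
                )
            )
    splits = [str(s) for s in manifest["split"]]
    has_splits = any(s for s in splits)
    return FeatureDataset(windows=windows, split_assignments=splits if has_splits else None)
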