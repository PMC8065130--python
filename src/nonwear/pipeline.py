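"""The interval-free non-wear algorithm, end to end.

Steps, in fixed order: detect candidate episodes on the 1-min SD grid,
merge bordering episodes separated by short artificial-movement gaps,
refine each episode's edges to 1-s resolution, classify the raw windows
immediately preceding and following each episode with the CNN, and combine
the two window decisions into one episode decision.

Episodes decided *wear* contribute no non-wear seconds even though they
sit below the quiescence threshold — distinguishing quiet wear
(sleep, sedentary time) from true non-wear is the whole point of the
classifier stage.  Defaults correspond to the best-performing
hyperparameter combination: merge gap 5 min, logical operator AND, and
missing edge windows defaulting to non-wear.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .baselines import merge_intervals
from .cnn import Sequential, predict
from .episodes import detect_candidates, merge_bordering, refine_edges
from .features import extract_windows
from .signal_io import AccelRecording, Interval, NONWEAR, WEAR

_OPERATORS = ("AND", "OR")
_EDGE_DEFAULTS = (WEAR, NONWEAR)


@dataclass(frozen=True)
class PipelineConfig:
    sd_threshold_g: float = 0.004
    bin_s: float = 60.0
    merge_min: int = 5
    window_s: float = 3
    operator: str = "AND"
    edge_default: str = NONWEAR
    decision_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.merge_min not in (1, 2, 3, 4, 5):
            raise ValueError("merge_min must be in 1..5")
        if self.operator not in _OPERATORS:
            raise ValueError(f"operator must be one of {_OPERATORS}")
        if self.edge_default not in _EDGE_DEFAULTS:
            raise ValueError(f"edge_default must be one of {_EDGE_DEFAULTS}")

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)


def decide_episode(
    start_pred: int | None,
    stop_pred: int | None,
    operator: str = "AND",
    edge_default: str = NONWEAR,
) -> str:
    """Combine start/stop window classes (1 = non-wear) into an episode label.

    A missing side (episode touching a recording boundary) takes the
    ``edge_default`` class.  AND requires both sides non-wear; OR either.
    """
    if start_pred is None and stop_pred is None and edge_default is None:
        raise ValueError("both sides absent and no edge default configured")
    default_cls = 1 if edge_default == NONWEAR else 0
    start = default_cls if start_pred is None else start_pred
    stop = default_cls if stop_pred is None else stop_pred
    if operator == "AND":
        return NONWEAR if (start == 1 and stop == 1) else WEAR
    if operator == "OR":
        return NONWEAR if (start == 1 or stop == 1) else WEAR
    raise ValueError(f"unknown operator {operator!r}")


def infer_nonwear(
    rec: AccelRecording,
    model: Sequential,
    cfg: PipelineConfig | None = None,
) -> list[Interval]:
    """Infer non-wear intervals for one recording.

    Returns the refined 1-s-resolution intervals of every candidate episode
    the classifier (plus edge defaults) decides is non-wear, sorted and
    non-overlapping.  All other time is wear.
    """
    cfg = cfg or PipelineConfig()
    expected_rows = int(round(cfg.window_s * rec.rate_hz))
    if model.input_shape != (expected_rows, 3):
        raise ValueError(
            f"model input {model.input_shape} does not match window_s="
            f"{cfg.window_s} at {rec.rate_hz} Hz (expected ({expected_rows}, 3))"
        )
    episodes = detect_candidates(rec, cfg.sd_threshold_g, cfg.bin_s)
    episodes = merge_bordering(episodes, cfg.merge_min)
    episodes = [
        refine_edges(rec, ep, cfg.sd_threshold_g) for ep in episodes
    ]
    out: list[Interval] = []
    for ep in episodes:
        preceding, following = extract_windows(rec, ep, cfg.window_s)
        start_pred = stop_pred = None
        batch = [w for w in (preceding, following) if w is not None]
        if batch:
            classes = [c for _, c in predict(model, batch, cfg.decision_threshold)]
            it = iter(classes)
            if preceding is not None:
                start_pred = next(it)
            if following is not None:
                stop_pred = next(it)
        decision = decide_episode(start_pred, stop_pred, cfg.operator, cfg.edge_default)
        if decision == NONWEAR:
            out.append(ep.interval)
    return merge_intervals(out)
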