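"""Synthetic raw-accelerometry cohorts with ground-truth wear/non-wear labels.

The generator emulates the signal classes an interval-free non-wear
detector has to tell apart:

* **active wear** — gravity distributed over the axes by a slowly drifting
  orientation plus band-limited movement noise (per-axis SD well above the
  4 mg quiescence threshold);
* **sedentary/sleep wear** — worn but nearly still: constant gravity
  projection plus sensor-level noise, interrupted by occasional
  posture-change bursts, with *no* removal signature at its boundaries;
* **non-wear** — the device at rest: constant gravity projection plus
  white sensor noise (per-axis SD <= 4 mg), optionally containing a short
  artificial-movement spike (a nudge of the unworn device);
* **removal/attachment transients** — 1-3 s high-dynamics bursts with an
  orientation change, bracketing every non-wear episode whose boundary is
  interior to the recording.

Every recording therefore contains candidate episodes that are true
non-wear and candidate episodes that are merely quiet wear, separable only
by what happens immediately before and after them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_io import AccelRecording, Interval, LabeledInterval, NONWEAR, WEAR

WEAR_ACTIVE = "wear_active"
WEAR_SEDENTARY = "wear_sedentary"

#: Wear bouts are kept longer than the largest explored merge gap (5 min),
#: so episode merging only ever bridges artificial movement *within* a
#: non-wear or sedentary span, never across a genuine wear bout.
_DEFAULT_MENU = (
    (WEAR_ACTIVE, (6.0, 15.0)),
    (WEAR_SEDENTARY, (6.0, 15.0)),
    (NONWEAR, (2.0, 30.0)),
)


class SchedulingError(ValueError):
    """Raised when an episode menu cannot tile the requested duration."""


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Durations in the episode menu are in minutes; everything else is in
    seconds, Hz or g.  ``noise_sd_nonwear_g`` must stay below the 4 mg
    quiescence threshold, mirroring the sensor noise floor.
    """

    seed: int = 0
    n_participants: int = 1
    duration_s: int = 21600
    rate_hz: float = 100.0
    noise_sd_nonwear_g: float = 0.002
    wear_active_sd_g: float = 0.05
    sedentary_burst_rate_per_hr: float = 4.0
    transient_duration_s: tuple[float, float] = (1.0, 3.0)
    transient_amp_g: tuple[float, float] = (0.5, 2.0)
    artificial_spike_prob: float = 0.3
    episode_menu: tuple = _DEFAULT_MENU

    def __post_init__(self) -> None:
        if not self.noise_sd_nonwear_g < 0.004:
            raise ValueError("noise_sd_nonwear_g must be < 0.004 g (4 mg)")
        if self.duration_s <= 0 or self.rate_hz <= 0:
            raise ValueError("duration_s and rate_hz must be positive")
        if not 0.0 <= self.artificial_spike_prob <= 1.0:
            raise ValueError("artificial_spike_prob must be in [0, 1]")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        for kind, (lo, hi) in self.episode_menu:
            if lo <= 0 or hi < lo:
                raise ValueError(f"bad duration range for {kind}: ({lo}, {hi})")


@dataclass(frozen=True)
class ScheduledEpisode:
    kind: str  # wear_active | wear_sedentary | nonwear
    interval: Interval

    @property
    def label(self) -> str:
        return NONWEAR if self.kind == NONWEAR else WEAR


@dataclass(frozen=True)
class SimEvent:
    """A transient, spike or posture burst; spans [start_s, stop_s)."""

    start_s: float
    stop_s: float
    kind: str  # removal | attachment | spike | burst


@dataclass
class SimOutput:
    recording: AccelRecording
    truth: list[LabeledInterval]
    event_log: list[SimEvent]
    schedule: list[ScheduledEpisode] = field(default_factory=list)


def schedule_episodes(cfg: SimConfig, rng: np.random.Generator) -> list[ScheduledEpisode]:
    """Sample an episode sequence tiling exactly ``[0, duration_s)``.

    Episode boundaries fall on whole seconds.  Non-wear episodes are never
    adjacent to each other and, when the menu offers active wear, are
    bracketed by it on both sides — taking a device off and putting it back
    on happens while the wearer is up and moving, not mid-sleep.  For the
    same reason the recording starts and ends with active wear (the device
    is worn when the recording is started and stopped).
    """
    menu = list(cfg.episode_menu)
    if not menu:
        raise SchedulingError("episode menu is empty")
    wear_entries = [m for m in menu if m[0] != NONWEAR]
    active_entries = [m for m in menu if m[0] == WEAR_ACTIVE]
    out: list[ScheduledEpisode] = []
    t = 0
    prev_kind: str | None = None
    while t < cfg.duration_s:
        if t == 0 and active_entries:
            pool = active_entries
        elif prev_kind == NONWEAR:
            if active_entries:
                pool = active_entries
            elif wear_entries:
                pool = wear_entries
            else:
                raise SchedulingError(
                    "menu has only non-wear episodes; adjacent non-wear is not allowed"
                )
        elif prev_kind == WEAR_SEDENTARY and active_entries:
            # non-wear may only follow active wear
            pool = [m for m in menu if m[0] != NONWEAR]
        else:
            pool = menu
        kind, (lo_min, hi_min) = pool[rng.integers(len(pool))]
        dur = int(round(rng.uniform(lo_min * 60.0, hi_min * 60.0)))
        dur = max(1, dur)
        if t + dur >= cfg.duration_s:
            # final episode: truncate to fit, and never end on non-wear
            if kind == NONWEAR and active_entries:
                kind = WEAR_ACTIVE
            elif kind == NONWEAR and wear_entries:
                kind = wear_entries[0][0]
            dur = cfg.duration_s - t
        out.append(ScheduledEpisode(kind, Interval(float(t), float(t + dur))))
        prev_kind = kind
        t += dur
    return out


def schedule_to_truth(schedule: list[ScheduledEpisode]) -> list[LabeledInterval]:
    """Collapse a schedule to wear/non-wear truth intervals tiling the recording."""
    truth: list[LabeledInterval] = []
    for ep in schedule:
        if truth and truth[-1].label == ep.label:
            prev = truth[-1]
            truth[-1] = LabeledInterval(
                Interval(prev.interval.start_s, ep.interval.stop_s), prev.label,
                participant_id=prev.participant_id,
            )
        else:
            truth.append(LabeledInterval(ep.interval, ep.label))
    return truth


def _unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _smooth_noise(rng: np.random.Generator, n: int, sd: float, rate_hz: float) -> np.ndarray:
    """Band-limited Gaussian noise, per-axis SD rescaled to ``sd``."""
    raw = rng.normal(0.0, 1.0, size=(n, 3))
    k = max(1, int(round(0.2 * rate_hz)))
    if k > 1 and n > k:
        kernel = np.ones(k) / k
        raw = np.column_stack([np.convolve(raw[:, a], kernel, mode="same") for a in range(3)])
    std = raw.std(axis=0, ddof=0)
    std[std == 0] = 1.0
    return raw / std * sd


def _oscillation(
    rng: np.random.Generator,
    n: int,
    rate_hz: float,
    amp: float,
    freq_range_hz: tuple[float, float] = (2.5, 8.0),
) -> np.ndarray:
    """Amplitude-modulated oscillation (Hann envelope) on a random axis mix.

    Removal/attachment transients use the default brisk band (several Hz);
    slow posture shifts pass a sub-Hz band.  The band is clipped below the
    Nyquist frequency of the recording rate.
    """
    t = np.arange(n) / rate_hz
    lo, hi = freq_range_hz
    hi = min(hi, 0.45 * rate_hz)
    lo = min(lo, 0.9 * hi)
    f = rng.uniform(lo, hi)
    envelope = np.hanning(max(n, 2))[:n]
    wave = amp * envelope * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    mix = _unit_vector(rng)
    return wave[:, None] * mix[None, :]


def _jerk(
    rng: np.random.Generator, n: int, rate_hz: float, amp: float
) -> np.ndarray:
    """Removal/attachment motion: brisk oscillation on all three axes.

    Handling the device excites every axis (unlike a subtle single-axis
    posture shift), each with its own frequency and phase in the brisk band.
    """
    t = np.arange(n) / rate_hz
    envelope = np.hanning(max(n, 2))[:n]
    # brisk band, kept well below Nyquist so the waveform is resolved
    hi = min(8.0, 0.35 * rate_hz)
    lo = min(1.5, 0.9 * hi)
    out = np.empty((n, 3))
    for axis in range(3):
        f = rng.uniform(lo, hi)
        scale = rng.uniform(0.5, 1.0) * rng.choice([-1.0, 1.0])
        out[:, axis] = (
            amp * scale * envelope * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        )
    return out


def _idx(rate_hz: float, t: float) -> int:
    return int(round(t * rate_hz))


def simulate_recording(cfg: SimConfig, participant_index: int = 0) -> SimOutput:
    """Synthesize one participant's recording, truth labels and event log.

    Deterministic in ``(cfg.seed, participant_index)``: the participant's
    random substream is spawned from that pair.
    """
    rng = np.random.default_rng([cfg.seed, participant_index])
    rate = cfg.rate_hz
    n = int(round(cfg.duration_s * rate))
    samples = np.zeros((n, 3))
    schedule = schedule_episodes(cfg, rng)
    events: list[SimEvent] = []

    orientations: list[np.ndarray] = []
    prev_orient = _unit_vector(rng)
    for ep in schedule:
        i0, i1 = _idx(rate, ep.interval.start_s), _idx(rate, ep.interval.stop_s)
        m = i1 - i0
        if ep.kind == WEAR_ACTIVE:
            # slow orientation drift between two poses + movement noise
            target = _unit_vector(rng)
            frac = np.linspace(0.0, 1.0, m)[:, None]
            grav = prev_orient[None, :] * (1 - frac) + target[None, :] * frac
            grav /= np.linalg.norm(grav, axis=1, keepdims=True)
            samples[i0:i1] = grav + _smooth_noise(rng, m, cfg.wear_active_sd_g, rate)
            prev_orient = target
        elif ep.kind == WEAR_SEDENTARY:
            samples[i0:i1] = prev_orient[None, :] + rng.normal(
                0.0, cfg.noise_sd_nonwear_g, size=(m, 3)
            )
            n_bursts = rng.poisson(
                cfg.sedentary_burst_rate_per_hr * ep.interval.duration_s / 3600.0
            )
            bursts = []
            for _ in range(n_bursts):
                b_dur = rng.uniform(2.0, 5.0)
                if ep.interval.duration_s < b_dur + 20.0:
                    continue
                b_start = rng.uniform(
                    ep.interval.start_s + 10.0,
                    ep.interval.stop_s - 10.0 - b_dur,
                )
                bursts.append((b_start, b_dur))
            for b_start, b_dur in sorted(bursts):
                j0, j1 = _idx(rate, b_start), _idx(rate, b_start + b_dur)
                samples[j0:j1] += _oscillation(
                    rng, j1 - j0, rate, rng.uniform(0.15, 0.35),
                    freq_range_hz=(0.3, 1.2),
                )
                events.append(SimEvent(b_start, b_start + b_dur, "burst"))
                # small posture change: orientation steps at the burst
                prev_orient = _unit_vector(rng) * 0.2 + prev_orient
                prev_orient /= np.linalg.norm(prev_orient)
                samples[j1:i1] = prev_orient[None, :] + rng.normal(
                    0.0, cfg.noise_sd_nonwear_g, size=(i1 - j1, 3)
                )
        else:  # nonwear: device at rest
            rest_orient = _unit_vector(rng)
            samples[i0:i1] = rest_orient[None, :] + rng.normal(
                0.0, cfg.noise_sd_nonwear_g, size=(m, 3)
            )
            if (
                rng.uniform() < cfg.artificial_spike_prob
                and ep.interval.duration_s >= 240.0
            ):
                s_dur = rng.uniform(1.0, 2.0)
                s_start = rng.uniform(
                    ep.interval.start_s + 90.0,
                    ep.interval.stop_s - 90.0 - s_dur,
                )
                j0, j1 = _idx(rate, s_start), _idx(rate, s_start + s_dur)
                samples[j0:j1] += _oscillation(
                    rng, j1 - j0, rate, rng.uniform(0.3, 0.8)
                )
                events.append(SimEvent(s_start, s_start + s_dur, "spike"))
            orientations.append(rest_orient)
            prev_orient = rest_orient

    # removal/attachment transients at every interior non-wear boundary
    for ep in schedule:
        if ep.kind != NONWEAR:
            continue
        a, b = ep.interval.start_s, ep.interval.stop_s
        if a > 0:
            d = rng.uniform(*cfg.transient_duration_s)
            d = min(d, a)
            j0, j1 = _idx(rate, a - d), _idx(rate, a)
            m = j1 - j0
            amp = rng.uniform(*cfg.transient_amp_g)
            frac = np.linspace(0.0, 1.0, m)[:, None]
            before = samples[max(0, j0 - 1)]
            after = samples[min(n - 1, j1)]
            base = before[None, :] * (1 - frac) + after[None, :] * frac
            samples[j0:j1] = base + _jerk(rng, m, rate, amp)
            events.append(SimEvent(a - d, a, "removal"))
        if b < cfg.duration_s:
            d = rng.uniform(*cfg.transient_duration_s)
            d = min(d, cfg.duration_s - b)
            j0, j1 = _idx(rate, b), _idx(rate, b + d)
            m = j1 - j0
            amp = rng.uniform(*cfg.transient_amp_g)
            frac = np.linspace(0.0, 1.0, m)[:, None]
            before = samples[max(0, j0 - 1)]
            after = samples[min(n - 1, j1)]
            base = before[None, :] * (1 - frac) + after[None, :] * frac
            samples[j0:j1] = base + _jerk(rng, m, rate, amp)
            events.append(SimEvent(b, b + d, "attachment"))

    rec = AccelRecording(
        participant_id=f"sim{participant_index:03d}",
        rate_hz=rate,
        start_epoch_s=0.0,
        samples=np.clip(samples, -8.0, 8.0),
    )
    truth = [
        LabeledInterval(li.interval, li.label, participant_id=rec.participant_id)
        for li in schedule_to_truth(schedule)
    ]
    events.sort(key=lambda e: e.start_s)
    return SimOutput(recording=rec, truth=truth, event_log=events, schedule=schedule)


def simulate_cohort(cfg: SimConfig) -> list[SimOutput]:
    """Independent recordings for every participant in the config."""
    return [simulate_recording(cfg, i) for i in range(cfg.n_participants)]
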