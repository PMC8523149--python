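"""Movement coding: velocity computation, event-aligned averages, shift null.

Velocity is computed from the animal's centroid track, smoothed with a 0.5 s
sliding average and resampled onto the 10 Hz imaging frame grid.  For each
neuron, speed in a +/-5 s window around every transient onset is averaged
after subtracting the per-event baseline (mean speed at -5..-3 s); the
"alignment score" is the mean of that profile in the +/-0.5 s window around
the onset.  Significance comes from a circular time-shift null: the velocity
is rotated by 10-1200 s within concatenated recorded time (which preserves
its marginal distribution exactly) and the score recomputed.  A neuron is
"heightened" if its observed score exceeds the null's 95th percentile, and
symmetrically "lowered" below the 5th; the lowered rule mirrors the top-5%
rule so both signs of coupling are detectable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import SessionDesign
from .transients import TransientTrain

__all__ = [
    "VelocityTrace",
    "AlignmentProfile",
    "MovementLabel",
    "NullScores",
    "compute_velocity",
    "total_distance",
    "align_to_events",
    "shift_null",
    "classify_movement",
    "label_movement",
    "sensitization_index",
]

LAG_HALF_S = 5.0
BASELINE_LAGS_S = (-5.0, -3.0)
SCORE_LAGS_S = (-0.5, 0.5)


@dataclass
class VelocityTrace:
    """Speed per imaging frame (same time base as the fluorescence traces)."""

    times_s: np.ndarray
    speed: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.speed = np.asarray(self.speed, dtype=float)
        if self.times_s.shape != self.speed.shape:
            raise ValueError("times and speed must have equal length")
        if np.any(self.speed < 0):
            raise ValueError("speed must be nonnegative")


@dataclass
class AlignmentProfile:
    """Baseline-subtracted event-triggered velocity average for one neuron."""

    neuron_id: str
    lags_s: np.ndarray
    profile: np.ndarray
    n_events_used: int
    score: float


@dataclass
class MovementLabel:
    neuron_id: str
    label: str                  # heightened / lowered / none
    score: float | None
    null_p05: float | None
    null_p95: float | None
    n_events_used: int
    reason: str = ""


@dataclass
class NullScores:
    """Shift-null distribution of alignment scores."""

    values: np.ndarray
    n_shuffles: int
    seed: int | None


# ---------------------------------------------------------------------------


def compute_velocity(
    track: pd.DataFrame,
    imaging_times: np.ndarray,
    smooth_s: float = 0.5,
) -> VelocityTrace:
    """Frame-to-frame Euclidean speed, 0.5 s-smoothed, resampled to 10 Hz.

    ``track`` needs columns ``time_s``, ``x``, ``y``.  Smoothing is a centred
    moving average on the track's own time base; resampling onto the imaging
    frame times is linear.
    """
    t = np.asarray(track["time_s"], dtype=float)
    x = np.asarray(track["x"], dtype=float)
    y = np.asarray(track["y"], dtype=float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("track times must be strictly increasing")
    speed = np.hypot(np.diff(x), np.diff(y)) / dt
    tm = 0.5 * (t[:-1] + t[1:])
    w = max(1, int(round(smooth_s / np.median(dt))))
    if w > 1:
        speed = np.convolve(speed, np.ones(w) / w, mode="same")
    resampled = np.interp(imaging_times, tm, speed)
    return VelocityTrace(times_s=np.asarray(imaging_times, float),
                         speed=np.clip(resampled, 0.0, None))


def total_distance(track: pd.DataFrame) -> float:
    """Path length of a centroid track (same units as x/y)."""
    return float(
        np.hypot(np.diff(np.asarray(track["x"])), np.diff(np.asarray(track["y"]))).sum()
    )


# ---------------------------------------------------------------------------


def _event_frames(
    train: TransientTrain, design: SessionDesign
) -> tuple[np.ndarray, int]:
    """Recorded-axis frame index of each onset, keeping only events whose
    +/-5 s window stays inside the event's own recording window."""
    fs = design.sample_rate_hz
    half = int(round(LAG_HALF_S * fs))
    edges = np.concatenate([[0], np.cumsum(design.frames_per_window())])
    keep = []
    for onset in train.onsets_s:
        for (a, b), lo, hi in zip(design.windows, edges[:-1], edges[1:]):
            if a <= onset < b:
                f = int(np.rint(design.to_recorded(onset)[0] * fs))
                if f - half >= lo and f + half < hi:
                    keep.append(f)
                break
    if not keep:
        return np.array([], dtype=int), 0
    return np.asarray(keep, dtype=int), len(keep)


def _lag_indices(fs: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    lags = np.arange(-int(round(LAG_HALF_S * fs)), int(round(LAG_HALF_S * fs)) + 1)
    base = lags[
        (lags >= BASELINE_LAGS_S[0] * fs) & (lags <= BASELINE_LAGS_S[1] * fs)
    ]
    score = lags[(lags >= SCORE_LAGS_S[0] * fs) & (lags <= SCORE_LAGS_S[1] * fs)]
    return lags, base, score


def align_to_events(
    vel: VelocityTrace, train: TransientTrain, design: SessionDesign
) -> AlignmentProfile | None:
    """Event-triggered, baseline-subtracted velocity average.

    Returns ``None`` when no event has a full +/-5 s window inside its
    recording window.
    """
    fs = design.sample_rate_hz
    frames, n_used = _event_frames(train, design)
    if n_used == 0:
        return None
    lags, base_l, score_l = _lag_indices(fs)
    segs = vel.speed[frames[:, None] + lags[None, :]]
    baselines = vel.speed[frames[:, None] + base_l[None, :]].mean(axis=1)
    prof = (segs - baselines[:, None]).mean(axis=0)
    score_mask = np.isin(lags, score_l)
    return AlignmentProfile(
        neuron_id=train.neuron_id,
        lags_s=lags / fs,
        profile=prof,
        n_events_used=n_used,
        score=float(prof[score_mask].mean()),
    )


def shift_null(
    vel: VelocityTrace,
    train: TransientTrain,
    design: SessionDesign,
    n_shuffles: int = 10_000,
    shift_range_s: tuple[float, float] = (10.0, 1200.0),
    seed: int | np.random.Generator = 0,
) -> NullScores | None:
    """Null alignment scores from circular rotations of the velocity.

    Each shuffle draws a shift magnitude uniformly in ``shift_range_s``
    (sign randomised), rotates the velocity circularly within concatenated
    recorded time, and recomputes the score for the same events.  A shift of
    one full recording length is the identity.
    """
    rng = np.random.default_rng(seed)
    fs = design.sample_rate_hz
    frames, n_used = _event_frames(train, design)
    if n_used == 0:
        return None
    T = len(vel.speed)
    _, base_l, score_l = _lag_indices(fs)
    # cumulative sum over a doubled signal: any window of the rotated trace
    # is a contiguous slice of the doubled original
    c = np.concatenate([[0.0], np.cumsum(np.concatenate([vel.speed, vel.speed]))])
    shifts = rng.uniform(shift_range_s[0], shift_range_s[1], size=n_shuffles)
    signs = rng.choice([-1, 1], size=n_shuffles)
    shift_frames = np.rint(shifts * fs).astype(int) * signs
    # rotating velocity by +s == sampling original at (index - s)
    pos = (frames[None, :] - shift_frames[:, None]) % T  # (n_shuffles, n_events)
    s0, s1 = int(score_l[0]), int(score_l[-1]) + 1
    b0, b1 = int(base_l[0]), int(base_l[-1]) + 1
    qs = (pos + s0) % T
    qb = (pos + b0) % T
    score_mean = (c[qs + (s1 - s0)] - c[qs]) / (s1 - s0)
    base_mean = (c[qb + (b1 - b0)] - c[qb]) / (b1 - b0)
    vals = (score_mean - base_mean).mean(axis=1)
    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    return NullScores(values=vals, n_shuffles=n_shuffles, seed=seed_val)


def _nearest_rank(sorted_vals: np.ndarray, pct: float) -> float:
    n = len(sorted_vals)
    idx = int(np.ceil(pct / 100.0 * n)) - 1
    return float(sorted_vals[max(0, min(idx, n - 1))])


def classify_movement(
    profile: AlignmentProfile | None,
    null: NullScores | None,
    upper_pct: float = 95.0,
    lower_pct: float = 5.0,
) -> MovementLabel:
    """Heightened above the null's 95th percentile, lowered below the 5th
    (nearest-rank percentiles, strict inequalities; ties are 'none')."""
    if profile is None or null is None:
        return MovementLabel(
            neuron_id=profile.neuron_id if profile else "",
            label="none", score=None, null_p05=None, null_p95=None,
            n_events_used=0, reason="no_usable_events",
        )
    sv = np.sort(null.values)
    hi = _nearest_rank(sv, upper_pct)
    lo = _nearest_rank(sv, lower_pct)
    if profile.score > hi:
        label = "heightened"
    elif profile.score < lo:
        label = "lowered"
    else:
        label = "none"
    return MovementLabel(
        neuron_id=profile.neuron_id,
        label=label,
        score=profile.score,
        null_p05=lo,
        null_p95=hi,
        n_events_used=profile.n_events_used,
    )


def label_movement(
    vel: VelocityTrace,
    train: TransientTrain,
    design: SessionDesign,
    n_shuffles: int = 10_000,
    shift_range_s: tuple[float, float] = (10.0, 1200.0),
    seed: int | np.random.Generator = 0,
) -> tuple[MovementLabel, AlignmentProfile | None]:
    """Profile, shift null and classification in one call."""
    prof = align_to_events(vel, train, design)
    if prof is None:
        return (
            MovementLabel(train.neuron_id, "none", None, None, None, 0,
                          reason="no_usable_events"),
            None,
        )
    null = shift_null(vel, train, design, n_shuffles, shift_range_s, seed)
    return classify_movement(prof, null), prof


def sensitization_index(dist_day1: float, dist_day8: float) -> float:
    """Ratio of distance moved on the second vs first cocaine day."""
    if dist_day1 <= 0:
        raise ValueError("day-1 distance must be positive")
    return dist_day8 / dist_day1
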