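"""Cocaine-responsiveness classification by the interval-shuffle bootstrap.

Per neuron, the change in transient frequency between the last 5 min before
and the first 5 min after the injection is compared to a within-neuron null:
the neuron's inter-transient intervals (including the latency from recording
start to the first transient) are permuted 10,000 times on the gap-free
recorded-time axis, each permutation is cumulated back into a surrogate
train, and the same frequency change is recomputed.  A neuron is "elevated"
if its observed change strictly exceeds the null's 99th percentile value and
"reduced" below the 1st (nearest-rank percentiles; ties classify as none).

Intervals are shuffled on concatenated recorded time so no artificial giant
interval spans the gaps between 5-min windows, and the first-onset latency is
part of the permuted set so shuffled trains can move mass across the
injection boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import permutations as _permutations

import numpy as np
from scipy import stats

from .design import SessionDesign
from .transients import TransientTrain

__all__ = [
    "ActivityChange",
    "NullDistribution",
    "ResponseLabel",
    "CrossSessionProfile",
    "window_count",
    "activity_change",
    "shuffle_null",
    "enumerate_null",
    "classify",
    "label_neuron",
    "fraction_responsive",
    "fisher_exact",
    "wilcoxon_signed_rank",
    "bonferroni",
    "track_profiles",
    "log2_response",
]

WINDOW_S = 300.0
DEFAULT_N_SHUFFLES = 10_000
DEFAULT_MIN_EVENTS = 5


@dataclass
class ActivityChange:
    neuron_id: str
    n_pre: int
    n_post: int

    @property
    def delta_hz(self) -> float:
        return (self.n_post - self.n_pre) / WINDOW_S


@dataclass
class NullDistribution:
    values: np.ndarray
    n_shuffles: int
    seed: int | None


@dataclass
class ResponseLabel:
    neuron_id: str
    label: str                      # elevated / reduced / none
    delta_hz: float | None
    null_p01: float | None
    null_p99: float | None
    n_pre: int = 0
    n_post: int = 0
    reason: str = ""


@dataclass
class CrossSessionProfile:
    tracked_id: str
    label_day1: str
    label_day8: str
    category_elevated: str = ""
    category_reduced: str = ""


# ---------------------------------------------------------------------------
# counting and observed change


def window_count(train: TransientTrain, window: tuple[float, float]) -> int:
    """Number of onsets with ``start <= t < end``."""
    a, b = window
    return int(
        np.searchsorted(train.onsets_s, b, side="left")
        - np.searchsorted(train.onsets_s, a, side="left")
    )


def activity_change(train: TransientTrain, design: SessionDesign) -> ActivityChange:
    """Transient-count change between the 5 min before and after injection."""
    pre_w, post_w = design.pre_post_windows(WINDOW_S)
    return ActivityChange(
        neuron_id=train.neuron_id,
        n_pre=window_count(train, pre_w),
        n_post=window_count(train, post_w),
    )


# ---------------------------------------------------------------------------
# interval-shuffle null


def _intervals_recorded(train: TransientTrain, design: SessionDesign) -> np.ndarray:
    """Permutable interval set on the gap-free recorded axis: first-onset
    latency followed by successive differences."""
    rec = np.sort(design.to_recorded(train.onsets_s))
    return np.concatenate([rec[:1], np.diff(rec)])


def _recorded_analysis_bounds(design: SessionDesign) -> tuple[float, float, float]:
    pre_w, post_w = design.pre_post_windows(WINDOW_S)
    a = design.to_recorded(pre_w[0])[0]
    inj = a + WINDOW_S
    return a, inj, inj + WINDOW_S


def _deltas_from_onset_matrix(
    onsets: np.ndarray, design: SessionDesign
) -> np.ndarray:
    a, inj, b = _recorded_analysis_bounds(design)
    n_pre = ((onsets >= a) & (onsets < inj)).sum(axis=1)
    n_post = ((onsets >= inj) & (onsets < b)).sum(axis=1)
    return (n_post - n_pre) / WINDOW_S


def shuffle_null(
    train: TransientTrain,
    design: SessionDesign,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int | np.random.Generator = 0,
    min_events: int = DEFAULT_MIN_EVENTS,
) -> NullDistribution:
    """Null frequency changes from uniform permutations of the interval set.

    Every permutation preserves the event count and the last-onset time.
    Raises ``ValueError`` below ``min_events`` onsets (callers label such
    neurons 'none' with reason ``too_few_events``).
    """
    if len(train) < min_events:
        raise ValueError("too_few_events")
    rng = np.random.default_rng(seed)
    iv = _intervals_recorded(train, design)
    perms = rng.permuted(np.tile(iv, (n_shuffles, 1)), axis=1)
    onsets = np.cumsum(perms, axis=1)
    vals = _deltas_from_onset_matrix(onsets, design)
    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    return NullDistribution(values=vals, n_shuffles=n_shuffles, seed=seed_val)


def enumerate_null(
    train: TransientTrain, design: SessionDesign
) -> np.ndarray:
    """Exact null over all interval permutations (tiny trains only)."""
    iv = _intervals_recorded(train, design)
    mats = np.array([p for p in _permutations(iv)])
    onsets = np.cumsum(mats, axis=1)
    return _deltas_from_onset_matrix(onsets, design)


def _nearest_rank(sorted_vals: np.ndarray, pct: float) -> float:
    n = len(sorted_vals)
    idx = int(np.ceil(pct / 100.0 * n)) - 1
    return float(sorted_vals[max(0, min(idx, n - 1))])


def classify(
    change: ActivityChange,
    null: NullDistribution,
    upper_pct: float = 99.0,
    lower_pct: float = 1.0,
) -> ResponseLabel:
    """Strict comparison against nearest-rank null percentiles."""
    sv = np.sort(null.values)
    hi = _nearest_rank(sv, upper_pct)
    lo = _nearest_rank(sv, lower_pct)
    obs = change.delta_hz
    if obs > hi:
        label = "elevated"
    elif obs < lo:
        label = "reduced"
    else:
        label = "none"
    return ResponseLabel(
        neuron_id=change.neuron_id,
        label=label,
        delta_hz=obs,
        null_p01=lo,
        null_p99=hi,
        n_pre=change.n_pre,
        n_post=change.n_post,
    )


def label_neuron(
    train: TransientTrain,
    design: SessionDesign,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int | np.random.Generator = 0,
    min_events: int = DEFAULT_MIN_EVENTS,
) -> ResponseLabel:
    """Observed change, shuffle null and classification in one call.

    Neurons with fewer than ``min_events`` onsets are labelled 'none' with
    reason ``too_few_events`` (they still count in denominators downstream).
    """
    change = activity_change(train, design)
    if len(train) < min_events:
        return ResponseLabel(
            neuron_id=train.neuron_id,
            label="none",
            delta_hz=change.delta_hz,
            null_p01=None,
            null_p99=None,
            n_pre=change.n_pre,
            n_post=change.n_post,
            reason="too_few_events",
        )
    null = shuffle_null(train, design, n_shuffles, seed, min_events)
    return classify(change, null)


# ---------------------------------------------------------------------------
# summaries and statistics


def fraction_responsive(labels: list[ResponseLabel]) -> dict:
    """Counts and fractions per direction; fractions sum to 1."""
    if not labels:
        raise ValueError("no_neurons")
    n = len(labels)
    counts = {
        k: sum(1 for l in labels if l.label == k)
        for k in ("elevated", "reduced", "none")
    }
    return {
        "n": n,
        "counts": counts,
        "fractions": {k: v / n for k, v in counts.items()},
    }


def fisher_exact(counts) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    Returns the cross-product odds ratio (``inf`` when the off-diagonal is
    empty) and the exact two-sided p-value (sum of hypergeometric
    probabilities at most that of the observed table).
    """
    table = np.asarray(counts, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a nonnegative 2x2 table")
    if table.sum(axis=0).min() == 0 and table.sum(axis=1).min() == 0:
        raise ValueError("margins must be positive")
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def wilcoxon_signed_rank(deltas) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped.  The exact null distribution is used up to
    n = 25 non-zero pairs, the continuity-corrected normal approximation
    above.  All-zero input is degenerate and reported as p = 1 with a
    warning.
    """
    d = np.asarray(deltas, dtype=float)
    d = d[d != 0]
    if len(d) == 0:
        warnings.warn("all paired differences are zero; Wilcoxon undefined",
                      stacklevel=2)
        return 0.0, 1.0
    method = "exact" if len(d) <= 25 else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", correction=(method == "approx"),
                         alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: ``min(1, m*p)`` per p-value."""
    p = np.asarray(p_values, dtype=float)
    m = len(p) if m is None else m
    return np.minimum(1.0, m * p)


def log2_response(n_pre: int, n_post: int) -> float:
    """log2((n_post + 10) / (n_pre + 10)); the +10 damps small counts."""
    return float(np.log2((n_post + 10.0) / (n_pre + 10.0)))


# ---------------------------------------------------------------------------
# cross-session tracking


def _category(l1: str, l2: str, direction: str) -> str:
    first, last = l1 == direction, l2 == direction
    if first and last:
        return "both"
    if last:
        return "last_exposure_only"
    if first:
        return "first_exposure_only"
    return "never"


def track_profiles(
    labels_s1: dict[str, ResponseLabel],
    labels_s2: dict[str, ResponseLabel],
    identity_map: dict[str, tuple[str, str]],
) -> tuple[list[CrossSessionProfile], dict]:
    """Profile neurons tracked across two sessions.

    ``identity_map`` maps a tracked id to its (session-1, session-2) neuron
    ids.  Per direction, each tracked neuron is categorised as responsive on
    both sessions, only the last, only the first, or never; the tallies
    partition the tracked set.
    """
    profiles = []
    tallies = {
        d: {"both": 0, "last_exposure_only": 0, "first_exposure_only": 0, "never": 0}
        for d in ("elevated", "reduced")
    }
    for tid, (id1, id2) in identity_map.items():
        if id1 not in labels_s1 or id2 not in labels_s2:
            continue
        l1, l2 = labels_s1[id1].label, labels_s2[id2].label
        prof = CrossSessionProfile(
            tracked_id=tid,
            label_day1=l1,
            label_day8=l2,
            category_elevated=_category(l1, l2, "elevated"),
            category_reduced=_category(l1, l2, "reduced"),
        )
        profiles.append(prof)
        tallies["elevated"][prof.category_elevated] += 1
        tallies["reduced"][prof.category_reduced] += 1
    return profiles, tallies
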