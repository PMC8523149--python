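"""Calcium transient detection, model fitting, cleaning and reconstruction.

A calcium transient is modelled as the product of a logistic rise and an
exponential decay sharing one reference time ``t0``::

    f(t) = alpha_p / (1 + exp(-(t - t0) / tau_g)) * exp(-(t - t0) / tau_d)

with ``alpha_p`` the upper asymptote of the rise, ``tau_g`` the growth time
constant, ``tau_d`` the decay time constant and ``f(t0) = alpha_p / 2``.  For
``tau_g < tau_d`` this rises quickly and decays slowly, vanishing in both
limits.  The same product is sometimes written with the opposite sign in the
logistic exponent; the two forms are identical under a sign flip of ``tau_g``
and this module uses the rising orientation throughout.

The detection chain is:

1. :func:`baseline_correct` — subtract a sliding lowest-quantile baseline;
2. :func:`detect_epochs` — threshold smoothed derivatives to find paired
   rise/decay epochs;
3. :func:`fit_reference` then :func:`fit_events` — nonlinear least-squares
   fits of the kernel to each epoch;
4. :func:`clean_fits` — reject implausible fits;
5. :func:`to_train` — emit the half-rise onset times used by all downstream
   inference.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.optimize import least_squares
from scipy.special import expit
from scipy.stats import median_abs_deviation

from .design import DesignError, SessionDesign

logger = logging.getLogger(__name__)

__all__ = [
    "RawTrace",
    "CorrectedTrace",
    "EpochPair",
    "TransientModelParams",
    "TransientEvent",
    "TransientTrain",
    "eval_kernel",
    "kernel_onset",
    "baseline_correct",
    "detect_epochs",
    "fit_reference",
    "fit_transient",
    "fit_events",
    "clean_fits",
    "reconstruct",
    "to_train",
    "detect_transients",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class RawTrace:
    """One neuron's fluorescence over a session's recorded windows."""

    neuron_id: str
    session_id: str
    sample_rate_hz: float
    samples: np.ndarray
    design: SessionDesign

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")
        if abs(len(self.samples) - self.design.n_frames) > len(self.design.windows):
            raise ValueError(
                f"trace length {len(self.samples)} does not match design "
                f"({self.design.n_frames} frames)"
            )


@dataclass
class CorrectedTrace:
    """Baseline-corrected trace; ``samples = raw - baseline`` elementwise."""

    neuron_id: str
    session_id: str
    sample_rate_hz: float
    samples: np.ndarray
    baseline: np.ndarray
    design: SessionDesign
    window_len_s: float
    low_fraction: float


@dataclass(frozen=True)
class EpochPair:
    """Frame indices of a rise run and the decay that follows it."""

    rise_start: int
    rise_end: int
    decay_end: int
    truncated: bool = False

    def __post_init__(self) -> None:
        if not (self.rise_start < self.rise_end <= self.decay_end):
            raise ValueError("need rise_start < rise_end <= decay_end")


@dataclass(frozen=True)
class TransientModelParams:
    """Parameters of the rise-decay product kernel (all strictly positive)."""

    alpha_p: float
    tau_g: float
    tau_d: float
    t0: float = 0.0

    def validate(self) -> "TransientModelParams":
        if self.alpha_p <= 0 or self.tau_g <= 0 or self.tau_d <= 0:
            raise ValueError("alpha_p, tau_g, tau_d must be strictly positive")
        return self


@dataclass
class TransientEvent:
    """One fitted transient with its quality metrics."""

    params: TransientModelParams
    onset_s: float
    peak_amp: float
    area: float
    rmse: float
    accepted: bool = True
    reason: str = ""
    seg_start: int = 0          # frame index of the fitted segment
    seg_stop: int = 0


@dataclass
class TransientTrain:
    """Sorted transient onset times (session seconds) for one neuron."""

    neuron_id: str
    session_id: str
    onsets_s: np.ndarray

    def __post_init__(self) -> None:
        self.onsets_s = np.asarray(self.onsets_s, dtype=float)
        if np.any(np.diff(self.onsets_s) <= 0):
            raise ValueError("onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.onsets_s)


# ---------------------------------------------------------------------------
# kernel


def eval_kernel(params: TransientModelParams, t: np.ndarray | float) -> np.ndarray:
    """Evaluate the transient kernel at times ``t`` (seconds).

    The decay exponent is capped so that far-left tails (where the logistic
    underflows to exactly zero) do not turn into 0*inf.
    """
    u = np.asarray(t, dtype=float) - params.t0
    e = np.exp(np.minimum(-u / params.tau_d, 700.0))
    return params.alpha_p * expit(u / params.tau_g) * e


def _kernel_curve(params: TransientModelParams, t0_grid: np.ndarray) -> np.ndarray:
    return eval_kernel(params, t0_grid)


def kernel_peak_time(params: TransientModelParams) -> float:
    """Time of the kernel maximum (closed form)."""
    r = params.tau_d / params.tau_g
    if r <= 1:
        return params.t0  # degenerate: decay faster than rise
    # d/du log f = (1-s)/tau_g - 1/tau_d = 0  with  s = expit(u/tau_g)
    return params.t0 + params.tau_g * np.log(r - 1.0)


def kernel_onset(params: TransientModelParams, dt: float = 0.005) -> float:
    """Half-rise time: earliest time on the rising limb where the kernel
    reaches half of its own maximum."""
    tp = kernel_peak_time(params)
    lo = params.t0 - 12.0 * params.tau_g
    grid = np.arange(lo, tp + dt, dt)
    y = eval_kernel(params, grid)
    half = 0.5 * y[-1]
    above = np.nonzero(y >= half)[0]
    i = int(above[0])
    if i == 0:
        return float(grid[0])
    # linear interpolation between the bracketing grid points
    t1, t2 = grid[i - 1], grid[i]
    y1, y2 = y[i - 1], y[i]
    return float(t1 + (half - y1) / (y2 - y1) * (t2 - t1))


# ---------------------------------------------------------------------------
# baseline correction


def _lowmean_baseline(x: np.ndarray, W: int, low_fraction: float) -> np.ndarray:
    """Per-frame mean of the lowest ``ceil(low_fraction*W)`` samples in a
    centred window of ``W`` frames, truncated at the segment edges."""
    n = len(x)
    if W > n:
        raise DesignError("baseline window longer than recorded segment")
    half = W // 2
    out = np.empty(n)
    # interior: full windows, vectorised partition
    k_full = int(np.ceil(low_fraction * W))
    if n >= W:
        view = sliding_window_view(x, W)
        part = np.partition(view, k_full - 1, axis=1)[:, :k_full]
        out[half : half + len(view)] = part.mean(axis=1)
    # edges: truncated windows
    for i in range(half):
        lo, hi = 0, min(n, i + (W - half))
        k = int(np.ceil(low_fraction * (hi - lo)))
        out[i] = np.partition(x[lo:hi], k - 1)[:k].mean()
    for i in range(half + max(0, n - W + 1), n):
        lo, hi = max(0, i - half), n
        k = int(np.ceil(low_fraction * (hi - lo)))
        out[i] = np.partition(x[lo:hi], k - 1)[:k].mean()
    return out


def baseline_correct(
    trace: RawTrace,
    window_len_s: float = 30.0,
    low_fraction: float = 0.2,
) -> CorrectedTrace:
    """Subtract a sliding lowest-``low_fraction`` running mean.

    The window never spans recording gaps: each recorded window is corrected
    independently.  Edge frames use the truncated window.
    """
    if not 0 < low_fraction < 1:
        raise ValueError("low_fraction must lie in (0, 1)")
    fs = trace.sample_rate_hz
    if window_len_s < 10.0 / fs:
        raise ValueError("baseline window must cover at least 10 frames")
    W = int(round(window_len_s * fs))
    baseline = np.empty_like(trace.samples)
    for seg in trace.design.segment_slices():
        baseline[seg] = _lowmean_baseline(trace.samples[seg], W, low_fraction)
    return CorrectedTrace(
        neuron_id=trace.neuron_id,
        session_id=trace.session_id,
        sample_rate_hz=fs,
        samples=trace.samples - baseline,
        baseline=baseline,
        design=trace.design,
        window_len_s=window_len_s,
        low_fraction=low_fraction,
    )


# ---------------------------------------------------------------------------
# epoch detection


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open ``[start, stop)`` index pairs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    stops = list(np.nonzero(d == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(mask))
    return list(zip(starts, stops))


def _smooth_diff(x: np.ndarray, w: int) -> np.ndarray:
    """Centred boxcar (width ``w``) of the first difference of ``x``."""
    d = np.diff(x)
    if w <= 1:
        return d
    kernel = np.ones(w) / w
    return np.convolve(d, kernel, mode="same")


def _running_median(x: np.ndarray, w: int) -> np.ndarray:
    """Centred running median (edges use the nearest full window)."""
    from scipy.ndimage import median_filter

    return median_filter(x, size=w, mode="nearest")


def _split_runs(
    d: np.ndarray, runs: list[tuple[int, int]], prominence: float
) -> list[tuple[int, int]]:
    """Split derivative runs that contain several prominent peaks
    (overlapping transients whose rises merge into one run)."""
    from scipy.signal import find_peaks

    out: list[tuple[int, int]] = []
    for a, b in runs:
        seg = d[a:b]
        peaks, _ = find_peaks(seg, prominence=prominence)
        if len(peaks) < 2:
            out.append((a, b))
            continue
        cuts = [a]
        for p0, p1 in zip(peaks[:-1], peaks[1:]):
            cuts.append(a + p0 + int(np.argmin(seg[p0:p1])) + 1)
        cuts.append(b)
        out.extend((c0, c1) for c0, c1 in zip(cuts[:-1], cuts[1:]) if c1 > c0)
    return out


def detect_epochs(
    trace: CorrectedTrace,
    k_rise: float = 2.5,
    k_fall: float = 2.5,
    min_len_s: float = 0.2,
    rise_smooth_s: float = 0.2,
    fall_smooth_s: float = 1.0,
    allow_truncated: bool = True,
) -> list[EpochPair]:
    """Find rise/decay epoch pairs by thresholding smoothed derivatives.

    The first difference of the corrected trace is boxcar-smoothed at two
    scales: a sharp one for the fast rise and a longer one for the slow decay
    (whose per-frame increments are otherwise buried in noise at 10 Hz).
    Each stream is thresholded at ``k * sigma``; the noise scale is the
    1.4826*MAD of the unsmoothed derivative, divided by the boxcar width to
    propagate it to each smoothed stream (estimating it on the smoothed
    streams directly would absorb transient structure and inflate with event
    rate).  Runs shorter than ``min_len_s`` are dropped, and rise runs
    containing several prominent derivative peaks are split at the
    intervening minima (overlapping transients).  Each rise is paired with
    the nearest subsequent fall that starts before the next rise; when the
    next transient interrupts the decay (``allow_truncated``), the epoch is
    cut at the next rise start instead of being discarded.
    """
    if k_rise <= 0 or k_fall <= 0:
        raise ValueError("thresholds must be positive")
    fs = trace.sample_rate_hz
    min_run = max(1, int(round(min_len_s * fs)))
    wr = max(1, int(round(rise_smooth_s * fs)))
    wf = max(1, int(round(fall_smooth_s * fs)))
    pairs: list[EpochPair] = []
    for seg in trace.design.segment_slices():
        x = trace.samples[seg]
        if len(x) < 3:
            continue
        # noise scale of the first difference, estimated from the second
        # difference (insensitive to the locally linear decay limbs that
        # shift the first-difference bulk at high event rates)
        sigma_d1 = median_abs_deviation(np.diff(x, n=2), scale="normal") / np.sqrt(3.0)
        if sigma_d1 == 0:
            continue
        dr = _smooth_diff(x, wr)
        # remove the locally constant trend a slow decay imposes on the
        # derivative, so a rise riding on the previous transient's decay is
        # judged against its local slope rather than zero
        dr = dr - _running_median(dr, max(3, 2 * wf + 1))
        df = _smooth_diff(x, wf)
        sr = sigma_d1 / wr
        sf = sigma_d1 / wf
        # a boxcar of width w already aggregates w frames of signal change,
        # so the minimum run length is counted net of the smoothing span;
        # runs shorter than the full min_run must additionally clear a higher
        # peak threshold (keeps single-sample noise crossings out)
        min_r = max(1, min_run - (wr - 1))
        min_f = max(1, min_run - (wf - 1))
        strong = 1.2 * k_rise * sr
        rises = [
            r
            for r in _runs(dr > k_rise * sr)
            if r[1] - r[0] >= min_run
            or (r[1] - r[0] >= min_r and dr[r[0] : r[1]].max() > strong)
        ]
        rises = _split_runs(dr, rises, prominence=2.0 * sr)
        falls = [r for r in _runs(df < -k_fall * sf) if r[1] - r[0] >= min_f]
        if not rises:
            continue
        fall_starts = np.array([a for a, _ in falls], dtype=int)
        for i, (rs, re) in enumerate(rises):
            nxt = rises[i + 1][0] if i + 1 < len(rises) else len(x)
            # falls starting at/after the rise end
            j = np.searchsorted(fall_starts, re, side="left")
            decay_end = None
            truncated = False
            if j < len(falls) and falls[j][0] < nxt:
                decay_end = min(falls[j][1], nxt)
            elif allow_truncated and j < len(falls) and nxt < len(x):
                # decay interrupted by the next transient
                decay_end = nxt
                truncated = True
            if decay_end is None:
                continue
            # diff index i sits between frames i and i+1
            rise_start = rs
            rise_end = re + 1
            decay_end_f = min(decay_end + 1, len(x))
            if rise_start < rise_end <= decay_end_f:
                pairs.append(
                    EpochPair(
                        rise_start=rise_start + seg.start,
                        rise_end=rise_end + seg.start,
                        decay_end=decay_end_f + seg.start,
                        truncated=truncated,
                    )
                )
    return pairs


# ---------------------------------------------------------------------------
# fitting


DEFAULT_REFERENCE = TransientModelParams(alpha_p=1.0, tau_g=0.1, tau_d=1.0, t0=0.0)


def _fit_kernel_ls(
    t: np.ndarray,
    y: np.ndarray,
    init: TransientModelParams,
    t0_bounds: tuple[float, float],
    max_nfev: int = 60,
    fixed_tau_g: float | None = None,
):
    """Bounded least-squares fit of the kernel with analytic Jacobian.

    With ``fixed_tau_g`` the growth constant is held at the reference value
    and only (alpha_p, tau_d, t0) are free: at 10 Hz the rise spans one or
    two frames and tau_g is not identifiable per event.  Returns
    ``(result, params)``.
    """

    def unpack(p):
        if fixed_tau_g is None:
            return p[0], p[1], p[2], p[3]
        return p[0], fixed_tau_g, p[1], p[2]

    def resid(p):
        a, tg, td, t0 = unpack(p)
        u = t - t0
        # cap the decay exponent: keeps trial points with tau_d << tau_g
        # finite without affecting any physically sensible fit
        return a * expit(u / tg) * np.exp(np.minimum(-u / td, 50.0)) - y

    def jac(p):
        a, tg, td, t0 = unpack(p)
        u = t - t0
        s = expit(u / tg)
        e = np.exp(np.minimum(-u / td, 50.0))
        f = a * s * e
        cols = {
            "a": s * e,
            "tg": f * (1.0 - s) * (-u / tg**2),
            "td": f * (u / td**2),
            "t0": f * (-(1.0 - s) / tg + 1.0 / td),
        }
        names = ["a", "tg", "td", "t0"] if fixed_tau_g is None else ["a", "td", "t0"]
        return np.stack([cols[n] for n in names], axis=1)

    amax = max(10.0 * np.max(np.abs(y)), 10.0 * init.alpha_p, 1e-3)
    # tau_d is weakly identified on short (truncated) segments: keep it
    # within a factor of 5 of the reference rather than letting it collapse
    td_lo = max(2e-2, init.tau_d / 5.0)
    td_hi = min(60.0, init.tau_d * 5.0)
    if fixed_tau_g is None:
        lb = [1e-8, 5e-3, td_lo, t0_bounds[0]]
        ub = [amax, 5.0, td_hi, t0_bounds[1]]
        x0 = [init.alpha_p, init.tau_g, init.tau_d, init.t0]
    else:
        lb = [1e-8, td_lo, t0_bounds[0]]
        ub = [amax, td_hi, t0_bounds[1]]
        x0 = [init.alpha_p, init.tau_d, init.t0]
    x0 = np.clip(x0, np.array(lb) + 1e-12, np.array(ub) - 1e-12)
    res = least_squares(
        resid, x0, jac=jac, bounds=(lb, ub), max_nfev=max_nfev, method="trf"
    )
    a, tg, td, t0 = unpack(res.x)
    return res, TransientModelParams(float(a), float(tg), float(td), float(t0))


def _lm_batch(
    Tm: np.ndarray,
    Ym: np.ndarray,
    mask: np.ndarray,
    x0: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    tau_g: float,
    n_iter: int = 40,
) -> tuple[np.ndarray, np.ndarray]:
    """Projected Levenberg-Marquardt over a batch of single-kernel fits.

    Parameters per event are ``(alpha_p, tau_d, t0)`` with ``tau_g`` shared
    (held at the reference value).  Returns the fitted parameter matrix and
    the per-event RMSE.  Numerically equivalent to the scipy per-event fit
    on well-posed segments (cross-checked in the test suite) but orders of
    magnitude faster on whole-session batches.
    """

    span = ub - lb

    def to_x(z):
        return lb + span * expit(z)

    def model_and_jac(z):
        x = to_x(z)
        a, td, t0 = x[:, 0:1], x[:, 1:2], x[:, 2:3]
        u = Tm - t0
        s = expit(u / tau_g)
        e = np.exp(np.minimum(-u / td, 50.0))
        f = a * s * e
        J = np.empty(Tm.shape + (3,))
        J[..., 0] = s * e
        J[..., 1] = f * (u / td**2)
        J[..., 2] = f * (-(1.0 - s) / tau_g + 1.0 / td)
        # chain rule for the bound-removing sigmoid reparametrisation
        sz = expit(z)
        J *= (span * sz * (1.0 - sz))[:, None, :]
        return f, J

    frac = np.clip((x0 - lb) / np.where(span > 0, span, 1.0), 1e-5, 1 - 1e-5)
    z = np.log(frac / (1.0 - frac))
    lam = np.full(len(z), 1e-2)
    f, J = model_and_jac(z)
    r = (f - Ym) * mask
    cost = (r**2).sum(axis=1)
    di = np.arange(3)
    for _ in range(n_iter):
        Jm = J * mask[..., None]
        JTJ = np.einsum("nlk,nlm->nkm", Jm, Jm)
        g = np.einsum("nlk,nl->nk", Jm, r)
        A = JTJ.copy()
        A[:, di, di] += lam[:, None] * np.maximum(JTJ[:, di, di], 1e-10) + 1e-12
        try:
            delta = -np.linalg.solve(A, g[..., None])[..., 0]
        except np.linalg.LinAlgError:
            A[:, di, di] += 1e-8
            delta = -np.linalg.solve(A, g[..., None])[..., 0]
        z_new = np.clip(z + delta, -30.0, 30.0)
        f_new, J_new = model_and_jac(z_new)
        r_new = (f_new - Ym) * mask
        cost_new = (r_new**2).sum(axis=1)
        better = cost_new < cost
        z[better] = z_new[better]
        r[better] = r_new[better]
        J[better] = J_new[better]
        cost[better] = cost_new[better]
        lam = np.where(better, lam / 3.0, lam * 2.5)
        if np.all(lam > 1e8):  # every event has stalled
            break
    rmse = np.sqrt(cost / np.maximum(mask.sum(axis=1), 1))
    return to_x(z), rmse


def fit_reference(
    trace: CorrectedTrace,
    pairs: Sequence[EpochPair],
    defaults: TransientModelParams | None = None,
) -> TransientModelParams:
    """Fit the peak-aligned average transient to get reference parameters.

    With fewer than three epoch pairs the configured defaults are returned
    (amplitude from the median epoch maximum when available).
    """
    fs = trace.sample_rate_hz
    defaults = defaults or DEFAULT_REFERENCE
    seg_maxima = [
        float(trace.samples[p.rise_start : p.decay_end].max()) for p in pairs
    ]
    # restrict the average to clearly supra-noise epochs, so sparse trains
    # whose candidate list is noise-dominated do not corrupt the reference
    sigma_n = (
        median_abs_deviation(np.diff(trace.samples, n=2), scale="normal")
        / np.sqrt(6.0)
    )
    strong = [p for p, m in zip(pairs, seg_maxima) if m >= 5.0 * sigma_n]
    if len(strong) < 3:
        logger.info(
            "%s/%s: %d strong epoch pairs; falling back to default reference",
            trace.neuron_id, trace.session_id, len(strong),
        )
        amp = np.median(seg_maxima) / 0.75 if seg_maxima else defaults.alpha_p
        return TransientModelParams(float(amp), defaults.tau_g, defaults.tau_d, 0.0)
    pairs = strong

    pre = int(round(1.0 * fs))
    post = int(round(3.0 * fs))
    stack = np.full((len(pairs), pre + post + 1), np.nan)
    for i, p in enumerate(pairs):
        peak = p.rise_start + int(
            np.argmax(trace.samples[p.rise_start : p.decay_end])
        )
        lo, hi = peak - pre, peak + post + 1
        a, b = max(lo, 0), min(hi, len(trace.samples))
        stack[i, a - lo : (a - lo) + (b - a)] = trace.samples[a:b]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        avg = np.nanmean(stack, axis=0)
    ok = np.isfinite(avg)
    t = (np.arange(pre + post + 1) - pre) / fs
    init = TransientModelParams(
        alpha_p=max(float(np.nanmax(avg)) / 0.75, 1e-6),
        tau_g=defaults.tau_g,
        tau_d=defaults.tau_d,
        t0=-0.1,
    )
    res, params = _fit_kernel_ls(t[ok], avg[ok], init, (t[0], t[-1]))
    if not res.success or params.tau_d < params.tau_g:
        return TransientModelParams(init.alpha_p, defaults.tau_g, defaults.tau_d, 0.0)
    return params


def _finalize_event(
    params: TransientModelParams,
    rmse: float,
    t: np.ndarray,
    seg_start: int,
    seg_stop: int,
    fine_dt: float = 0.01,
    success: bool = True,
) -> TransientEvent:
    """Half-rise onset, peak and area from the fitted curve on a fine grid."""
    grid = np.arange(t[0], t[-1] + fine_dt, fine_dt)
    curve = eval_kernel(params, grid)
    ipk = int(np.argmax(curve))
    peak = float(curve[ipk])
    half = 0.5 * peak
    rising = curve[: ipk + 1]
    above = np.nonzero(rising >= half)[0]
    if len(above) == 0 or above[0] == 0:
        onset = float(grid[0])
    else:
        i = int(above[0])
        y1, y2 = rising[i - 1], rising[i]
        onset = float(grid[i - 1] + (half - y1) / (y2 - y1) * fine_dt)
    area = float(np.trapezoid(curve, grid))
    return TransientEvent(
        params=params,
        onset_s=onset,
        peak_amp=peak,
        area=area,
        rmse=rmse,
        accepted=success,
        reason="" if success else "fit_failed",
        seg_start=seg_start,
        seg_stop=seg_stop,
    )


def fit_transient(
    trace: CorrectedTrace,
    pair: EpochPair,
    init: TransientModelParams,
    margin_pre_s: float = 1.0,
    margin_post_factor: float = 3.0,
    seg_bounds: tuple[int, int] | None = None,
    free_tau_g: bool = False,
) -> TransientEvent:
    """Fit one transient on its epoch plus margins.

    The fitted segment extends ``margin_pre_s`` before the rise and
    ``margin_post_factor * tau_d`` (reference) after the decay end, clipped
    to ``seg_bounds`` (used to avoid bleeding into neighbouring epochs) and
    to the recording-window edges.  By default ``tau_g`` is held at the
    reference value (``free_tau_g=True`` releases it).  ``onset_s`` is the
    half-rise time of the fitted curve and ``area`` its integral over the
    segment.
    """
    fs = trace.sample_rate_hz
    times = trace.design.frame_times()
    # locate the enclosing recording window
    seg = next(
        s for s in trace.design.segment_slices()
        if s.start <= pair.rise_start < s.stop
    )
    lo = pair.rise_start - int(round(margin_pre_s * fs))
    hi = pair.decay_end + int(round(margin_post_factor * init.tau_d * fs))
    lo, hi = max(lo, seg.start), min(hi, seg.stop)
    if seg_bounds is not None:
        lo, hi = max(lo, seg_bounds[0]), min(hi, seg_bounds[1])
    t = times[lo:hi]
    y = trace.samples[lo:hi]
    if len(t) < 4:  # squeezed between neighbours: nothing to fit
        return TransientEvent(
            params=TransientModelParams(1e-6, init.tau_g, init.tau_d, float(times[lo])),
            onset_s=float(times[lo]),
            peak_amp=0.0, area=0.0, rmse=0.0,
            accepted=False, reason="segment_too_short",
            seg_start=lo, seg_stop=hi,
        )
    peak_i = pair.rise_start + int(np.argmax(trace.samples[pair.rise_start : pair.decay_end]))
    t_peak = times[peak_i]
    r = init.tau_d / max(init.tau_g, 1e-6)
    t0_init = t_peak - (init.tau_g * np.log(r - 1.0) if r > 1 else 0.0)
    start = TransientModelParams(
        alpha_p=max(float(y.max()) / 0.75, 1e-6),
        tau_g=init.tau_g,
        tau_d=init.tau_d,
        t0=float(np.clip(t0_init, t[0], t[-1])),
    )
    res, params = _fit_kernel_ls(
        t, y, start, (float(t[0]), float(t[-1])),
        fixed_tau_g=None if free_tau_g else init.tau_g,
    )
    rmse = float(np.sqrt(np.mean(res.fun**2)))
    return _finalize_event(params, rmse, t, lo, hi, success=bool(res.success))


def _segment_bounds(
    trace: CorrectedTrace, pairs: Sequence[EpochPair], reference: TransientModelParams,
    margin_pre_s: float = 1.0, margin_post_factor: float = 3.0,
) -> list[tuple[int, int]]:
    """Per-pair fit-segment frame ranges: epoch plus margins, clipped to the
    recording window and to the neighbouring epochs."""
    fs = trace.sample_rate_hz
    segs = trace.design.segment_slices()
    out = []
    for i, p in enumerate(pairs):
        win = next(s for s in segs if s.start <= p.rise_start < s.stop)
        lo = p.rise_start - int(round(margin_pre_s * fs))
        hi = p.decay_end + int(round(margin_post_factor * reference.tau_d * fs))
        lo = max(lo, win.start, pairs[i - 1].decay_end if i > 0 else 0)
        hi = min(hi, win.stop, pairs[i + 1].rise_start if i + 1 < len(pairs) else len(trace.samples))
        out.append((lo, hi))
    return out


def fit_events(
    trace: CorrectedTrace,
    pairs: Sequence[EpochPair],
    reference: TransientModelParams | None = None,
    free_tau_g: bool = False,
) -> list[TransientEvent]:
    """Fit every epoch pair, splitting neighbouring segments between epochs.

    Uses the vectorised batch fitter (``tau_g`` held at the reference) unless
    ``free_tau_g`` requests full four-parameter per-event fits.
    """
    if not pairs:
        return []
    if reference is None:
        reference = fit_reference(trace, pairs)
    if free_tau_g:
        events = []
        for i, p in enumerate(pairs):
            lo = pairs[i - 1].decay_end if i > 0 else 0
            hi = pairs[i + 1].rise_start if i + 1 < len(pairs) else len(trace.samples)
            events.append(
                fit_transient(trace, p, reference,
                              seg_bounds=(max(lo, 0), hi), free_tau_g=True)
            )
        return events

    times = trace.design.frame_times()
    bounds = _segment_bounds(trace, pairs, reference)
    n = len(pairs)
    L = max(hi - lo for lo, hi in bounds)
    Tm = np.zeros((n, L))
    Ym = np.zeros((n, L))
    mask = np.zeros((n, L))
    x0 = np.empty((n, 3))
    lb = np.empty((n, 3))
    ub = np.empty((n, 3))
    short = np.zeros(n, dtype=bool)
    r = reference.tau_d / max(reference.tau_g, 1e-6)
    peak_lag = reference.tau_g * np.log(r - 1.0) if r > 1 else 0.0
    td_lo = max(2e-2, reference.tau_d / 5.0)
    td_hi = min(60.0, reference.tau_d * 5.0)
    for i, ((lo, hi), p) in enumerate(zip(bounds, pairs)):
        m = hi - lo
        if m < 4:
            short[i] = True
            continue
        Tm[i, :m] = times[lo:hi]
        Tm[i, m:] = times[hi - 1]
        Ym[i, :m] = trace.samples[lo:hi]
        mask[i, :m] = 1.0
        peak_i = p.rise_start + int(
            np.argmax(trace.samples[p.rise_start : p.decay_end])
        )
        ymax = float(trace.samples[lo:hi].max())
        x0[i] = [max(ymax / 0.75, 1e-6), reference.tau_d,
                 float(np.clip(times[peak_i] - peak_lag, times[lo], times[hi - 1]))]
        lb[i] = [1e-8, td_lo, times[lo]]
        ub[i] = [max(10.0 * abs(ymax), 10.0 * reference.alpha_p, 1e-3),
                 td_hi, times[hi - 1]]
    ok = ~short
    x = np.zeros((n, 3))
    rmse = np.zeros(n)
    if ok.any():
        x[ok], rmse[ok] = _lm_batch(
            Tm[ok], Ym[ok], mask[ok], x0[ok], lb[ok], ub[ok], reference.tau_g
        )
    events: list[TransientEvent] = []
    for i, (lo, hi) in enumerate(bounds):
        if short[i]:
            events.append(
                TransientEvent(
                    params=TransientModelParams(
                        1e-6, reference.tau_g, reference.tau_d, float(times[lo])
                    ),
                    onset_s=float(times[lo]), peak_amp=0.0, area=0.0, rmse=0.0,
                    accepted=False, reason="segment_too_short",
                    seg_start=lo, seg_stop=hi,
                )
            )
            continue
        params = TransientModelParams(
            float(x[i, 0]), reference.tau_g, float(x[i, 1]), float(x[i, 2])
        )
        events.append(
            _finalize_event(params, float(rmse[i]), times[lo:hi], lo, hi)
        )
    return events


def refine_reference(
    trace: CorrectedTrace,
    pairs: Sequence[EpochPair],
    events: Sequence[TransientEvent],
    fallback: TransientModelParams | None = None,
    max_events: int = 40,
    fine_dt: float = 0.02,
) -> TransientModelParams:
    """Second-pass reference from a ``t0``-realigned event average.

    The first-pass reference aligns epochs on their noisy peak sample, which
    smears the fast rise severalfold.  Realigning the largest events on
    their fitted ``t0`` (a continuous quantity) and averaging on a fine grid
    recovers nearly unbiased shape constants; the sharper reference in turn
    removes most of the half-rise onset bias.
    """
    fallback = fallback or DEFAULT_REFERENCE
    sigma_n = (
        median_abs_deviation(np.diff(trace.samples, n=2), scale="normal")
        / np.sqrt(6.0)
    )
    strong = [e for e in events if e.peak_amp >= 5.0 * sigma_n]
    if len(strong) < 3:
        return fallback
    times = trace.design.frame_times()
    order = np.argsort([-e.peak_amp for e in strong])[:max_events]
    grid = np.arange(-1.0, 3.0, fine_dt)
    stack = []
    for i in order:
        e = strong[int(i)]
        sl = slice(e.seg_start, e.seg_stop)
        u = times[sl] - e.params.t0
        m = (u >= grid[0]) & (u <= grid[-1])
        if m.sum() < 10:
            continue
        stack.append(
            np.interp(grid, u[m], trace.samples[sl][m], left=np.nan, right=np.nan)
        )
    if len(stack) < 3:
        return fallback
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        avg = np.nanmean(np.asarray(stack), axis=0)
    ok = np.isfinite(avg)
    init = TransientModelParams(
        max(float(np.nanmax(avg)), 1e-6) / 0.75, 0.1, 1.0, 0.0
    )
    res, params = _fit_kernel_ls(grid[ok], avg[ok], init, (float(grid[0]), float(grid[-1])))
    if not res.success or params.tau_d < params.tau_g:
        return fallback
    return TransientModelParams(params.alpha_p, params.tau_g, params.tau_d, 0.0)


# ---------------------------------------------------------------------------
# cleaning, reconstruction, train extraction


def quiet_sigma(trace: CorrectedTrace, pairs: Sequence[EpochPair]) -> float:
    """SD of the corrected trace outside all detected epochs.

    On dense traces with too few quiet frames, falls back to the
    second-difference robust noise estimate (density-independent).
    """
    mask = np.ones(len(trace.samples), dtype=bool)
    fs = trace.sample_rate_hz
    pad = int(round(0.5 * fs))
    for p in pairs:
        mask[max(0, p.rise_start - pad) : min(len(mask), p.decay_end + pad)] = False
    if mask.sum() < 0.1 * len(mask):
        return float(
            median_abs_deviation(np.diff(trace.samples, n=2), scale="normal")
            / np.sqrt(6.0)
        )
    return float(np.std(trace.samples[mask]))


def clean_fits(
    events: Sequence[TransientEvent],
    trace: CorrectedTrace | None = None,
    pairs: Sequence[EpochPair] | None = None,
    min_amp_sigma: float = 3.5,
    tau_d_limits: tuple[float, float] = (0.1, 20.0),
    rmse_frac: float = 0.5,
    sigma_quiet: float | None = None,
) -> list[TransientEvent]:
    """Flag implausible fits; nothing is deleted, only ``accepted`` is set.

    Rejection rules: peak amplitude below ``min_amp_sigma`` quiet-period SDs;
    decay faster than rise (``tau_d < tau_g``); ``tau_d`` outside
    ``tau_d_limits``; RMSE above ``rmse_frac`` of the peak amplitude.
    """
    if sigma_quiet is None:
        if trace is None:
            raise ValueError("need either sigma_quiet or the corrected trace")
        sigma_quiet = quiet_sigma(trace, pairs or [])
    out = []
    for ev in events:
        reasons = [] if ev.accepted else [ev.reason]
        p = ev.params
        if ev.peak_amp < min_amp_sigma * sigma_quiet:
            reasons.append("low_amplitude")
        if p.tau_d < p.tau_g:
            reasons.append("no_fast_rise_slow_decay")
        if not tau_d_limits[0] <= p.tau_d <= tau_d_limits[1]:
            reasons.append("tau_d_out_of_range")
        if ev.rmse > rmse_frac * max(ev.peak_amp, 1e-12):
            reasons.append("poor_fit")
        out.append(
            replace(ev, accepted=not reasons, reason=";".join(r for r in reasons if r))
        )
    return out


def reconstruct(
    events: Sequence[TransientEvent], trace: CorrectedTrace
) -> tuple[np.ndarray, dict]:
    """Sum accepted fitted kernels on the session frame grid.

    Returns the reconstructed trace and statistics: R-squared against the
    corrected trace (``None`` with no accepted events) and each accepted
    event's relative area contribution.
    """
    times = trace.design.frame_times()
    recon = np.zeros_like(trace.samples)
    accepted = [e for e in events if e.accepted]
    for ev in accepted:
        sl = slice(ev.seg_start, ev.seg_stop)
        recon[sl] += eval_kernel(ev.params, times[sl])
    if accepted:
        ss_res = float(np.sum((trace.samples - recon) ** 2))
        ss_tot = float(np.sum((trace.samples - trace.samples.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else None
        total_area = sum(e.area for e in accepted)
        contributions = [e.area / total_area for e in accepted]
    else:
        r2 = None
        contributions = []
    return recon, {"r_squared": r2, "contributions": contributions}


def to_train(
    events: Sequence[TransientEvent],
    neuron_id: str,
    session_id: str,
    design: SessionDesign,
) -> TransientTrain:
    """Sorted accepted half-rise onsets; onsets within one frame are merged,
    keeping the event with the larger area."""
    acc = sorted((e for e in events if e.accepted), key=lambda e: e.onset_s)
    dt = 1.0 / design.sample_rate_hz
    merged: list[TransientEvent] = []
    for ev in acc:
        if merged and ev.onset_s - merged[-1].onset_s <= dt:
            if ev.area > merged[-1].area:
                merged[-1] = ev
        else:
            merged.append(ev)
    onsets = np.array([e.onset_s for e in merged])
    onsets = onsets[design.contains(onsets)]
    return TransientTrain(neuron_id=neuron_id, session_id=session_id, onsets_s=onsets)


# ---------------------------------------------------------------------------
# one-call driver


@dataclass
class DetectorConfig:
    window_len_s: float = 30.0
    low_fraction: float = 0.2
    k_rise: float = 2.5
    k_fall: float = 2.5
    min_len_s: float = 0.2
    rise_smooth_s: float = 0.2
    fall_smooth_s: float = 1.0
    min_amp_sigma: float = 3.5
    tau_d_limits: tuple[float, float] = (0.1, 20.0)
    rmse_frac: float = 0.5
    refine_reference: bool = True


def detect_transients(
    trace: RawTrace, config: DetectorConfig | None = None
) -> tuple[TransientTrain, list[TransientEvent], CorrectedTrace]:
    """Full chain: baseline correction, epoch detection, fitting, cleaning."""
    cfg = config or DetectorConfig()
    corrected = baseline_correct(trace, cfg.window_len_s, cfg.low_fraction)
    pairs = detect_epochs(
        corrected,
        k_rise=cfg.k_rise,
        k_fall=cfg.k_fall,
        min_len_s=cfg.min_len_s,
        rise_smooth_s=cfg.rise_smooth_s,
        fall_smooth_s=cfg.fall_smooth_s,
    )
    reference = fit_reference(corrected, pairs)
    events = fit_events(corrected, pairs, reference)
    if cfg.refine_reference and pairs:
        refined = refine_reference(corrected, pairs, events, fallback=reference)
        if refined is not reference:
            events = fit_events(corrected, pairs, refined)
    events = clean_fits(
        events,
        corrected,
        pairs,
        min_amp_sigma=cfg.min_amp_sigma,
        tau_d_limits=cfg.tau_d_limits,
        rmse_frac=cfg.rmse_frac,
    )
    train = to_train(events, trace.neuron_id, trace.session_id, trace.design)
    return train, events, corrected
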