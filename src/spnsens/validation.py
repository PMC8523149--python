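"""Ground-truth validation suite: the benchmarks the package is judged by.

Each function generates its own synthetic inputs from a seed, runs the
relevant part of the analysis, and returns a dict of plain numbers.  The
test suite asserts on these numbers; ``scripts/acceptance.py`` reports them.
Problem sizes are arguments so tests and the acceptance script can choose
their own scale.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np

from . import synth
from .design import SessionDesign
from .movement import label_movement
from .responsiveness import (
    enumerate_null,
    fisher_exact,
    label_neuron,
    shuffle_null,
    wilcoxon_signed_rank,
)
from .transients import (
    TransientModelParams,
    TransientTrain,
    _finalize_event,
    _fit_kernel_ls,
    detect_transients,
    eval_kernel,
    kernel_onset,
)

__all__ = [
    "kernel_agreement",
    "fit_recovery",
    "detector_operating_point",
    "null_calibration",
    "power_curve",
    "shuffle_oracle",
    "movement_calibration",
    "movement_power",
    "movement_independence",
    "fisher_oracle",
    "wilcoxon_oracle",
    "photometry_recovery",
    "cohort_dichotomy",
]


# ---------------------------------------------------------------------------
# kernel


def _kernel_brute(alpha_p, tau_g, tau_d, t0, t):
    """Independent scalar evaluation of the transient kernel (math only)."""
    u = t - t0
    return alpha_p / (1.0 + math.exp(-u / tau_g)) * math.exp(-u / tau_d)


def kernel_agreement(n_grid: int = 1000) -> dict:
    """Midpoint identity f(t0)=alpha_p/2 and agreement with the brute-force
    evaluation on a grid, in max relative error."""
    p = TransientModelParams(alpha_p=2.3, tau_g=0.11, tau_d=0.9, t0=0.4)
    mid = float(eval_kernel(p, p.t0))
    mid_err = abs(mid - p.alpha_p / 2.0) / (p.alpha_p / 2.0)
    t = np.linspace(p.t0 - 2.0, p.t0 + 6.0, n_grid)
    fast = eval_kernel(p, t)
    brute = np.array([_kernel_brute(p.alpha_p, p.tau_g, p.tau_d, p.t0, x) for x in t])
    denom = np.maximum(np.abs(brute), 1e-300)
    grid_err = float(np.max(np.abs(fast - brute) / denom))
    return {"midpoint_rel_err": mid_err, "grid_max_rel_err": grid_err, "n": n_grid}


# ---------------------------------------------------------------------------
# per-event fit recovery


def fit_recovery(n: int = 200, seed: int = 0) -> dict:
    """Recovery of amplitude, decay constant and half-rise onset from noisy
    isolated transients (noise SD = 0.1 x peak)."""
    rng = np.random.default_rng(seed)
    errs_a, errs_td, errs_on = [], [], []
    for _ in range(n):
        a = rng.uniform(1.0, 5.0)
        tg = rng.uniform(0.05, 0.2)
        td = rng.uniform(0.5, 2.0)
        p = TransientModelParams(a, tg, td, 0.0)
        t = np.arange(-2.0, 6.0, 0.1)
        clean = eval_kernel(p, t)
        y = clean + rng.normal(0.0, 0.1 * clean.max(), len(t))
        init = TransientModelParams(max(float(y.max()), 1e-3) / 0.75, 0.1, 1.0, 0.0)
        res, params = _fit_kernel_ls(t, y, init, (float(t[0]), float(t[-1])))
        ev = _finalize_event(
            params, float(np.sqrt(np.mean(res.fun**2))), t, 0, len(t)
        )
        errs_a.append(abs(params.alpha_p - a) / a)
        errs_td.append(abs(params.tau_d - td) / td)
        errs_on.append(abs(ev.onset_s - kernel_onset(p)))
    return {
        "alpha_median_rel_err": float(np.median(errs_a)),
        "tau_d_median_rel_err": float(np.median(errs_td)),
        "onset_median_abs_err_s": float(np.median(errs_on)),
        "n": n,
    }


# ---------------------------------------------------------------------------
# detector operating point


def _rate_draw(rng: np.random.Generator, lo: float = 0.05, hi: float = 0.5) -> float:
    """Log-uniform rate draw: transient frequencies are highly variable
    across neurons and heavy-tailed rate heterogeneity is the realistic
    default."""
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def detector_operating_point(
    n_neurons: int = 500, n_noise_sessions: int = 10, seed: int = 0
) -> dict:
    """End-to-end event-count recovery at SNR 10 plus the pure-noise false
    event rate (per 300 s, after fit cleaning)."""
    design = SessionDesign()
    rng = np.random.default_rng(seed)
    rel = []
    for i in range(n_neurons):
        rate = _rate_draw(rng)
        spec = synth.SynthNeuronSpec(
            neuron_id=f"n{i}", rate_pre_hz=rate, rate_post_hz=rate,
            noise_sd=0.153, drift_amp=0.3,
        )
        train = synth.gen_event_train(spec, design, rng)
        raw = synth.render_trace(train, spec, design, rng)
        detected, _, _ = detect_transients(raw)
        rel.append(abs(len(detected) - len(train)) / max(len(train), 1))
    # pure-noise sessions
    false_events = 0
    noise_spec = synth.SynthNeuronSpec(
        neuron_id="noise", rate_pre_hz=0.0, rate_post_hz=0.0,
        noise_sd=0.153, drift_amp=0.3,
    )
    for _ in range(n_noise_sessions):
        empty = TransientTrain("noise", design.session_id, np.array([]))
        raw = synth.render_trace(empty, noise_spec, design, rng)
        detected, _, _ = detect_transients(raw)
        false_events += len(detected)
    per_300s = false_events / (n_noise_sessions * design.total_recorded_s / 300.0)
    rel = np.asarray(rel)
    return {
        "frac_within_10pct": float((rel <= 0.10).mean()),
        "median_rel_count_err": float(np.median(rel)),
        "noise_false_events_per_300s": float(per_300s),
        "n": n_neurons,
    }


# ---------------------------------------------------------------------------
# responsiveness null calibration and power


def null_calibration(
    n_neurons: int = 1000, n_shuffles: int = 1000,
    rate_hz: float = 0.1, seed: int = 0,
) -> dict:
    """False-flag rates of the interval-shuffle classifier on homogeneous
    Poisson neurons (nominal 0.01 per direction)."""
    design = SessionDesign()
    rng = np.random.default_rng(seed)
    counts = {"elevated": 0, "reduced": 0, "none": 0, "skipped": 0}
    for i in range(n_neurons):
        spec = synth.SynthNeuronSpec(
            neuron_id=f"n{i}", rate_pre_hz=rate_hz, rate_post_hz=rate_hz
        )
        train = synth.gen_event_train(spec, design, rng)
        lab = label_neuron(train, design, n_shuffles=n_shuffles, seed=rng)
        if lab.reason == "too_few_events":
            counts["skipped"] += 1
            continue
        counts[lab.label] += 1
    n_eff = n_neurons - counts["skipped"]
    return {
        "elevated_rate": counts["elevated"] / max(n_eff, 1),
        "reduced_rate": counts["reduced"] / max(n_eff, 1),
        "n": n_eff,
        "n_shuffles": n_shuffles,
    }


def power_curve(
    ratios=(1.0, 1.5, 2.0, 3.0),
    n_neurons: int = 250,
    n_shuffles: int = 1000,
    rate_pre: float = 0.1,
    seed: int = 0,
) -> dict:
    """P(elevated) as a function of the post/pre rate ratio."""
    design = SessionDesign()
    rng = np.random.default_rng(seed)
    out = {}
    for ratio in ratios:
        hits = 0
        n_eff = 0
        for i in range(n_neurons):
            spec = synth.SynthNeuronSpec(
                neuron_id=f"n{i}",
                rate_pre_hz=rate_pre,
                rate_post_hz=rate_pre * ratio,
                true_label="elevated" if ratio > 1 else "none",
            )
            train = synth.gen_event_train(spec, design, rng)
            lab = label_neuron(train, design, n_shuffles=n_shuffles, seed=rng)
            if lab.reason == "too_few_events":
                continue
            n_eff += 1
            hits += lab.label == "elevated"
        out[float(ratio)] = hits / max(n_eff, 1)
    return {"p_elevated": out, "n": n_neurons, "n_shuffles": n_shuffles}


def shuffle_oracle(n_events: int = 5, n_shuffles: int = 20_000, seed: int = 0) -> dict:
    """Sampled shuffle null vs full enumeration of all interval permutations
    for a tiny train: support match and moment agreement."""
    design = SessionDesign()
    rng = np.random.default_rng(seed)
    rec = np.sort(rng.uniform(0.0, design.total_recorded_s - 1.0, size=n_events))
    onsets = design.to_session(rec)
    train = TransientTrain("oracle", design.session_id, np.sort(onsets))
    exact = enumerate_null(train, design)
    sampled = shuffle_null(train, design, n_shuffles=n_shuffles, seed=seed)
    support_exact = set(np.round(exact, 9))
    support_sampled = set(np.round(sampled.values, 9))
    return {
        "support_covered": float(support_sampled <= support_exact),
        "support_fraction_seen": len(support_sampled & support_exact)
        / len(support_exact),
        "mean_abs_diff": abs(float(exact.mean()) - float(sampled.values.mean())),
        "sd_abs_diff": abs(float(exact.std()) - float(sampled.values.std())),
        "n_permutations": int(math.factorial(n_events)),
    }


# ---------------------------------------------------------------------------
# movement classifier


def _movement_cohort_neuron(design, rng, coupling, gain, rate_hz=0.1):
    spec = synth.SynthNeuronSpec(
        neuron_id="m", rate_pre_hz=rate_hz, rate_post_hz=rate_hz,
        velocity_coupling=coupling, coupling_gain=gain,
    )
    train = synth.gen_event_train(spec, design, rng)
    vel = synth.gen_velocity(design, train, coupling=coupling, gain=gain, seed=rng)
    return train, vel


def movement_calibration(
    n_neurons: int = 1000, n_shifts: int = 1000, seed: int = 0
) -> dict:
    """False-flag rate per tail with velocity uncoupled from events
    (nominal 0.05 per tail)."""
    design = SessionDesign()
    rng = np.random.default_rng(seed)
    heightened = lowered = n_eff = 0
    for _ in range(n_neurons):
        train, vel = _movement_cohort_neuron(design, rng, "none", 0.0)
        lab, _ = label_movement(vel, train, design, n_shuffles=n_shifts, seed=rng)
        if lab.reason:
            continue
        n_eff += 1
        heightened += lab.label == "heightened"
        lowered += lab.label == "lowered"
    return {
        "heightened_rate": heightened / max(n_eff, 1),
        "lowered_rate": lowered / max(n_eff, 1),
        "n": n_eff,
        "n_shifts": n_shifts,
    }


def movement_power(
    n_neurons: int = 200, n_shifts: int = 1000, gain: float = 6.0, seed: int = 0
) -> dict:
    """Detection rate with strong event-locked velocity bumps, per sign."""
    design = SessionDesign()
    rng = np.random.default_rng(seed)
    out = {}
    for coupling, target in (("heightened", "heightened"), ("lowered", "lowered")):
        hit = n_eff = 0
        for _ in range(n_neurons // 2):
            train, vel = _movement_cohort_neuron(design, rng, coupling, gain)
            lab, _ = label_movement(vel, train, design, n_shuffles=n_shifts, seed=rng)
            if lab.reason:
                continue
            n_eff += 1
            hit += lab.label == target
        out[coupling] = hit / max(n_eff, 1)
    out["correct_sign_rate"] = float(np.mean([out["heightened"], out["lowered"]]))
    out["n"] = n_neurons
    return out


def movement_independence(
    n_neurons: int = 600,
    n_shifts: int = 600,
    n_shuffles: int = 600,
    frac_responsive: float = 0.3,
    frac_coupled: float = 0.3,
    gain: float = 6.0,
    seed: int = 0,
) -> dict:
    """With cocaine-responsiveness and velocity-coupling assigned
    independently, the movement-coding fraction within the cocaine-responsive
    subset should match the marginal fraction."""
    design = SessionDesign()
    rng = np.random.default_rng(seed)
    mov_flags, resp_flags = [], []
    for i in range(n_neurons):
        responsive = rng.random() < frac_responsive
        coupled = rng.random() < frac_coupled
        spec = synth.SynthNeuronSpec(
            neuron_id=f"n{i}",
            rate_pre_hz=0.1,
            rate_post_hz=0.3 if responsive else 0.1,
            true_label="elevated" if responsive else "none",
            velocity_coupling="heightened" if coupled else "none",
            coupling_gain=gain if coupled else 0.0,
        )
        train = synth.gen_event_train(spec, design, rng)
        vel = synth.gen_velocity(
            design, train,
            coupling=spec.velocity_coupling, gain=spec.coupling_gain, seed=rng,
        )
        rlab = label_neuron(train, design, n_shuffles=n_shuffles, seed=rng)
        mlab, _ = label_movement(vel, train, design, n_shuffles=n_shifts, seed=rng)
        resp_flags.append(rlab.label != "none")
        mov_flags.append(mlab.label == "heightened")
    mov = np.array(mov_flags)
    resp = np.array(resp_flags)
    marginal = float(mov.mean())
    within = float(mov[resp].mean()) if resp.any() else float("nan")
    n_resp = int(resp.sum())
    se = math.sqrt(max(marginal * (1 - marginal), 1e-12) / max(n_resp, 1))
    return {
        "marginal_fraction": marginal,
        "fraction_within_responsive": within,
        "abs_difference": abs(within - marginal),
        "binomial_se": se,
        "n": n_neurons,
        "n_responsive": n_resp,
    }


# ---------------------------------------------------------------------------
# statistics oracles


def _fisher_oracle_p(table) -> float:
    """Exact two-sided Fisher p by direct enumeration with integer
    combinatorics (independent of any statistics library)."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    denom = math.comb(n, c1)
    k_lo = max(0, c1 - r2)
    k_hi = min(r1, c1)
    probs = {
        k: math.comb(r1, k) * math.comb(r2, c1 - k) / denom
        for k in range(k_lo, k_hi + 1)
    }
    p_obs = probs[a]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12)))


def fisher_oracle(max_total: int = 40) -> dict:
    """Compare fisher_exact with the enumeration oracle over every 2x2 table
    with grand total <= ``max_total``."""
    worst = 0.0
    n_tables = 0
    for n in range(1, max_total + 1):
        for r1 in range(n + 1):
            r2 = n - r1
            for a in range(r1 + 1):
                b = r1 - a
                for c in range(r2 + 1):
                    d = r2 - c
                    table = [[a, b], [c, d]]
                    if (a + c == 0 and b + d == 0) or (r1 == 0 and r2 == 0):
                        continue
                    try:
                        _, p = fisher_exact(table)
                    except ValueError:
                        continue
                    p_oracle = _fisher_oracle_p(table)
                    worst = max(worst, abs(p - p_oracle))
                    n_tables += 1
    return {"max_abs_p_diff": worst, "n_tables": n_tables}


def wilcoxon_oracle(max_n: int = 10, seed: int = 0) -> dict:
    """Compare wilcoxon_signed_rank against full 2^n sign-pattern
    enumeration, for every sign assignment of one magnitude draw per n.

    The oracle two-sided p for an observed positive-rank sum W+ is
    ``min(1, 2*min(P(W <= W+), P(W >= W+)))`` over the 2^n equally likely
    sign patterns.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    n_cases = 0
    for n in range(1, max_n + 1):
        mags = np.sort(rng.uniform(0.5, 10.0, size=n))  # distinct, no ties
        ranks = np.arange(1, n + 1, dtype=float)
        # null distribution of W+ over all sign patterns, computed once
        patterns = np.array(list(product([0.0, 1.0], repeat=n)))
        ws_all = patterns @ ranks
        for signs in product([-1.0, 1.0], repeat=n):
            signs = np.array(signs)
            d = mags * signs
            _, p = wilcoxon_signed_rank(d)
            w_obs = float(ranks[signs > 0].sum())
            p_lo = (ws_all <= w_obs).mean()
            p_hi = (ws_all >= w_obs).mean()
            p_oracle = min(1.0, 2.0 * min(p_lo, p_hi))
            worst = max(worst, abs(p - p_oracle))
            n_cases += 1
    return {"max_abs_p_diff": worst, "n_cases": n_cases}


# ---------------------------------------------------------------------------
# photometry


def photometry_recovery(step: float = 0.02, seed: int = 0) -> dict:
    """Recovery of a known relative dopamine step in the 0-5 and 10-15 min
    bins (control fit on the pre-injection baseline), plus the artifact-only
    noise floor."""
    from .photometry import bin_dff, compute_dff, fit_control

    sig, truth = synth.gen_photometry(da_amplitude=step, seed=seed)
    window = (float(sig.times_s[0]), 0.0)
    coeffs = fit_control(sig, fit_window=window)
    dff = compute_dff(sig, coeffs)
    bins = bin_dff(dff, [(0.0, 300.0), (600.0, 900.0)])
    rel_errs = [abs(b - step) / step for b in bins]
    # artifact-only control
    sig0, _ = synth.gen_photometry(da_amplitude=0.0, seed=seed + 1)
    coeffs0 = fit_control(sig0, fit_window=window)
    dff0 = compute_dff(sig0, coeffs0)
    bins0 = bin_dff(dff0, [(0.0, 300.0), (600.0, 900.0)])
    noise_ratio = 0.002 / float(np.mean(coeffs0.slope * sig0.ch405 + coeffs0.intercept))
    return {
        "bin_0_5_dff": bins[0],
        "bin_10_15_dff": bins[1],
        "bin_0_5_rel_err": rel_errs[0],
        "bin_10_15_rel_err": rel_errs[1],
        "artifact_only_max_abs_bin_dff": float(max(abs(b) for b in bins0)),
        "noise_bound_3x": 3.0 * noise_ratio,
        "true_step": step,
        "n": len(sig.times_s),
    }


# ---------------------------------------------------------------------------
# end-to-end cohort dichotomy


def cohort_dichotomy(
    out_dir: str = "scratch/acc_cohort",
    n_neurons: int = 24,
    n_animals_per_class: int = 2,
    n_shuffles: int = 1000,
    movement_n_shuffles: int = 500,
    seed: int = 0,
) -> dict:
    """Full pipeline on a designed three-day cohort with increasing responder
    fractions; returns the recovered fraction sequences and cross-session
    category tallies."""
    from .pipeline import RunConfig, run_all
    from .synth import SynthConfig, gen_cohort

    cfg = SynthConfig(
        out_dir=out_dir,
        seed=seed,
        n_neurons=n_neurons,
        n_animals_per_class=n_animals_per_class,
        responder_fractions=(0.05, 0.25, 0.45),
    )
    cohort_dir, _ = gen_cohort(cfg)
    run_cfg = RunConfig(
        cohort_dir=str(cohort_dir),
        out_dir=str(cohort_dir) + "_run",
        seed=seed,
        n_shuffles=n_shuffles,
        movement_n_shuffles=movement_n_shuffles,
        qc_min_neurons=min(20, n_neurons),
    )
    report = run_all(run_cfg)
    d1 = report["fractions"]["D1-like"]
    d2 = report["fractions"]["D2-like"]
    days = run_cfg.days
    d1_elev = [d1[d]["elevated"]["fraction"] for d in days]
    d2_red = [d2[d]["reduced"]["fraction"] for d in days]
    cross = report["cross_session"]
    both = cross["D1-like"]["elevated"]["both"] + cross["D2-like"]["reduced"]["both"]
    last_only = (
        cross["D1-like"]["elevated"]["last_exposure_only"]
        + cross["D2-like"]["reduced"]["last_exposure_only"]
    )
    return {
        "d1_elevated_fractions": d1_elev,
        "d2_reduced_fractions": d2_red,
        "d1_strictly_increasing": float(d1_elev[0] < d1_elev[1] < d1_elev[2]),
        "d2_strictly_increasing": float(d2_red[0] < d2_red[1] < d2_red[2]),
        "cross_session_both": both,
        "cross_session_last_only": last_only,
        "sensitization_indices": report["sensitization_index"],
        "n_neurons_per_day": {
            c: {d: report["fractions"][c][d]["n"] for d in days}
            for c in ("D1-like", "D2-like")
        },
        "report": report,
    }
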