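import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spnsens.transients as T
from spnsens.design import SessionDesign
from spnsens.synth import DEFAULT_SHAPE, SynthNeuronSpec, gen_event_train, render_trace
from spnsens.transients import (
    DetectorConfig,
    EpochPair,
    RawTrace,
    TransientModelParams,
    baseline_correct,
    clean_fits,
    detect_epochs,
    detect_transients,
    eval_kernel,
    fit_events,
    fit_reference,
    fit_transient,
    kernel_onset,
    reconstruct,
    to_train,
)

# ---------------------------------------------------------------------------
# kernel


class TestKernel:
    def test_midpoint_is_half_amplitude(self):
        p = TransientModelParams(2.0, 0.1, 1.0, t0=0.3)
        assert eval_kernel(p, 0.3) == pytest.approx(1.0, rel=1e-12)

    def test_vanishes_in_both_limits(self):
        p = TransientModelParams(2.0, 0.1, 1.0, 0.0)
        assert eval_kernel(p, -50.0) < 1e-12
        assert eval_kernel(p, 200.0) < 1e-12

    def test_rising_orientation_value(self):
        # rising form at t=1 for alpha=2, tau_g=0.1, tau_d=1, t0=0
        p = TransientModelParams(2.0, 0.1, 1.0, 0.0)
        expected = 2.0 / (1.0 + math.exp(-10.0)) * math.exp(-1.0)
        assert eval_kernel(p, 1.0) == pytest.approx(expected, rel=1e-12)

    def test_printed_orientation_under_sign_flip(self):
        # the product form with a decreasing logistic (exponent +(t-t0)/tau_g)
        # equals this kernel with tau_g negated
        p = TransientModelParams(2.0, -0.1, 1.0, 0.0)
        expected = 2.0 / (1.0 + math.exp(10.0)) * math.exp(-1.0)
        assert eval_kernel(p, 1.0) == pytest.approx(expected, rel=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        alpha=st.floats(0.5, 10.0),
        tau_g=st.floats(0.02, 0.3),
        ratio=st.floats(2.1, 30.0),
    )
    def test_peak_after_t0_and_onset_before_peak(self, alpha, tau_g, ratio):
        p = TransientModelParams(alpha, tau_g, tau_g * ratio, 0.0)
        tp = T.kernel_peak_time(p)
        onset = kernel_onset(p)
        assert tp > 0.0
        assert onset < tp
        # kernel is positive and below the asymptote everywhere
        t = np.linspace(-2.0, 10.0, 200)
        y = eval_kernel(p, t)
        assert np.all(y >= 0.0) and np.all(y <= alpha)


# ---------------------------------------------------------------------------
# baseline correction


class TestBaseline:
    def test_constant_trace_corrects_to_zero(self, design):
        raw = RawTrace("n", "s", 10.0, np.full(design.n_frames, 3.7), design)
        corr = baseline_correct(raw)
        np.testing.assert_allclose(corr.samples, 0.0, atol=1e-12)

    def test_additive_shift_invariance(self, design, rng):
        x = rng.normal(0, 0.2, design.n_frames)
        c1 = baseline_correct(RawTrace("n", "s", 10.0, x, design))
        c2 = baseline_correct(RawTrace("n", "s", 10.0, x + 5.0, design))
        np.testing.assert_allclose(c1.samples, c2.samples, atol=1e-10)

    def test_recovers_transient_on_offset(self, design):
        t = design.frame_times()
        p = TransientModelParams(2.0, 0.06, 0.8, t0=-450.0)
        raw_samples = 1.5 + eval_kernel(p, t)
        corr = baseline_correct(RawTrace("n", "s", 10.0, raw_samples, design))
        np.testing.assert_allclose(
            corr.samples, eval_kernel(p, t), atol=0.02 * p.alpha_p
        )

    def test_idempotent_within_estimator_variance(self, design, rng):
        # the lowest-quantile running mean has sampling variability of a few
        # per cent of the noise SD; a second application must stay below 10%
        noise_sd = 0.15
        x = rng.normal(0, noise_sd, design.n_frames)
        c1 = baseline_correct(RawTrace("n", "s", 10.0, x, design))
        c2 = baseline_correct(RawTrace("n", "s", 10.0, c1.samples, design))
        rms = float(np.sqrt(np.mean((c2.samples - c1.samples) ** 2)))
        assert rms < 0.10 * noise_sd

    def test_window_longer_than_segment_rejected(self, design, rng):
        raw = RawTrace("n", "s", 10.0, rng.normal(size=design.n_frames), design)
        with pytest.raises(Exception):
            baseline_correct(raw, window_len_s=400.0)


# ---------------------------------------------------------------------------
# epoch detection


class TestDetectEpochs:
    def _corrected(self, design, samples):
        return baseline_correct(RawTrace("n", "s", 10.0, samples, design))

    def test_pure_noise_rarely_fires_at_3_sigma(self, design):
        # at k=3 the epoch detector itself stays quiet on noise
        rng = np.random.default_rng(0)
        n_pairs = 0
        for _ in range(20):
            corr = self._corrected(design, rng.normal(0, 0.15, design.n_frames))
            n_pairs += len(detect_epochs(corr, k_rise=3.0, k_fall=3.0))
        # under one pair per 300 s of recording
        assert n_pairs / (20 * 4) <= 1.0

    def test_single_clean_kernel_gives_one_event(self, design):
        # SNR 10: one accepted transient whose epoch brackets the peak
        # (sub-threshold noise candidates are removed by fit cleaning)
        rng = np.random.default_rng(1)
        t = design.frame_times()
        p = TransientModelParams(2.0, 0.06, 0.8, t0=-450.0)
        raw = RawTrace(
            "n", "s", 10.0,
            eval_kernel(p, t) + rng.normal(0, 0.1 * 2.0 * 0.77, design.n_frames),
            design,
        )
        train, events, _ = detect_transients(raw)
        assert len(train) == 1
        accepted = [e for e in events if e.accepted]
        t_lo = t[accepted[0].seg_start]
        t_hi = t[accepted[0].seg_stop - 1]
        assert t_lo < -450.0 < t_hi

    def test_two_kernels_30s_apart_give_two_events(self, design):
        rng = np.random.default_rng(2)
        t = design.frame_times()
        y = rng.normal(0, 0.15, design.n_frames)
        for t0 in (-450.0, -420.0):
            y += eval_kernel(TransientModelParams(2.0, 0.06, 0.8, t0), t)
        train, events, _ = detect_transients(RawTrace("n", "s", 10.0, y, design))
        assert len(train) == 2
        assert -450.5 < train.onsets_s[0] < -449.5
        assert -420.5 < train.onsets_s[1] < -419.5

    def test_empty_trace_gives_empty_list(self, design):
        corr = self._corrected(design, np.zeros(design.n_frames))
        assert detect_epochs(corr) == []


# ---------------------------------------------------------------------------
# fitting


class TestFitting:
    def test_reference_recovers_known_kernel(self, design):
        # identical noiseless transients -> reference within 1%
        t = design.frame_times()
        true = TransientModelParams(2.0, 0.1, 1.0)
        y = np.zeros(design.n_frames)
        t0s = [-550.0 + 40.0 * k for k in range(6)]
        for t0 in t0s:
            y += eval_kernel(TransientModelParams(2.0, 0.1, 1.0, t0), t)
        corr = baseline_correct(RawTrace("n", "s", 10.0, y + 1.0, design))
        pairs = detect_epochs(corr)
        assert len(pairs) == 6
        ref = fit_reference(corr, pairs)
        assert ref.alpha_p == pytest.approx(true.alpha_p, rel=0.05)
        assert ref.tau_d == pytest.approx(true.tau_d, rel=0.05)

    def test_reference_defaults_without_pairs(self, design):
        corr = baseline_correct(
            RawTrace("n", "s", 10.0, np.zeros(design.n_frames), design)
        )
        ref = fit_reference(corr, [])
        assert ref.tau_g == pytest.approx(0.1)
        assert ref.tau_d == pytest.approx(1.0)

    def test_noiseless_event_fit_self_consistent(self, design):
        t = design.frame_times()
        true = TransientModelParams(3.0, 0.08, 0.9, t0=-450.0)
        y = eval_kernel(true, t)
        corr = baseline_correct(RawTrace("n", "s", 10.0, y, design))
        pairs = detect_epochs(corr)
        assert len(pairs) == 1
        ev = fit_transient(corr, pairs[0], true, free_tau_g=True)
        assert ev.params.alpha_p == pytest.approx(true.alpha_p, rel=0.01)
        assert ev.params.tau_d == pytest.approx(true.tau_d, rel=0.01)
        assert ev.rmse < 1e-3
        assert ev.onset_s < T.kernel_peak_time(ev.params)

    def test_batch_fitter_matches_reference_path(self, design, quiet_neuron):
        _, _, raw = quiet_neuron
        corr = baseline_correct(raw)
        pairs = detect_epochs(corr)
        ref = fit_reference(corr, pairs)
        batch = fit_events(corr, pairs, ref)
        per_event = []
        for i, p in enumerate(pairs):
            lo = pairs[i - 1].decay_end if i > 0 else 0
            hi = pairs[i + 1].rise_start if i + 1 < len(pairs) else len(corr.samples)
            per_event.append(
                fit_transient(corr, p, ref, seg_bounds=(max(lo, 0), hi))
            )
        rel_amp = [
            abs(a.params.alpha_p - b.params.alpha_p) / max(b.params.alpha_p, 1e-9)
            for a, b in zip(batch, per_event)
        ]
        # bulk agreement; a few ill-posed segments may settle differently
        assert np.median(rel_amp) < 1e-3
        assert np.mean(np.asarray(rel_amp) < 0.05) > 0.9


# ---------------------------------------------------------------------------
# cleaning / reconstruction / train


class TestCleanReconstructTrain:
    def _one_event(self, design):
        t = design.frame_times()
        true = TransientModelParams(3.0, 0.08, 0.9, t0=-450.0)
        y = eval_kernel(true, t)
        corr = baseline_correct(RawTrace("n", "s", 10.0, y, design))
        pairs = detect_epochs(corr)
        events = fit_events(corr, pairs)
        return corr, pairs, events

    def test_zero_amplitude_event_rejected(self, design):
        corr, pairs, events = self._one_event(design)
        ev = events[0]
        ev_zero = T.TransientEvent(
            params=ev.params, onset_s=ev.onset_s, peak_amp=0.0, area=0.0,
            rmse=0.0, seg_start=ev.seg_start, seg_stop=ev.seg_stop,
        )
        out = clean_fits([ev_zero], corr, pairs, sigma_quiet=0.1)
        assert not out[0].accepted and "low_amplitude" in out[0].reason

    def test_rejection_monotone_in_amplitude_threshold(self, design, quiet_neuron):
        _, _, raw = quiet_neuron
        corr = baseline_correct(raw)
        pairs = detect_epochs(corr)
        events = fit_events(corr, pairs)
        accepted = [
            sum(e.accepted for e in clean_fits(events, corr, pairs, min_amp_sigma=k))
            for k in (1.0, 3.0, 5.0, 8.0)
        ]
        assert all(a >= b for a, b in zip(accepted, accepted[1:]))

    def test_fast_decay_shape_rejected(self, design):
        corr, pairs, events = self._one_event(design)
        bad = T.TransientEvent(
            params=TransientModelParams(3.0, 0.5, 0.2, -450.0),
            onset_s=-450.0, peak_amp=3.0, area=1.0, rmse=0.0,
            seg_start=events[0].seg_start, seg_stop=events[0].seg_stop,
        )
        out = clean_fits([bad], corr, pairs, sigma_quiet=0.1)
        assert not out[0].accepted
        assert "no_fast_rise_slow_decay" in out[0].reason

    def test_reconstruct_noiseless_event(self, design):
        corr, pairs, events = self._one_event(design)
        events = clean_fits(events, corr, pairs, sigma_quiet=0.01)
        recon, stats = reconstruct(events, corr)
        assert stats["r_squared"] > 0.99
        assert sum(stats["contributions"]) == pytest.approx(1.0)

    def test_reconstruct_without_events(self, design):
        corr = baseline_correct(
            RawTrace("n", "s", 10.0, np.zeros(design.n_frames), design)
        )
        recon, stats = reconstruct([], corr)
        assert stats["r_squared"] is None
        assert not stats["contributions"]
        np.testing.assert_allclose(recon, 0.0)

    def test_to_train_sorts_and_keeps_nearby_onsets(self, design):
        def ev(onset, area):
            return T.TransientEvent(
                params=TransientModelParams(1.0, 0.06, 0.8, onset),
                onset_s=onset, peak_amp=1.0, area=area, rmse=0.0,
            )

        train = to_train([ev(-100.0, 1.0), ev(-250.0, 1.0), ev(-99.7, 1.0)],
                         "n", "s", design)
        # unsorted input sorted; onsets 0.3 s apart both kept
        np.testing.assert_allclose(train.onsets_s, [-250.0, -100.0, -99.7])

    def test_to_train_merges_same_frame_onsets_keeping_larger_area(self, design):
        def ev(onset, area):
            return T.TransientEvent(
                params=TransientModelParams(1.0, 0.06, 0.8, onset),
                onset_s=onset, peak_amp=1.0, area=area, rmse=0.0,
            )

        train = to_train([ev(-100.0, 1.0), ev(-99.95, 9.0)], "n", "s", design)
        assert len(train) == 1


# ---------------------------------------------------------------------------
# end-to-end on one neuron


def test_full_chain_recovers_counts_and_onsets(design, quiet_neuron):
    spec, truth_train, raw = quiet_neuron
    train, events, _ = detect_transients(raw)
    n_true = len(truth_train)
    assert abs(len(train) - n_true) <= 0.1 * n_true
    true_onsets = truth_train.onsets_s + T.kernel_onset(spec.shape)
    errs = [np.min(np.abs(true_onsets - o)) for o in train.onsets_s]
    assert np.median(errs) < 0.3
    # onset error unbiased within one frame
    signed = [true_onsets[np.argmin(np.abs(true_onsets - o))] - o for o in train.onsets_s]
    assert abs(np.median(signed)) <= 0.1
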