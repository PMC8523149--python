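import json
from pathlib import Path

import numpy as np
import pytest
from scipy import stats

from spnsens.design import SessionDesign
from spnsens.synth import (
    DEFAULT_SHAPE,
    SynthConfig,
    SynthNeuronSpec,
    gen_cohort,
    gen_event_train,
    gen_photometry,
    gen_velocity,
    render_trace,
    velocity_to_centroid,
)
from spnsens.transients import eval_kernel


class TestEventTrains:
    def test_same_seed_gives_identical_trains(self, design):
        spec = SynthNeuronSpec(neuron_id="n", rate_pre_hz=0.2, rate_post_hz=0.2)
        a = gen_event_train(spec, design, 42)
        b = gen_event_train(spec, design, 42)
        np.testing.assert_array_equal(a.onsets_s, b.onsets_s)

    def test_zero_post_rate_means_no_events_after_injection(self, design):
        spec = SynthNeuronSpec(neuron_id="n", rate_pre_hz=0.3, rate_post_hz=0.0,
                               true_label="reduced")
        train = gen_event_train(spec, design, 0)
        assert np.all(train.onsets_s < 0.0)

    def test_count_within_poisson_tail_bound(self, design):
        # expectation 120 over four 300 s windows at 0.1 Hz
        spec = SynthNeuronSpec(neuron_id="n", rate_pre_hz=0.1, rate_post_hz=0.1)
        counts = [len(gen_event_train(spec, design, s)) for s in range(50)]
        bound = 3.0 * np.sqrt(120.0)
        assert np.mean([abs(c - 120.0) <= bound for c in counts]) >= 0.96

    def test_events_inside_windows_and_sorted(self, design, rng):
        spec = SynthNeuronSpec(neuron_id="n", rate_pre_hz=0.4, rate_post_hz=0.4)
        train = gen_event_train(spec, design, rng)
        assert np.all(np.diff(train.onsets_s) > 0)
        assert design.contains(train.onsets_s).all()

    def test_window_counts_are_poisson(self, design):
        # KS against the Poisson law over many neurons (conservative for
        # discrete data, so a pass is meaningful at alpha=0.01)
        spec = SynthNeuronSpec(neuron_id="n", rate_pre_hz=0.1, rate_post_hz=0.1)
        counts = []
        for s in range(300):
            train = gen_event_train(spec, design, s)
            counts.append(np.sum((train.onsets_s >= -300) & (train.onsets_s < 0)))
        p = stats.kstest(counts, stats.poisson(30.0).cdf).pvalue
        assert p > 0.01

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            SynthNeuronSpec(neuron_id="n", rate_pre_hz=-0.1, rate_post_hz=0.1)

    def test_label_rate_consistency_enforced(self):
        with pytest.raises(ValueError):
            SynthNeuronSpec(neuron_id="n", rate_pre_hz=0.1, rate_post_hz=0.1,
                            true_label="elevated")


class TestRenderTrace:
    def test_noiseless_single_event_is_one_kernel(self, design):
        spec = SynthNeuronSpec(neuron_id="n", rate_pre_hz=0.1, rate_post_hz=0.1,
                               noise_sd=0.0, drift_amp=0.0)
        train = gen_event_train(spec, design, 3)
        train.onsets_s = train.onsets_s[:1]
        raw = render_trace(train, spec, design, 0)
        t = design.frame_times()
        expected = eval_kernel(
            type(spec.shape)(spec.shape.alpha_p, spec.shape.tau_g,
                             spec.shape.tau_d, train.onsets_s[0]),
            t,
        )
        # rendering truncates each kernel at ~10 decay constants
        np.testing.assert_allclose(raw.samples, expected, atol=1e-4 * spec.shape.alpha_p)
        peak_factor = raw.samples.max() / spec.shape.alpha_p
        assert 0.5 < peak_factor < 1.0

    def test_empty_train_is_pure_noise(self, design):
        from spnsens.transients import TransientTrain

        spec = SynthNeuronSpec(neuron_id="n", rate_pre_hz=0.1, rate_post_hz=0.1,
                               noise_sd=0.2, drift_amp=0.0)
        empty = TransientTrain("n", design.session_id, np.array([]))
        raw = render_trace(empty, spec, design, 5)
        assert abs(raw.samples.mean()) < 0.02
        assert raw.samples.std() == pytest.approx(0.2, rel=0.05)

    def test_residual_sd_matches_noise_sd(self, design):
        spec = SynthNeuronSpec(neuron_id="n", rate_pre_hz=0.2, rate_post_hz=0.2,
                               noise_sd=0.15, drift_amp=0.0)
        train = gen_event_train(spec, design, 3)
        raw = render_trace(train, spec, design, 4)
        t = design.frame_times()
        clean = np.zeros_like(t)
        for e in train.onsets_s:
            clean += eval_kernel(
                type(spec.shape)(spec.shape.alpha_p, spec.shape.tau_g,
                                 spec.shape.tau_d, e), t,
            )
        resid = raw.samples - clean
        assert resid.std() == pytest.approx(0.15, rel=0.05)


class TestVelocityAndPhotometry:
    def test_zero_gain_equals_no_coupling(self, design):
        spec = SynthNeuronSpec(neuron_id="n", rate_pre_hz=0.1, rate_post_hz=0.1)
        train = gen_event_train(spec, design, 1)
        a = gen_velocity(design, train, coupling="heightened", gain=0.0, seed=9)
        b = gen_velocity(design, train, coupling="none", gain=0.0, seed=9)
        np.testing.assert_allclose(a.speed, b.speed)

    def test_velocity_nonnegative_and_deterministic(self, design):
        v1 = gen_velocity(design, None, seed=3)
        v2 = gen_velocity(design, None, seed=3)
        assert np.all(v1.speed >= 0)
        np.testing.assert_array_equal(v1.speed, v2.speed)

    def test_centroid_track_reproduces_speed_scale(self, design):
        vel = gen_velocity(design, None, seed=2)
        track = velocity_to_centroid(vel, seed=2)
        d = np.hypot(np.diff(track["x"]), np.diff(track["y"]))
        mean_speed = d.sum() / (vel.times_s[-1] - vel.times_s[0])
        assert mean_speed == pytest.approx(vel.speed.mean(), rel=0.15)

    def test_photometry_deterministic_and_truth_stored(self):
        s1, t1 = gen_photometry(seed=5)
        s2, t2 = gen_photometry(seed=5)
        np.testing.assert_array_equal(s1.ch470, s2.ch470)
        np.testing.assert_array_equal(s1.ch405, s2.ch405)
        assert t1["da_amplitude"] == 0.02
        assert np.all(t1["true_dff"][s1.times_s < 0] == 0.0)


class TestCohort:
    def test_cohort_layout_and_determinism(self, tmp_path):
        cfg = SynthConfig(
            out_dir=str(tmp_path / "c1"), seed=11, n_neurons=6,
            n_animals_per_class=1, photometry=False,
        )
        out1, truth1 = gen_cohort(cfg)
        cfg2 = SynthConfig(
            out_dir=str(tmp_path / "c2"), seed=11, n_neurons=6,
            n_animals_per_class=1, photometry=False,
        )
        out2, truth2 = gen_cohort(cfg2)
        for f in sorted(out1.glob("*_traces.csv")):
            assert (out2 / f.name).read_bytes() == f.read_bytes()
        # one trace file per animal per day, n_neurons each
        import pandas as pd

        f = next(out1.glob("d1_m0_saline_traces.csv"))
        assert pd.read_csv(f)["neuron_id"].nunique() == 6

    def test_identity_map_is_bijection_on_tracked_subset(self, tmp_path):
        cfg = SynthConfig(out_dir=str(tmp_path / "c"), seed=0, n_neurons=8,
                          n_animals_per_class=1, photometry=False)
        out, _ = gen_cohort(cfg)
        identity = json.loads((out / "identity_map.json").read_text())
        for animal, m in identity.items():
            for day in cfg.days:
                ids = [v[day] for v in m["tracked_ids"].values()]
                assert len(ids) == len(set(ids))

    def test_ground_truth_event_times_inside_windows(self, tmp_path, design):
        cfg = SynthConfig(out_dir=str(tmp_path / "c"), seed=2, n_neurons=4,
                          n_animals_per_class=1, photometry=False)
        _, truth = gen_cohort(cfg)
        for key, times in truth.event_t0s.items():
            assert design.contains(np.asarray(times)).all()
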