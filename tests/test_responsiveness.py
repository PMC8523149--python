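import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spnsens.design import SessionDesign
from spnsens.responsiveness import (
    ActivityChange,
    NullDistribution,
    ResponseLabel,
    activity_change,
    bonferroni,
    classify,
    enumerate_null,
    fisher_exact,
    fraction_responsive,
    label_neuron,
    log2_response,
    shuffle_null,
    track_profiles,
    wilcoxon_signed_rank,
    window_count,
    _intervals_recorded,
)
from spnsens.transients import TransientTrain


def train_of(onsets, design):
    return TransientTrain("n", design.session_id, np.asarray(onsets, float))


class TestCounting:
    def test_window_count_examples(self, design):
        tr = train_of([10.0, 50.0, 250.0], design)
        assert window_count(tr, (0.0, 300.0)) == 3
        empty = TransientTrain("n", "s", np.array([]))
        assert window_count(empty, (0.0, 300.0)) == 0
        # half-open: onset exactly at the end excluded
        tr2 = train_of([10.0, 250.0], design)
        assert window_count(tr2, (0.0, 250.0)) == 1

    def test_activity_change_arithmetic(self, design):
        pre = list(np.linspace(-299, -1, 30))
        post = list(np.linspace(1, 299, 90))
        ch = activity_change(train_of(pre + post, design), design)
        assert ch.n_pre == 30 and ch.n_post == 90
        assert ch.delta_hz == pytest.approx(0.2)

    def test_delta_ignores_events_outside_analysis_windows(self, design):
        base = [-10.0, 10.0]
        ch1 = activity_change(train_of(base, design), design)
        ch2 = activity_change(train_of([-550.0] + base + [700.0], design), design)
        assert ch1.delta_hz == ch2.delta_hz


class TestShuffleNull:
    def test_intervals_preserve_count_and_last_onset(self, design, rng):
        onsets = np.sort(design.to_session(np.sort(rng.uniform(0, 1199, 30))))
        tr = train_of(onsets, design)
        iv = _intervals_recorded(tr, design)
        assert len(iv) == 30
        # any permutation cumulates to the same final time
        perm = rng.permutation(iv)
        assert np.cumsum(perm)[-1] == pytest.approx(
            design.to_recorded(onsets)[-1]
        )

    def test_deterministic_given_seed(self, design, rng):
        onsets = np.sort(design.to_session(np.sort(rng.uniform(0, 1199, 20))))
        tr = train_of(onsets, design)
        a = shuffle_null(tr, design, n_shuffles=50, seed=5)
        b = shuffle_null(tr, design, n_shuffles=50, seed=5)
        np.testing.assert_array_equal(a.values, b.values)

    def test_too_few_events_labelled_none(self, design):
        tr = train_of([-100.0, 100.0], design)
        lab = label_neuron(tr, design, n_shuffles=10, seed=0)
        assert lab.label == "none" and lab.reason == "too_few_events"

    def test_equally_spaced_train_degenerate_null(self, design):
        # equal intervals: every permutation is the identity; label none
        onsets = design.to_session(np.arange(10.0, 1190.0, 40.0))
        tr = train_of(np.sort(onsets), design)
        lab = label_neuron(tr, design, n_shuffles=200, seed=0)
        assert lab.label == "none"
        null = shuffle_null(tr, design, n_shuffles=200, seed=0)
        assert np.ptp(null.values) <= 2 / 300.0  # essentially concentrated

    def test_sampled_null_matches_enumeration_for_tiny_train(self, design, rng):
        rec = np.sort(rng.uniform(0, 1195, 5))
        tr = train_of(design.to_session(rec), design)
        exact = enumerate_null(tr, design)
        sampled = shuffle_null(tr, design, n_shuffles=20000, seed=1)
        assert set(np.round(sampled.values, 9)) <= set(np.round(exact, 9))
        assert sampled.values.mean() == pytest.approx(exact.mean(), abs=5e-4)


class TestClassify:
    def _null(self, values):
        return NullDistribution(np.asarray(values, float), len(values), 0)

    def test_strictly_above_all_nulls_is_elevated(self):
        ch = ActivityChange("n", 10, 40)
        null = self._null(np.linspace(-0.05, 0.05, 100))
        assert classify(ch, null).label == "elevated"

    def test_tie_with_percentile_value_is_none(self):
        null = self._null(np.arange(100) / 300.0)
        hi = np.sort(null.values)[98]  # nearest-rank 99th percentile
        ch = ActivityChange("n", 0, 98)
        assert ch.delta_hz == hi
        assert classify(ch, null).label == "none"

    def test_below_first_percentile_is_reduced(self):
        ch = ActivityChange("n", 40, 10)
        null = self._null(np.linspace(-0.05, 0.05, 100))
        assert classify(ch, null).label == "reduced"


class TestSummaries:
    def _labels(self, spec):
        return [
            ResponseLabel(f"n{i}", lab, 0.0, None, None)
            for i, lab in enumerate(spec)
        ]

    def test_fraction_responsive_counts(self):
        labels = self._labels(["elevated"] * 10 + ["none"] * 90)
        out = fraction_responsive(labels)
        assert out["fractions"]["elevated"] == pytest.approx(0.10)
        assert sum(out["fractions"].values()) == pytest.approx(1.0)

    def test_fraction_responsive_empty_errors(self):
        with pytest.raises(ValueError, match="no_neurons"):
            fraction_responsive([])

    def test_track_profiles_categories_partition(self):
        l1 = {"a": ResponseLabel("a", "elevated", 0, None, None),
              "b": ResponseLabel("b", "none", 0, None, None),
              "c": ResponseLabel("c", "reduced", 0, None, None)}
        l2 = {"a": ResponseLabel("a", "elevated", 0, None, None),
              "b": ResponseLabel("b", "elevated", 0, None, None),
              "c": ResponseLabel("c", "none", 0, None, None)}
        idmap = {"t0": ("a", "a"), "t1": ("b", "b"), "t2": ("c", "c")}
        profiles, tallies = track_profiles(l1, l2, idmap)
        assert {p.category_elevated for p in profiles} == {
            "both", "last_exposure_only", "never"
        }
        for direction in ("elevated", "reduced"):
            assert sum(tallies[direction].values()) == len(idmap)


class TestStatistics:
    def test_fisher_symmetric_table(self):
        odds, p = fisher_exact([[5, 5], [5, 5]])
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_fisher_diagonal_table_exact_value(self):
        _, p = fisher_exact([[10, 0], [0, 10]])
        assert p == pytest.approx(2.0 / math.comb(20, 10), rel=1e-9)

    def test_fisher_row_swap_inverts_odds_preserves_p(self):
        o1, p1 = fisher_exact([[8, 2], [3, 7]])
        o2, p2 = fisher_exact([[3, 7], [8, 2]])
        assert o1 == pytest.approx(1.0 / o2)
        assert p1 == pytest.approx(p2)

    def test_wilcoxon_all_zero_degenerate(self):
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            stat, p = wilcoxon_signed_rank([0.0, 0.0, 0.0])
        assert p == 1.0
        assert any("zero" in str(x.message) for x in w)

    def test_wilcoxon_five_positive_exact(self):
        _, p = wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0, 5.0])
        assert p == pytest.approx(2.0 / 2**5)

    def test_wilcoxon_antisymmetric_under_sign_flip(self, rng):
        d = rng.normal(size=12)
        d = d[d != 0]
        _, p1 = wilcoxon_signed_rank(d)
        _, p2 = wilcoxon_signed_rank(-d)
        assert p1 == pytest.approx(p2)

    def test_bonferroni_examples(self):
        np.testing.assert_allclose(bonferroni([0.01, 0.5], m=3), [0.03, 1.0])

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=8))
    def test_bonferroni_order_preserving(self, ps):
        adj = bonferroni(ps)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_log2_response_examples(self):
        assert log2_response(7, 7) == 0.0
        assert log2_response(10, 30) == pytest.approx(1.0)
        assert log2_response(3, 11) == pytest.approx(-log2_response(11, 3))
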