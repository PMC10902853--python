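"""The parch statistic: monotonization, autocorrelation, scaling, reports."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import parchscale as ps
from parchscale.hydration_counter import WaterCountSeries
from parchscale.parch_core import (
    ParchParams,
    autocorrelation,
    average_acf,
    categorize,
    categorize_and_summarize,
    compute_parch,
    heatmap_bins,
    monotonize,
    parch_value,
    reference_cbar_from_series,
)
from parchscale.synthetic import reference_fixture


def series_of(counts, dt=10.0, labels=None, names=None):
    counts = np.atleast_2d(np.asarray(counts))
    return WaterCountSeries(
        times_ps=np.arange(counts.shape[1]) * dt,
        counts=counts,
        residue_labels=labels,
        residue_names=names,
    )


def largest_nonincreasing_minorant(w, vmax):
    """Brute-force oracle: pointwise max over all non-increasing series <= w."""
    L = len(w)
    best = [0] * L
    for cand in itertools.combinations_with_replacement(range(vmax, -1, -1), L):
        # combinations_with_replacement of a descending range yields
        # non-increasing tuples only
        if all(c <= x for c, x in zip(cand, w)):
            best = [max(b, c) for b, c in zip(best, cand)]
    return best


class TestMonotonize:
    def test_running_minimum_example(self):
        np.testing.assert_array_equal(
            monotonize([5, 6, 4, 4, 5, 2]), [5, 5, 4, 4, 4, 2]
        )

    def test_nonincreasing_unchanged(self):
        np.testing.assert_array_equal(monotonize([3, 2, 1]), [3, 2, 1])
        np.testing.assert_array_equal(monotonize([4, 4, 4]), [4, 4, 4])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            monotonize([1, -1])

    def test_exhaustive_minorant_oracle(self):
        for L in range(1, 6):
            for w in itertools.product(range(4), repeat=L):
                expected = largest_nonincreasing_minorant(w, vmax=3)
                np.testing.assert_array_equal(monotonize(list(w)), expected)

    @given(st.lists(st.integers(min_value=0, max_value=50), min_size=1, max_size=40))
    @settings(deadline=None, max_examples=200)
    def test_idempotent_bounded_nonincreasing(self, w):
        eta = monotonize(w)
        np.testing.assert_array_equal(monotonize(eta), eta)
        assert np.all(eta <= np.asarray(w))
        assert np.all(np.diff(eta) <= 0)


class TestAutocorrelation:
    def test_constant_normalized_is_one(self):
        np.testing.assert_allclose(autocorrelation(np.full(8, 3.0)), np.ones(8))

    def test_impulse(self):
        eta = np.zeros(6)
        eta[0] = 1.0
        C = autocorrelation(eta)
        np.testing.assert_allclose(C, [1, 0, 0, 0, 0, 0])

    def test_unnormalized_lag0_is_mean_square(self):
        eta = np.array([3.0, 2.0, 2.0, 1.0])
        C = autocorrelation(eta, normalize=False)
        assert C[0] == pytest.approx(np.mean(eta**2))
        # hand-computed lag-1: (3*2 + 2*2 + 2*1)/3
        assert C[1] == pytest.approx((6 + 4 + 2) / 3)

    def test_all_zero_returns_zero(self):
        np.testing.assert_array_equal(autocorrelation(np.zeros(5)), np.zeros(5))

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            autocorrelation(np.array([1.0]))


class TestAverageAcf:
    def test_constant_is_one(self):
        assert average_acf(np.ones(11), dt=10.0) == pytest.approx(1.0)

    def test_zero_is_zero(self):
        assert average_acf(np.zeros(11), dt=10.0) == pytest.approx(0.0)

    def test_linear_decay_is_half(self):
        tau = np.linspace(0, 1, 101)
        C = 1 - tau
        assert abs(average_acf(C, dt=0.01) - 0.5) < 1e-9

    def test_degenerate_lag_grid_raises(self):
        with pytest.raises(ValueError):
            average_acf(np.ones(1), dt=10.0)
        with pytest.raises(ValueError):
            average_acf(np.ones(5), dt=0.0)


class TestParchValue:
    def test_reference_scores_ten(self):
        assert parch_value(0.37, 0.37) == pytest.approx(10.0)

    def test_dry_residue_scores_zero(self):
        assert parch_value(0.0, 0.5) == pytest.approx(0.0)

    def test_linearity(self):
        assert parch_value(0.25, 0.5) == pytest.approx(5.0)

    def test_bad_reference_raises(self):
        with pytest.raises(ValueError):
            parch_value(0.1, 0.0)

    def test_above_ten_warned_not_clamped(self):
        with pytest.warns(UserWarning, match="reference"):
            assert parch_value(2.0, 1.0) == pytest.approx(20.0)


class TestScalingInvariance:
    def test_normalized_pv_invariant_to_count_scaling(self):
        w = np.array([9, 9, 7, 5, 5, 3, 1, 0, 0, 0])
        ref = reference_fixture()
        params = ParchParams(reference_cbar=reference_cbar_from_series(ref))
        pv1 = compute_parch(series_of(w), params).parch_values[0]
        pv3 = compute_parch(series_of(3 * w), params).parch_values[0]
        assert pv3 == pytest.approx(pv1, rel=1e-12)

    def test_unnormalized_scales_quadratically(self):
        w = np.array([4, 3, 3, 2, 1, 1])
        dt = 10.0
        cbar = average_acf(autocorrelation(monotonize(w), normalize=False), dt)
        cbar2 = average_acf(autocorrelation(monotonize(2 * w), normalize=False), dt)
        assert cbar2 == pytest.approx(4 * cbar, rel=1e-12)


@given(
    st.lists(st.integers(min_value=0, max_value=8), min_size=4, max_size=25),
    st.integers(min_value=0, max_value=8),
)
@settings(deadline=None, max_examples=150)
def test_stochastic_dominance_slower_loss_higher_cbar(drops, extra):
    """If eta_a >= eta_b pointwise (both non-increasing, equal start), Cbar_a >= Cbar_b."""
    b = np.clip(10.0 - np.cumsum(np.minimum(drops, 3)), 0, None)  # non-increasing
    a = np.minimum(b + extra, b[0])  # still non-increasing, same start value
    assert np.all(a >= b) and a[0] == b[0]
    if a[0] == 0:
        return
    dt = 10.0
    cbar_a = average_acf(autocorrelation(a), dt)
    cbar_b = average_acf(autocorrelation(b), dt)
    assert cbar_a >= cbar_b - 1e-12


class TestComputeParch:
    def test_reference_identical_series_scores_ten_high(self):
        ref = reference_fixture()
        params = ParchParams(reference_cbar=ref)
        result = compute_parch(ref, params)
        assert result.parch_values[0] == pytest.approx(10.0)
        assert result.categories == ["high"]

    def test_all_zero_residue_scores_zero_low(self):
        ref = reference_fixture()
        series = series_of(np.zeros(101, dtype=int))
        result = compute_parch(series, ParchParams(reference_cbar=ref))
        assert result.parch_values[0] == 0.0
        assert result.categories == ["low"]

    def test_three_identical_replicates_equal_single(self):
        w = np.array([[8, 8, 6, 4, 2, 1, 0, 0]])
        ref = reference_fixture()
        params = ParchParams(reference_cbar=ref)
        single = compute_parch(series_of(w), params)
        triple = compute_parch([series_of(w)] * 3, params)
        np.testing.assert_allclose(triple.parch_values, single.parch_values)
        assert triple.n_replicates == 3

    def test_replicate_policies_commute_with_shared_reference(self):
        rng = np.random.default_rng(0)
        reps = [
            series_of(np.sort(rng.integers(0, 10, size=(3, 12)), axis=1)[:, ::-1])
            for _ in range(3)
        ]
        ref = reference_fixture()
        cbar_ref = reference_cbar_from_series(ref)
        a = compute_parch(reps, ParchParams(reference_cbar=cbar_ref,
                                            replicate_policy="mean-of-Cbar"))
        b = compute_parch(reps, ParchParams(reference_cbar=cbar_ref,
                                            replicate_policy="mean-of-PV"))
        np.testing.assert_allclose(a.parch_values, b.parch_values)

    def test_replicate_residue_mismatch_raises(self):
        ref = reference_fixture()
        s1 = series_of([[1, 1], [2, 2]], labels=["res_1", "res_2"])
        s2 = series_of([[1, 1], [2, 2]], labels=["res_1", "res_3"])
        with pytest.raises(ValueError, match="residue set"):
            compute_parch([s1, s2], ParchParams(reference_cbar=ref))


class TestReference:
    def test_multi_residue_rejected(self):
        s = series_of([[1, 1], [2, 2]])
        with pytest.raises(ValueError, match="exactly one"):
            reference_cbar_from_series(s)

    def test_zero_series_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            reference_cbar_from_series(series_of(np.zeros(5, dtype=int)))

    def test_any_series_against_itself_is_ten(self):
        w = np.array([7, 7, 5, 4, 4, 2, 1, 1, 0, 0])
        s = series_of(w)
        cbar = reference_cbar_from_series(s)
        result = compute_parch(s, ParchParams(reference_cbar=cbar))
        assert result.parch_values[0] == pytest.approx(10.0)


class TestReports:
    def result_with(self, pvs, names=None):
        pvs = np.asarray(pvs, dtype=float)
        from parchscale.parch_core import ParchResult

        return ParchResult(
            residue_labels=[f"res_{i}" for i in range(pvs.size)],
            eta=np.empty((0, 0, 0)),
            cbar=pvs / 10,
            parch_values=pvs,
            categories=[categorize(v) for v in pvs],
            cbar_ref=1.0,
            n_replicates=1,
            residue_names=names,
        )

    def test_category_boundaries(self):
        assert categorize(0.0) == "low"
        assert categorize(0.1) == "low"
        assert categorize(0.1000001) == "medium"
        assert categorize(0.8) == "medium"
        assert categorize(0.8000001) == "high"

    def test_all_zero_protein_fully_low(self):
        summary = categorize_and_summarize(self.result_with(np.zeros(7)))
        assert summary.set_index("category").loc["low", "percent"] == pytest.approx(100.0)

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(5)
        summary = categorize_and_summarize(self.result_with(rng.uniform(0, 2, 33)))
        assert summary["percent"].sum() == pytest.approx(100.0)

    def test_hand_built_ten_residue_distribution(self):
        pvs = [0.0, 0.05, 0.1, 0.2, 0.5, 0.8, 0.81, 1.5, 2.9, 9.0]
        summary = categorize_and_summarize(self.result_with(pvs)).set_index("category")
        assert summary.loc["low", "count"] == 3
        assert summary.loc["medium", "count"] == 3
        assert summary.loc["high", "count"] == 4
        assert summary.loc["high", "percent"] == pytest.approx(40.0)

    def test_heatmap_single_residue_first_bin(self):
        m = heatmap_bins([self.result_with([0.05], names=["ALA"])])
        assert m.loc["ALA"].iloc[0] == 1
        assert m.to_numpy().sum() == 1

    def test_heatmap_totals_conserved(self):
        rng = np.random.default_rng(6)
        names = list(rng.choice(
            ["ALA", "GLY", "LYS", "GLU", "TRP"], size=40))
        m = heatmap_bins([self.result_with(rng.uniform(0, 3.0, 40), names=names)])
        assert m.to_numpy().sum() == 40

    def test_heatmap_hand_built(self):
        names = ["ALA", "ALA", "GLY", "LYS", "LYS", "LYS", "GLU", "GLU",
                 "TRP", "SER", "SER", "VAL"]
        pvs = [0.05, 0.15, 0.05, 1.05, 1.05, 2.95, 0.25, 3.0, 0.65, 0.05,
               0.05, 0.35]
        m = heatmap_bins([self.result_with(pvs, names=names)])
        assert m.loc["ALA", "[0.0,0.1)"] == 1
        assert m.loc["ALA", "[0.1,0.2)"] == 1
        assert m.loc["LYS", "[1.0,1.1)"] == 2
        assert m.loc["LYS", "[2.9,3.0]"] == 1
        assert m.loc["GLU", "[2.9,3.0]"] == 1  # 3.0 closes the last bin
        assert m.loc["SER", "[0.0,0.1)"] == 2
        assert m.to_numpy().sum() == 12

    def test_heatmap_overflow_flagged(self):
        with pytest.warns(UserWarning, match="overflow"):
            m = heatmap_bins([self.result_with([3.5], names=["LYS"])])
        assert m.loc["LYS", ">3.0"] == 1


def test_pv_bounded_by_ten_under_pointwise_dominated_acf():
    """Residues whose normalized ACF never exceeds the reference's score <= 10."""
    ref = reference_fixture()
    cbar_ref = reference_cbar_from_series(ref)
    rng = np.random.default_rng(7)
    T = ref.n_frames
    ref_acf = autocorrelation(monotonize(ref.counts[0]))
    for _ in range(50):
        w = np.clip(20 - np.cumsum(rng.integers(0, 3, size=T)), 0, None)
        eta = monotonize(w)
        C = autocorrelation(eta)
        assert np.all(C <= ref_acf + 1e-12)
        pv = parch_value(average_acf(C, 10.0), cbar_ref)
        assert 0.0 <= pv <= 10.0 + 1e-9
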