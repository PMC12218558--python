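"""Geodetector q-statistic, Jenks discretization, sampling, interactions."""

import itertools

import numpy as np
import pytest

from vegdyn.geodetector import (
    classify_interaction,
    factor_q,
    interaction_q,
    jenks_breaks,
    q_significance,
    run_detector,
    sample_points,
    significance_stars,
    stratify,
)
from vegdyn.grids import GeoTransform, Grid
from vegdyn.synthetic import QDesign, make_stratified_response

GT = GeoTransform(0, 10, 1, -1)


def partition_ss(x_sorted, cuts):
    """Total within-class SS of a contiguous partition given cut positions."""
    ss = 0.0
    for a, b in zip((0,) + cuts, cuts + (len(x_sorted),)):
        seg = x_sorted[a:b]
        ss += ((seg - seg.mean()) ** 2).sum()
    return ss


def exhaustive_best_ss(x, k):
    x = np.sort(np.asarray(x, float))
    best = np.inf
    for cuts in itertools.combinations(range(1, len(x)), k - 1):
        best = min(best, partition_ss(x, cuts))
    return best


class TestJenks:
    def test_two_clear_clusters(self):
        breaks = jenks_breaks([1, 2, 3, 10, 11, 12], 2)
        assert len(breaks) == 1
        assert 3 < breaks[0] <= 10
        labels = stratify([1, 2, 3, 10, 11, 12], breaks)
        assert list(labels) == [1, 1, 1, 2, 2, 2]

    def test_k_one_no_thresholds(self):
        assert len(jenks_breaks([1.0, 2.0, 5.0], 1)) == 0

    def test_k_equals_n_zero_within_ss(self):
        x = np.array([1.0, 4.0, 9.0, 16.0])
        breaks = jenks_breaks(x, 4)
        labels = stratify(x, breaks)
        assert len(set(labels)) == 4

    def test_k_exceeding_distinct_count_rejected(self):
        with pytest.raises(ValueError):
            jenks_breaks([1.0, 1.0, 2.0], 3)

    def test_matches_exhaustive_partition_search(self):
        rng = np.random.default_rng(21)
        for _ in range(200):
            n = int(rng.integers(5, 15))
            k = int(rng.integers(2, 5))
            x = rng.normal(size=n)
            breaks = jenks_breaks(x, k)
            labels = stratify(x, breaks)
            got = sum(((x[labels == h] - x[labels == h].mean()) ** 2).sum()
                      for h in np.unique(labels))
            assert got == pytest.approx(exhaustive_best_ss(x, k), abs=1e-9)


class TestStratify:
    def test_below_all_thresholds_is_stratum_one(self):
        assert stratify([-5.0], [0.0, 1.0])[0] == 1

    def test_value_equal_to_threshold_goes_up(self):
        assert stratify([1.0], [1.0])[0] == 2

    def test_matches_comparison_oracle(self):
        rng = np.random.default_rng(22)
        t = np.sort(rng.normal(size=4))
        v = rng.normal(size=100)
        labels = stratify(v, t)
        expect = 1 + (v[:, None] >= t[None, :]).sum(axis=1)
        np.testing.assert_array_equal(labels, expect)


class TestSamplePoints:
    def _grids(self, shape=(20, 20), mask_frac=0.0, seed=0):
        rng = np.random.default_rng(seed)
        mask = rng.random(shape) < mask_frac
        resp = Grid(rng.random(shape), GeoTransform(0, shape[0], 1, -1), mask=mask)
        fac = Grid(rng.random(shape), GeoTransform(0, shape[0], 1, -1))
        return resp, {"f": fac}

    def test_full_grid_yields_distinct_points(self):
        resp, f = self._grids((8, 8))
        t = sample_points(resp, f, n=40, seed=1)
        assert len(t) == 40
        assert len(set(zip(t.data.x, t.data.y))) == 40

    def test_same_seed_identical_tables(self):
        resp, f = self._grids()
        a = sample_points(resp, f, n=100, seed=5)
        b = sample_points(resp, f, n=100, seed=5)
        assert a.data.equals(b.data)

    def test_drop_fraction_tracks_mask_fraction(self):
        resp, f = self._grids((60, 60), mask_frac=0.25, seed=3)
        t = sample_points(resp, f, n=2000, seed=7)
        frac = t.n_dropped / 2000
        # binomial 3 sigma around 0.25 at n=2000
        assert abs(frac - 0.25) < 3 * np.sqrt(0.25 * 0.75 / 2000) + 0.01

    def test_too_few_survivors_rejected(self):
        resp, f = self._grids((8, 8), mask_frac=0.95, seed=4)
        with pytest.raises(ValueError):
            sample_points(resp, f, n=60, seed=1)


class TestFactorQ:
    def test_single_stratum_zero(self):
        assert factor_q([1.0, 2.0, 3.0], ["A", "A", "A"]) == 0.0

    def test_pure_between_strata_one(self):
        assert factor_q([1, 1, 5, 5], ["A", "A", "B", "B"]) == 1.0

    def test_worked_instance(self):
        assert factor_q([1, 2, 3, 4], ["A", "A", "B", "B"]) == pytest.approx(0.8)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(200):
            n = int(rng.integers(4, 60))
            y = rng.normal(size=n)
            labels = rng.integers(0, rng.integers(2, 6), size=n)
            sst = ((y - y.mean()) ** 2).sum()
            ssw = sum(((y[labels == h] - y[labels == h].mean()) ** 2).sum()
                      for h in np.unique(labels))
            if sst == 0:
                continue
            q = factor_q(y, labels)
            assert q == pytest.approx(1 - ssw / sst, abs=1e-12)
            assert 0.0 <= q <= 1.0

    def test_affine_invariance_of_y(self):
        rng = np.random.default_rng(24)
        y = rng.normal(size=40)
        labels = rng.integers(0, 4, 40)
        assert factor_q(3.5 * y - 2, labels) == pytest.approx(factor_q(y, labels))

    def test_zero_total_variance_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            factor_q([2.0, 2.0, 2.0], ["A", "B", "C"])


class TestSignificance:
    def test_perfect_separation_attains_minimum_p(self):
        y = np.concatenate([np.zeros(20), np.ones(20)]) + \
            np.random.default_rng(0).normal(0, 0.01, 40)
        labels = np.repeat([0, 1], 20)
        p = q_significance(y, labels, n_perm=199, seed=1)
        assert p == pytest.approx(1 / 200)

    def test_seed_determinism(self):
        rng = np.random.default_rng(25)
        y = rng.normal(size=50)
        labels = rng.integers(0, 3, 50)
        p1 = q_significance(y, labels, n_perm=199, seed=9)
        p2 = q_significance(y, labels, n_perm=199, seed=9)
        assert p1 == p2

    def test_null_rejection_rate_calibrated(self):
        rng = np.random.default_rng(26)
        rejections = 0
        reps = 200
        for i in range(reps):
            y = rng.normal(size=80)
            labels = rng.integers(0, 4, 80)  # independent of y: true null
            p = q_significance(y, labels, n_perm=99, seed=1000 + i)
            rejections += p <= 0.05
        rate = rejections / reps
        assert abs(rate - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_noncentral_f_agrees_on_strong_effect(self):
        y = np.concatenate([np.zeros(30), np.ones(30)]) + \
            np.random.default_rng(1).normal(0, 0.05, 60)
        labels = np.repeat([0, 1], 30)
        assert q_significance(y, labels, method="noncentral_f") < 0.01

    def test_small_n_perm_rejected(self):
        with pytest.raises(ValueError):
            q_significance([1, 2, 3, 4], [0, 0, 1, 1], n_perm=10)


class TestInteraction:
    def test_constant_second_factor_reduces_to_first(self):
        rng = np.random.default_rng(27)
        y = rng.normal(size=30)
        a = rng.integers(0, 3, 30)
        b = np.zeros(30, dtype=int)
        assert interaction_q(y, a, b) == pytest.approx(factor_q(y, a))

    def test_identical_factors_reduce_to_single(self):
        rng = np.random.default_rng(28)
        y = rng.normal(size=30)
        a = rng.integers(0, 3, 30)
        assert interaction_q(y, a, a) == pytest.approx(factor_q(y, a))

    def test_equals_factor_q_on_explicit_pair_labels(self):
        rng = np.random.default_rng(29)
        y = rng.normal(size=40)
        a = rng.integers(0, 3, 40)
        b = rng.integers(0, 4, 40)
        pairs = [f"{u}|{v}" for u, v in zip(a, b)]
        assert interaction_q(y, a, b) == pytest.approx(factor_q(y, pairs), abs=1e-12)

    def test_refinement_monotonicity(self):
        rng = np.random.default_rng(30)
        for _ in range(200):
            n = int(rng.integers(6, 80))
            y = rng.normal(size=n)
            a = rng.integers(0, rng.integers(2, 5), n)
            b = rng.integers(0, rng.integers(2, 5), n)
            qa, qb = factor_q(y, a), factor_q(y, b)
            qab = interaction_q(y, a, b)
            assert qab >= max(qa, qb) - 1e-12


class TestInteractionTaxonomy:
    @pytest.mark.parametrize("qa,qb,qab,expect", [
        (0.3, 0.4, 0.5, "double-factor enhancement"),
        (0.3, 0.4, 0.8, "nonlinear enhancement"),
        (0.3, 0.4, 0.2, "nonlinear weakening"),
        (0.3, 0.4, 0.7, "independence"),
        (0.3, 0.4, 0.35, "single-factor nonlinear weakening"),
    ])
    def test_five_categories(self, qa, qb, qab, expect):
        assert classify_interaction(qa, qb, qab) == expect

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_interaction(0.3, 1.2, 0.5)

    def test_star_coding_thresholds(self):
        assert significance_stars(0.005) == "***"
        assert significance_stars(0.02) == "**"
        assert significance_stars(0.07) == "*"
        assert significance_stars(0.2) == ""


class TestRunDetector:
    def _table(self, target_q=0.76, n=1600, seed=0):
        import pandas as pd

        from vegdyn.geodetector import SampleTable

        rng = np.random.default_rng(seed)
        strata = rng.integers(1, 6, n)
        y = make_stratified_response(QDesign(strata=strata, target_q=target_q, seed=seed))
        noise_factor = rng.normal(size=n)
        df = pd.DataFrame({
            "point_id": np.arange(n), "x": rng.random(n), "y": rng.random(n),
            "response": y, "designed": strata.astype(float), "noise": noise_factor,
        })
        return SampleTable(df, categorical=("designed",))

    def test_designed_q_recovered(self):
        det = run_detector(self._table(), n_perm=99, seed=1)
        assert det.q_by_factor["designed"] == pytest.approx(0.76, abs=0.05)
        assert det.q_by_factor["noise"] < 0.05

    def test_interaction_matrix_symmetric_with_categories(self):
        det = run_detector(self._table(n=400), n_perm=99, seed=2)
        iq = det.interaction_q
        assert iq.loc["designed", "noise"] == iq.loc["noise", "designed"]
        assert det.interaction_class.loc["designed", "noise"] in {
            "independence", "nonlinear enhancement", "double-factor enhancement",
            "nonlinear weakening", "single-factor nonlinear weakening",
        }
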