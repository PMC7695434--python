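"""Comparison statistics: acceleration, test error, regression residuals,
Williams and Welch tests, BH adjustment, cohort evaluation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pediclocks.evaluation import adjust_linear, evaluate_clocks
from pediclocks.stats import (
    age_acceleration,
    bh_adjust,
    fit_age_regression,
    welch_t_test,
    williams_test,
)
from pediclocks.stats import residual_se_test as variance_ratio_test
from pediclocks.stats import test_error as median_abs_error
from pediclocks.types import AgeEstimates, ESTIMATE_COLUMNS, SampleSheet


def _estimates(sample_ids, meth, chron, clock="toy", score=False):
    meth = np.asarray(meth, dtype=float)
    chron = np.asarray(chron, dtype=float)
    return AgeEstimates(
        pd.DataFrame(
            {
                "sample_id": list(sample_ids),
                "clock": clock,
                "native_value": meth,
                "methylation_age_years": np.nan if score else meth,
                "chronological_age_years": chron,
                "acceleration_years": np.nan if score else meth - chron,
                "score": meth if score else np.nan,
                "probe_coverage": 1.0,
            },
            columns=ESTIMATE_COLUMNS,
        )
    )


class TestAccelerationAndTestError:
    def test_acceleration_is_elementwise_difference(self):
        out = age_acceleration([10.0, 3.0, 5.0], [8.0, 10.0, 5.0])
        assert out.tolist() == [2.0, -7.0, 0.0]

    def test_acceleration_propagates_missing(self):
        out = age_acceleration([np.nan, 2.0], [1.0, 1.0])
        assert np.isnan(out[0]) and out[1] == 1.0

    @pytest.mark.parametrize(
        "diffs, expected",
        [([1.0, -2.0, 3.0], 2.0), ([1.0, -3.0], 2.0), ([0.0, 0.0], 0.0)],
    )
    def test_median_absolute_difference(self, diffs, expected):
        chron = np.zeros(len(diffs))
        assert median_abs_error(np.asarray(diffs), chron) == pytest.approx(expected)


class TestAgeRegression:
    def test_perfect_fit(self):
        chron = np.linspace(0, 18, 20)
        fit = fit_age_regression(chron, 2 * chron + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.residual_se == pytest.approx(0.0, abs=1e-10)

    def test_residual_se_invariant_under_affine_shift(self):
        rng = np.random.default_rng(0)
        chron = rng.uniform(0, 18, 50)
        meth = chron + rng.normal(0, 2, 50)
        base = fit_age_regression(chron, meth).residual_se
        for a, b in [(5.0, 0.0), (0.0, 3.0), (-2.5, 0.7), (100.0, -4.0)]:
            shifted = fit_age_regression(chron, meth + a + b * chron)
            assert shifted.residual_se == pytest.approx(base, abs=1e-8)

    def test_residual_se_estimates_noise_sd(self):
        rng = np.random.default_rng(1)
        chron = rng.uniform(0, 18, 500)
        sigma = 2.5
        fit = fit_age_regression(chron, chron + rng.normal(0, sigma, 500))
        assert fit.residual_se == pytest.approx(sigma, rel=0.10)

    def test_constant_chronological_age_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_age_regression(np.full(5, 3.0), np.arange(5.0))


class TestWilliams:
    def test_equal_correlations_give_zero_statistic(self):
        t, p = williams_test(0.6, 0.6, 0.4, 30)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_antisymmetric_in_swapped_correlations(self):
        t1, p1 = williams_test(0.8, 0.5, 0.4, 40)
        t2, p2 = williams_test(0.5, 0.8, 0.4, 40)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_type_one_error_calibrated_under_null(self):
        # trivariate normal with equal population correlations to the shared
        # variable; empirical rejection at alpha = 0.05 over 2000 replicates
        rng = np.random.default_rng(2024)
        rho, rkh = 0.5, 0.3
        C = np.array([[1, rho, rho], [rho, 1, rkh], [rho, rkh, 1]])
        L = np.linalg.cholesky(C)
        n, B = 50, 2000
        rej = 0
        for _ in range(B):
            X = rng.standard_normal((n, 3)) @ L.T
            R = np.corrcoef(X.T)
            _, p = williams_test(R[0, 1], R[0, 2], R[1, 2], n)
            rej += p < 0.05
        assert abs(rej / B - 0.05) <= 0.015

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError):
            williams_test(1.0, 0.5, 0.3, 30)
        with pytest.raises(ValueError):
            williams_test(0.5, 0.4, 0.3, 3)


class TestWelch:
    def test_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0])
        t, p = welch_t_test(a, a)
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_large_shift_is_overwhelming(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 5, 50)
        b = rng.normal(10, 5, 50)
        _, p = welch_t_test(a, b)
        assert p < 1e-10

    def test_agrees_with_exact_permutation_oracle(self):
        # enumerate all 6-6 splits; permutation p of |t| vs the Welch p
        rng = np.random.default_rng(7)
        for _ in range(8):
            a = rng.normal(0, 1, 6)
            b = rng.normal(0.8, 1.3, 6)
            t_obs, p_welch = welch_t_test(a, b)
            pooled = np.concatenate([a, b])
            count = total = 0
            for comb in itertools.combinations(range(12), 6):
                mask = np.zeros(12, bool)
                mask[list(comb)] = True
                t_perm, _ = welch_t_test(pooled[mask], pooled[~mask])
                count += abs(t_perm) >= abs(t_obs) - 1e-12
                total += 1
            assert abs(p_welch - count / total) <= 0.1

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [1.0, 2.0])


class TestResidualSeTest:
    def test_identical_residuals(self):
        r = np.random.default_rng(4).normal(0, 1, 30)
        F, p = variance_ratio_test(r, r)
        assert F == pytest.approx(1.0) and p == pytest.approx(1.0)

    def test_detects_threefold_spread(self):
        rng = np.random.default_rng(5)
        _, p = variance_ratio_test(rng.normal(0, 1, 100), rng.normal(0, 3, 100))
        assert p < 1e-6

    def test_swap_inverts_statistic_keeps_p(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 40), rng.normal(0, 2, 50)
        F1, p1 = variance_ratio_test(a, b)
        F2, p2 = variance_ratio_test(b, a)
        assert F1 == pytest.approx(1 / F2)
        assert p1 == pytest.approx(p2)


def _bh_brute(p):
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        adj[i] = prev
    return adj


class TestBHAdjust:
    def test_hand_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=6)
    )
    def test_matches_brute_force_step_up(self, pvals):
        assert np.allclose(bh_adjust(pvals), _bh_brute(pvals))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=6)
    )
    def test_dominates_input_and_capped(self, pvals):
        adj = bh_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-15)
        assert np.all(adj <= 1.0)

    def test_permutation_invariance_up_to_reorder(self):
        p = [0.04, 0.001, 0.9, 0.2, 0.05, 0.012]
        base = bh_adjust(p)
        for perm in itertools.permutations(range(6)):
            out = bh_adjust([p[i] for i in perm])
            assert np.allclose([out[perm.index(i)] for i in range(6)], base)


class TestEvaluateClocks:
    @staticmethod
    def _two_clock_estimates(seed=0, sd_good=1.0, sd_bad=8.0, n=150):
        rng = np.random.default_rng(seed)
        chron = rng.uniform(0, 18, n)
        ids = [f"s{i}" for i in range(n)]
        good = _estimates(ids, chron + rng.normal(0, sd_good, n), chron, clock="good")
        bad = _estimates(ids, chron + rng.normal(0, sd_bad, n), chron, clock="bad")
        return AgeEstimates.concat([good, bad]), chron, ids

    def test_identical_clocks_not_flagged(self):
        rng = np.random.default_rng(1)
        chron = rng.uniform(0, 18, 50)
        meth = chron + rng.normal(0, 2, 50)
        ids = [f"s{i}" for i in range(50)]
        est = AgeEstimates.concat(
            [_estimates(ids, meth, chron, "a"), _estimates(ids, meth, chron, "b")]
        )
        _, contrasts = evaluate_clocks(est)
        will = contrasts[contrasts["kind"] == "williams"]
        assert (will["adj_p_value"] == 1.0).all()

    def test_better_clock_wins_williams_contrast(self):
        wins = 0
        for seed in range(20):
            est, _, _ = self._two_clock_estimates(seed)
            _, contrasts = evaluate_clocks(est)
            will = contrasts[contrasts["kind"] == "williams"].iloc[0]
            wins += will["adj_p_value"] < 0.05
        assert wins >= 19

    def test_score_only_clock_excluded_from_acceleration(self):
        rng = np.random.default_rng(2)
        chron = rng.uniform(0, 18, 30)
        ids = [f"s{i}" for i in range(30)]
        est = AgeEstimates.concat(
            [
                _estimates(ids, chron + 1, chron, "ager"),
                _estimates(ids, rng.uniform(0, 1, 30), chron, "mitotic", score=True),
            ]
        )
        metrics, _ = evaluate_clocks(est)
        by_clock = metrics.set_index("clock")
        assert np.isnan(by_clock.loc["mitotic", "acceleration_mean"])
        assert np.isnan(by_clock.loc["mitotic", "test_error_years"])
        assert np.isfinite(by_clock.loc["mitotic", "pearson_r"])
        assert np.isfinite(by_clock.loc["ager", "acceleration_mean"])

    def test_sample_order_invariance(self):
        est, chron, ids = self._two_clock_estimates(3)
        perm = est.table.sample(frac=1.0, random_state=0).reset_index(drop=True)
        m1, c1 = evaluate_clocks(est)
        m2, c2 = evaluate_clocks(AgeEstimates(perm))
        pd.testing.assert_frame_equal(m1, m2)
        pd.testing.assert_frame_equal(
            c1.sort_values("contrast").reset_index(drop=True),
            c2.sort_values("contrast").reset_index(drop=True),
        )

    def test_group_contrasts_with_bh_families(self):
        rng = np.random.default_rng(4)
        n = 90
        chron = rng.uniform(0, 18, n)
        ids = [f"s{i}" for i in range(n)]
        groups = np.array(["g1", "g2", "g3"])[np.arange(n) % 3]
        offset = np.where(groups == "g3", 12.0, 0.0)
        est = _estimates(ids, chron + offset + rng.normal(0, 2, n), chron)
        sheet = SampleSheet(
            pd.DataFrame(
                {"age_years": chron, "group": groups}, index=pd.Index(ids)
            )
        )
        _, contrasts = evaluate_clocks(est, sheet)
        welch = contrasts[contrasts["kind"] == "welch_t"].set_index("contrast")
        assert welch.loc["toy: g1 vs g3", "adj_p_value"] < 0.05
        assert welch.loc["toy: g2 vs g3", "adj_p_value"] < 0.05
        assert welch.loc["toy: g1 vs g2", "adj_p_value"] > 0.05
        assert (welch["family"] == "cohort/groups/toy").all()


class TestAdjustLinear:
    def test_identity_when_already_calibrated(self):
        chron = np.linspace(1, 18, 30)
        est = _estimates([f"s{i}" for i in range(30)], chron, chron)
        out = adjust_linear(est)
        assert np.allclose(out.table["methylation_age_years"], chron)

    def test_affine_miscalibration_fully_corrected(self):
        chron = np.linspace(1, 18, 30)
        est = _estimates([f"s{i}" for i in range(30)], 0.5 * chron + 3, chron)
        out = adjust_linear(est)
        assert np.allclose(out.table["methylation_age_years"], chron)

    def test_pearson_r_unchanged(self):
        rng = np.random.default_rng(5)
        chron = rng.uniform(0, 18, 60)
        meth = 0.7 * chron + 4 + rng.normal(0, 1.5, 60)
        est = _estimates([f"s{i}" for i in range(60)], meth, chron)
        out = adjust_linear(est)
        r0 = np.corrcoef(chron, meth)[0, 1]
        r1 = np.corrcoef(chron, out.table["methylation_age_years"])[0, 1]
        assert r1 == pytest.approx(r0)
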