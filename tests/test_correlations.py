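import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import lexichain as lx


def mvn(corr, n, seed):
    L = np.linalg.cholesky(np.asarray(corr))
    return np.random.default_rng(seed).standard_normal((n, len(corr))) @ L.T


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        res = lx.pearson(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.p == 0.0

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = rng.standard_normal(25)
            y = rng.standard_normal(25) + 0.4 * x
            res = lx.pearson(x, y)
            sp_r, sp_p = stats.pearsonr(x, y)
            assert res.r == pytest.approx(sp_r, abs=1e-12)
            assert res.p == pytest.approx(sp_p, rel=1e-9)

    def test_sum_of_products_oracle(self):
        x = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
        y = np.array([3.0, 7.0, 1.0, 9.0, 4.0])
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert lx.pearson(x, y).r == pytest.approx(expected, abs=1e-12)

    def test_weakest_printed_correlation_is_significant(self):
        # r = 0.56 at n = 41 -> p ~ 1.4e-4 < 0.001
        p = lx.partial_p(0.56, 41, n_controls=0)
        assert p < 0.001
        assert p == pytest.approx(1.4e-4, rel=0.05)

    def test_zero_variance_and_short_input_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            lx.pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="at least 3"):
            lx.pearson([1.0, 2.0], [1.0, 2.0])

    def test_p_monotone_in_r_and_n(self):
        ps_r = [lx.partial_p(r, 41, 0) for r in (0.2, 0.4, 0.6, 0.8)]
        assert ps_r == sorted(ps_r, reverse=True)
        ps_n = [lx.partial_p(0.4, n, 0) for n in (10, 20, 40, 80)]
        assert ps_n == sorted(ps_n, reverse=True)


class TestPartialCorrelation:
    def test_printed_worked_example(self):
        res = lx.partial_correlation_from_r(0.76, 0.72, 0.57, 41)
        assert round(res.r_partial, 2) == 0.61
        assert res.df == 38

    def test_uncorrelated_control_leaves_r_unchanged(self):
        res = lx.partial_correlation_from_r(0.45, 0.0, 0.0, 30)
        assert res.r_partial == pytest.approx(0.45)

    def test_equals_residual_regression_correlation(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            z = rng.standard_normal(40)
            x = 0.5 * z + rng.standard_normal(40)
            y = 0.3 * z + rng.standard_normal(40)
            res = lx.partial_correlation(x, y, z)
            bx = np.polyfit(z, x, 1)
            by = np.polyfit(z, y, 1)
            rx = x - np.polyval(bx, z)
            ry = y - np.polyval(by, z)
            oracle = lx.pearson(rx, ry).r
            assert res.r_partial == pytest.approx(oracle, abs=1e-10)

    def test_matches_pingouin(self):
        X = mvn([[1, 0.6, 0.4], [0.6, 1, 0.5], [0.4, 0.5, 1]], 60, seed=4)
        df = pd.DataFrame(X, columns=["x", "y", "z"])
        ours = lx.partial_correlation(df["x"], df["y"], df["z"])
        ref = pg.partial_corr(df, x="x", y="y", covar="z")
        assert ours.r_partial == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert ours.p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)

    def test_non_psd_triad_rejected(self):
        with pytest.raises(ValueError, match="positive semi-definite"):
            lx.partial_correlation_from_r(0.9, -0.9, 0.9, 30)


class TestPartialP:
    def test_printed_nonsignificant_partial(self):
        p = lx.partial_p(0.24, 41, 1)
        assert f"{p:.2f}" == "0.14"

    def test_printed_significant_partial(self):
        p = lx.partial_p(0.61, 41, 1)
        assert p < 0.001
        assert p == pytest.approx(2.93e-5, rel=0.01)

    def test_zero_partial_gives_p_one(self):
        assert lx.partial_p(0.0, 41, 1) == pytest.approx(1.0)

    def test_degenerate_df_rejected(self):
        with pytest.raises(ValueError, match="degrees of freedom"):
            lx.partial_p(0.5, 3, 1)


class TestFisherZ:
    @given(st.floats(min_value=-0.999, max_value=0.999))
    def test_transform_and_inverse_are_mutual(self, r):
        assert lx.fisher_z_inv(lx.fisher_z(r)) == pytest.approx(r, abs=1e-12)


class TestDependentComparison:
    def test_equal_correlations_give_null_result(self):
        res = lx.compare_dependent_overlapping(0.6, 0.6, 0.4, 41)
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_statistic_antisymmetric(self):
        a = lx.compare_dependent_overlapping(0.83, 0.76, 0.56, 41)
        b = lx.compare_dependent_overlapping(0.76, 0.83, 0.56, 41)
        assert a.statistic == pytest.approx(-b.statistic)

    @pytest.mark.parametrize("method", ["steiger_z", "williams_t"])
    def test_adjacent_level_contrast_not_significant(self, method):
        # printed pattern: 0.83 vs 0.76 sharing the middle task -> p ~ 0.35
        res = lx.compare_dependent_overlapping(0.83, 0.76, 0.56, 41, method=method)
        assert 0.30 < res.p < 0.40

    @pytest.mark.parametrize("method", ["steiger_z", "williams_t"])
    def test_nonadjacent_contrasts_significant(self, method):
        strong = lx.compare_dependent_overlapping(0.83, 0.56, 0.76, 41, method=method)
        assert strong.p < 0.001
        weak = lx.compare_dependent_overlapping(0.56, 0.76, 0.83, 41, method=method)
        assert weak.p < 0.01

    def test_unit_correlation_rejected(self):
        with pytest.raises(ValueError, match="Fisher transform"):
            lx.compare_dependent_overlapping(1.0, 0.5, 0.4, 41)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            lx.compare_dependent_overlapping(0.5, 0.4, 0.3, 8)


class TestPermutationCompare:
    def test_identical_variables_give_p_one(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(50)
        y = rng.standard_normal(50)
        res = lx.permutation_compare(x, y, y, n_perm=1000, seed=0)
        assert res.delta_r == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_null_p_values_are_uniform(self):
        """With equal population correlations the permutation p-value is
        uniform (KS check over repeated draws)."""
        corr = [[1, 0.5, 0.5], [0.5, 1, 0.6], [0.5, 0.6, 1]]
        rng = np.random.default_rng(99)
        ps = []
        for _ in range(150):
            X = mvn(corr, 100, seed=rng.integers(2**31))
            ps.append(lx.permutation_compare(X[:, 0], X[:, 1], X[:, 2],
                                             n_perm=1000, seed=rng).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_agrees_with_steiger_under_effect(self):
        X = mvn([[1, 0.6, 0.3], [0.6, 1, 0.4], [0.3, 0.4, 1]], 200, seed=7)
        r = np.corrcoef(X, rowvar=False)
        p_z = lx.compare_dependent_overlapping(r[0, 1], r[0, 2], r[1, 2], 200).p
        p_perm = lx.permutation_compare(X[:, 0], X[:, 1], X[:, 2],
                                        n_perm=5000, seed=1).p
        assert abs(p_z - p_perm) < 0.01


class TestCorrelationMatrixOp:
    def _std(self, X):
        return pd.DataFrame(X, columns=list(lx.TASKS))

    def test_duplicated_column_gives_unit_correlation(self):
        rng = np.random.default_rng(8)
        base = rng.standard_normal(20)
        X = np.column_stack([base, base, rng.standard_normal(20), rng.standard_normal(20)])
        out = lx.correlation_matrix(self._std(X))
        assert out.r_matrix.loc["NRT", "ADT"] == pytest.approx(1.0)

    def test_structure_and_consistency(self):
        corr = [
            [1.0, 0.78, 0.72, 0.57],
            [0.78, 1.0, 0.83, 0.56],
            [0.72, 0.83, 1.0, 0.76],
            [0.57, 0.56, 0.76, 1.0],
        ]
        X = mvn(corr, 600, seed=9)
        out = lx.correlation_matrix(self._std(X))
        m = out.r_matrix.to_numpy()
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 1.0)
        # partials are reproducible from the sample r's
        for (a, b), res in out.partials.items():
            expected = lx.partial_correlation_from_r(
                float(out.r_matrix.loc[a, b]),
                float(out.r_matrix.loc[a, "NRT"]),
                float(out.r_matrix.loc[b, "NRT"]),
                out.n,
            )
            assert res.r_partial == pytest.approx(expected.r_partial, abs=1e-12)
        assert len(out.comparisons) == 3
        assert {c.shared for c in out.comparisons} == {"ADT", "LDT", "GDT"}

    def test_printed_matrix_recovers_printed_partials(self):
        """Feeding the published pairwise correlations through the partial
        formula reproduces the published partial triad (the third value
        recomputes to 0.22 from the rounded inputs)."""
        r = {"AL": 0.83, "AG": 0.56, "LG": 0.76, "NA": 0.78, "NL": 0.72, "NG": 0.57}
        p_al = lx.partial_correlation_from_r(r["AL"], r["NA"], r["NL"], 41).r_partial
        p_lg = lx.partial_correlation_from_r(r["LG"], r["NL"], r["NG"], 41).r_partial
        p_ag = lx.partial_correlation_from_r(r["AG"], r["NA"], r["NG"], 41).r_partial
        assert p_al == pytest.approx(0.61, abs=0.01)
        assert p_lg == pytest.approx(0.61, abs=0.005)
        assert 0.22 <= round(p_ag, 2) <= 0.24

    def test_missing_task_column_rejected(self):
        X = np.random.default_rng(1).standard_normal((10, 3))
        df = pd.DataFrame(X, columns=["NRT", "ADT", "LDT"])
        with pytest.raises(ValueError, match="missing task column"):
            lx.correlation_matrix(df)

    def test_synthetic_cohort_matches_generative_oracle(
        self, default_model, default_walk
    ):
        """Sample correlations of a large simulated cohort sit within
        +-0.05 of the Monte-Carlo implied matrix."""
        design = lx.ExperimentDesign(n_participants=300)
        trials = lx.simulate_experiment(default_model, design, default_walk, seed=77)
        res = lx.run_analysis(trials)
        implied = lx.implied_task_rt_correlations(
            default_model, default_walk, oracle_n=100_000, seed=78
        )
        diff = (res.correlations.r_matrix - implied).abs().to_numpy().max()
        assert diff < 0.05
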