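"""PCA clustering, Cohen's d, sample-size inversion and rm-correlation."""

import numpy as np
import pandas as pd
import pytest

from painsgrid import (
    DegenerateInputError,
    baseline_table,
    cohens_d,
    normal_approx_power,
    pca_measures,
    rm_corr,
    sample_size,
    two_sample_t_power,
)


def _correlated_triplet(n=4000, seed=0):
    rng = np.random.default_rng(seed)
    shared = rng.normal(size=n)
    return pd.DataFrame(
        {"a": shared, "b": shared, "c": rng.normal(size=n)}
    )


class TestPCA:
    def test_perfect_pair_dominates_pc1(self):
        """Closed form: corr matrix [[1,1,0],[1,1,0],[0,0,1]] has eigenpairs
        (2, (1,1,0)/sqrt2) and (1, (0,0,1)): loadings (1,1,0) and (0,0,1)."""
        res = pca_measures(_correlated_triplet())
        L = res.loadings
        assert L.loc["a", "PC1"] == pytest.approx(1.0, abs=0.02)
        assert L.loc["b", "PC1"] == pytest.approx(1.0, abs=0.02)
        assert abs(L.loc["c", "PC1"]) < 0.05
        assert abs(L.loc["c", "PC2"]) == pytest.approx(1.0, abs=0.02)
        assert res.explained_variance[0] == pytest.approx(2.0, abs=0.05)

    def test_row_permutation_invariance(self, default_series):
        table = baseline_table(default_series)
        shuffled = table.sample(frac=1, random_state=3).reset_index(drop=True)
        a = pca_measures(table).loadings
        b = pca_measures(shuffled).loadings
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-9)

    def test_loadings_reproduce_correlation_matrix(self, default_series):
        table = baseline_table(default_series)
        res = pca_measures(table)
        L = res.loadings.to_numpy()
        R = table.drop(columns="patient_id").corr().to_numpy()
        assert np.allclose(L @ L.T, R, atol=1e-8)

    def test_explained_ratios_and_score_orthogonality(self, default_series):
        res = pca_measures(baseline_table(default_series))
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0)
        assert np.all(np.diff(res.explained_variance_ratio) <= 1e-12)
        S = res.scores.to_numpy()
        cov = np.cov(S, rowvar=False)
        off = cov - np.diag(np.diag(cov))
        assert np.allclose(off, 0, atol=1e-8)

    def test_constant_column_named_in_error(self):
        table = pd.DataFrame({"a": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(DegenerateInputError, match="flat"):
            pca_measures(table)


class TestCohensD:
    def test_identical_groups(self):
        res = cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.d == 0.0

    def test_separated_groups_sign_convention(self):
        res = cohens_d([1.0, 1.01, 0.99, 1.0], [0.0, 0.01, -0.01, 0.0])
        assert res.d > 50  # near-zero pooled SD inflates |d|
        assert cohens_d([0.0, 0.01, -0.01, 0.0], [1.0, 1.01, 0.99, 1.0]).d < 0

    def test_hand_computed_toy_table(self):
        a = np.array([-40.0, -25.0, -31.0, -22.0])
        s = np.array([-10.0, -5.0, -12.0, -3.0])
        sp = np.sqrt(((3 * a.var(ddof=1)) + 3 * s.var(ddof=1)) / 6)
        assert cohens_d(a, s).d == pytest.approx((a.mean() - s.mean()) / sp,
                                                 abs=1e-12)

    def test_shift_invariance_and_sign_equivariance(self):
        rng = np.random.default_rng(1)
        a, s = rng.normal(1, 1, 20), rng.normal(0, 1, 20)
        d0 = cohens_d(a, s).d
        assert cohens_d(a + 7, s + 7).d == pytest.approx(d0)
        assert cohens_d(-a, -s).d == pytest.approx(-d0)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(DegenerateInputError):
            cohens_d([2.0, 2.0, 2.0], [2.0, 2.0])


class TestSampleSize:
    def test_printed_design_sizes(self):
        """Per-group n for the published effect sizes: 44 (d=0.60, normal
        approximation) and 62 (d=0.51, noncentral-t search)."""
        assert sample_size(0.60, 0.80, 0.05, "normal").n_per_group == 44
        assert sample_size(0.51, 0.80, 0.05, "t").n_per_group == 62

    def test_t_method_matches_statsmodels_solver(self):
        import statsmodels.stats.power as smp

        for d in (0.31, 0.51, 0.60, 1.0):
            ours = sample_size(d, 0.80, 0.05, "t").n_per_group
            ref = int(np.ceil(smp.tt_ind_solve_power(effect_size=d, alpha=0.05,
                                                     power=0.80)))
            assert ours == ref

    def test_t_never_below_normal(self):
        for d in (0.2, 0.35, 0.6, 1.2):
            assert (
                sample_size(d, 0.80, 0.05, "t").n_per_group
                >= sample_size(d, 0.80, 0.05, "normal").n_per_group
            )

    def test_inverse_square_scaling(self):
        small = sample_size(0.3, 0.80, 0.05, "normal").n_per_group
        large = sample_size(0.6, 0.80, 0.05, "normal").n_per_group
        assert small / large == pytest.approx(4.0, rel=0.05)

    def test_achieved_power_meets_target(self):
        for d in (0.4, 0.51):
            n = sample_size(d, 0.80, 0.05, "t").n_per_group
            assert two_sample_t_power(n, d) >= 0.80
            assert two_sample_t_power(n - 1, d) < 0.80

    def test_null_effect_rejected(self):
        with pytest.raises(DegenerateInputError):
            sample_size(0.0)

    def test_power_functions_monotone_in_n(self):
        ns = np.array([10, 20, 40, 80])
        pt = [two_sample_t_power(n, 0.5) for n in ns]
        pn = [normal_approx_power(n, 0.5) for n in ns]
        assert all(np.diff(pt) > 0) and all(np.diff(pn) > 0)


class TestRepeatedMeasuresCorrelation:
    def test_matches_pingouin(self, default_series):
        pingouin = pytest.importorskip("pingouin")
        ours = rm_corr(default_series, "vas", "panas_pos")
        ref = pingouin.rm_corr(data=default_series, x="vas", y="panas_pos",
                               subject="patient_id")
        assert ours["r"] == pytest.approx(float(ref["r"].iloc[0]), abs=1e-6)
        assert ours["dof"] == int(ref["dof"].iloc[0])
        assert ours["p"] == pytest.approx(float(ref["pval"].iloc[0]), rel=1e-6)

    def test_removes_between_patient_association(self):
        # x and y share only patient-level means: rm correlation ~ 0
        rng = np.random.default_rng(12)
        rows = []
        for i in range(40):
            base = rng.normal()
            for d in range(6):
                rows.append((f"p{i}", d, base + rng.normal(0, 0.5),
                             base + rng.normal(0, 0.5)))
        df = pd.DataFrame(rows, columns=["patient_id", "day", "x", "y"])
        assert abs(rm_corr(df, "x", "y")["r"]) < 0.15
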