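import warnings

import numpy as np
import pytest
from scipy import stats

from cpgset_ewas.io_formats import ValidationError
from cpgset_ewas.kinship import KinshipMatrix, kinship_from_pedigree
from cpgset_ewas.synthetic_cohort import SimConfig, simulate_pedigree
from cpgset_ewas.vc_score import (
    davies_pvalue,
    fit_null_lm,
    fit_null_lmm,
    vc_score_test,
)


def identity_kinship(n):
    return KinshipMatrix(0.5 * np.eye(n), [f"s{i}" for i in range(n)])


def score_test_oracle(x, C, z):
    """Single-covariate score test with the null variance estimate."""
    n = len(x)
    M = np.eye(n) - C @ np.linalg.solve(C.T @ C, C.T)
    sigma2 = (x @ M @ x) / (n - C.shape[1])
    zc = z - z.mean()
    stat = (zc @ M @ x) ** 2 / ((zc @ M @ zc) * sigma2)
    return float(stats.chi2.sf(stat, 1))


class TestFitNullLm:
    def test_intercept_only(self):
        x = np.array([1.0, 2.0, 3.0, 6.0])
        nm = fit_null_lm(x, np.ones((4, 1)))
        assert nm.beta[0] == pytest.approx(x.mean())
        assert nm.sigma_e2 == pytest.approx(x.var(ddof=1))

    def test_projection_annihilates_covariates(self):
        rng = np.random.default_rng(0)
        C = np.column_stack([np.ones(30), rng.standard_normal((30, 2))])
        nm = fit_null_lm(rng.standard_normal(30), C)
        assert np.abs(nm.P0 @ C).max() < 1e-8

    def test_exact_fit_rejected(self):
        rng = np.random.default_rng(1)
        C = np.column_stack([np.ones(10), rng.standard_normal(10)])
        x = C @ np.array([1.0, 2.0])
        with pytest.raises(ValidationError, match="degenerate"):
            fit_null_lm(x, C)

    def test_rank_deficiency_rejected(self):
        C = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(ValidationError):
            fit_null_lm(np.arange(10.0), C)


class TestFitNullLmm:
    def test_identity_kinship_collapses_to_lm(self):
        rng = np.random.default_rng(2)
        n = 80
        C = np.column_stack([np.ones(n), rng.standard_normal(n)])
        x = rng.standard_normal(n)
        lm = fit_null_lm(x, C)
        lmm = fit_null_lmm(x, C, identity_kinship(n))
        # only the total variance is identified; P0 must coincide
        assert np.abs(lm.P0 - lmm.P0).max() < 1e-6
        assert lmm.sigma_g2 + lmm.sigma_e2 == pytest.approx(lm.sigma_e2, rel=1e-6)

    def test_variance_ratio_recovery(self):
        cfg = SimConfig(n_families=40, family_structure="three_gen", seed=0)
        kin = kinship_from_pedigree(simulate_pedigree(cfg))
        d, U = kin.eig_2phi()
        L = U * np.sqrt(d)
        n = kin.n
        rng = np.random.default_rng(3)
        C = np.ones((n, 1))
        ratios = []
        for _ in range(30):
            x = L @ rng.standard_normal(n) + rng.standard_normal(n)  # (1, 1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = fit_null_lmm(x, C, kin)
            ratios.append(m.sigma_g2 / (m.sigma_g2 + m.sigma_e2))
        assert np.mean(ratios) == pytest.approx(0.5, abs=0.1)

    def test_zero_heritability_hits_boundary(self):
        cfg = SimConfig(n_families=30, family_structure="nuclear2", seed=1)
        kin = kinship_from_pedigree(simulate_pedigree(cfg))
        n = kin.n
        rng = np.random.default_rng(4)
        C = np.ones((n, 1))
        at_zero = 0
        for _ in range(20):
            x = rng.standard_normal(n)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = fit_null_lmm(x, C, kin)
            if m.sigma_g2 / (m.sigma_g2 + m.sigma_e2) < 0.05:
                at_zero += 1
        assert at_zero > 10  # majority at or near the zero boundary


class TestVcScoreTest:
    def test_single_cpg_matches_score_test(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 100
            C = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
            x = rng.standard_normal(n)
            z = 0.2 * x + rng.standard_normal(n)
            res = vc_score_test(fit_null_lm(x, C), z[:, None])
            assert res.pvalue == pytest.approx(score_test_oracle(x, C, z), abs=1e-8)

    def test_trace_identity(self):
        rng = np.random.default_rng(5)
        n, p = 60, 7
        C = np.ones((n, 1))
        nm = fit_null_lm(rng.standard_normal(n), C)
        Y = rng.standard_normal((n, p))
        res = vc_score_test(nm, Y)
        Z = Y - Y.mean(axis=0)
        trace = np.trace(nm.P0 @ (Z @ Z.T))
        assert res.eigenvalues.sum() == pytest.approx(trace, abs=1e-6)

    def test_pvalue_invariant_to_trait_scaling(self):
        rng = np.random.default_rng(6)
        n = 80
        C = np.ones((n, 1))
        x = rng.standard_normal(n)
        Y = rng.standard_normal((n, 5))
        p1 = vc_score_test(fit_null_lm(x, C), Y).pvalue
        p2 = vc_score_test(fit_null_lm(7.3 * x, C), Y).pvalue
        assert p1 == pytest.approx(p2, rel=1e-8)

    def test_family_collapse_to_unrelated(self):
        rng = np.random.default_rng(7)
        n = 90
        C = np.column_stack([np.ones(n), rng.standard_normal(n)])
        x = rng.standard_normal(n)
        Y = rng.standard_normal((n, 6))
        p_lm = vc_score_test(fit_null_lm(x, C), Y).pvalue
        p_lmm = vc_score_test(fit_null_lmm(x, C, identity_kinship(n)), Y).pvalue
        assert abs(p_lm - p_lmm) < 1e-6

    def test_permutation_null_matches_mixture(self):
        # p-values of Q over permuted traits should be uniform
        rng = np.random.default_rng(8)
        n, p = 120, 8
        C = np.ones((n, 1))
        x = rng.standard_normal(n)
        Y = rng.standard_normal((n, p)) @ np.linalg.cholesky(
            0.6 * np.eye(p) + 0.4
        ).T
        pvals = []
        for _ in range(500):
            xp = x[rng.permutation(n)]
            pvals.append(vc_score_test(fit_null_lm(xp, C), Y).pvalue)
        pvals = np.sort(pvals)
        uniform = (np.arange(1, 501) - 0.5) / 500
        assert np.corrcoef(pvals, uniform)[0, 1] > 0.99
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_constant_block_warns_and_returns_one(self):
        rng = np.random.default_rng(9)
        nm = fit_null_lm(rng.standard_normal(20), np.ones((20, 1)))
        with pytest.warns(UserWarning, match="constant"):
            res = vc_score_test(nm, np.full((20, 3), 0.5))
        assert res.pvalue == 1.0

    def test_empty_block_rejected(self):
        rng = np.random.default_rng(10)
        nm = fit_null_lm(rng.standard_normal(20), np.ones((20, 1)))
        with pytest.raises(ValidationError):
            vc_score_test(nm, np.empty((20, 0)))


class TestDaviesPvalue:
    def test_chi2_closed_forms(self):
        p1, m1 = davies_pvalue(3.841459, np.array([1.0]))
        assert p1 == pytest.approx(0.0500, abs=1e-6)
        p2, m2 = davies_pvalue(5.991465, np.array([1.0, 1.0]))
        assert p2 == pytest.approx(0.0500, abs=1e-6)

    def test_scaled_single_weight(self):
        p, _ = davies_pvalue(10.0, np.array([2.5]))
        assert p == pytest.approx(stats.chi2.sf(4.0, 1), abs=1e-10)

    def test_against_monte_carlo(self):
        lam = np.array([2.0, 1.0])
        rng = np.random.default_rng(11)
        draws = rng.standard_normal((2, 2_000_000)) ** 2
        mc = float(np.mean(lam @ draws > 10.0))
        p, method = davies_pvalue(10.0, lam)
        sd = np.sqrt(mc * (1 - mc) / 2_000_000)
        assert abs(p - mc) < 3 * sd
        assert method == "davies"

    def test_extreme_tail_falls_back_gracefully(self):
        p, method = davies_pvalue(5000.0, np.array([1.0, 0.5, 0.25]))
        assert 0 < p < 1e-100
        assert method in ("davies", "liu")

    def test_nonpositive_q(self):
        assert davies_pvalue(0.0, np.array([1.0]))[0] == 1.0

    def test_no_positive_weights_rejected(self):
        with pytest.raises(ValidationError):
            davies_pvalue(1.0, np.array([0.0, -1.0]))
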