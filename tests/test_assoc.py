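"""Kinship algebra, REML null fits, and the mixed-model Wald test against
closed-form and GLS oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from slopescan import (
    GenotypeMatrix,
    KinshipMatrix,
    compute_kinship,
    default_cross_design,
    lmm_fit_null,
    lmm_gwas,
    make_crosses,
)
from slopescan.synthdata import split_rng

from conftest import toy_variant_table


def _gm(dosages):
    d = np.asarray(dosages, dtype=float)
    return GenotypeMatrix([f"S{i}" for i in range(d.shape[0])], d)


class TestKinship:
    def test_identical_samples_identical_rows(self):
        gm = _gm([[0, 1, 2], [0, 1, 2], [2, 1, 0]])
        K = compute_kinship(gm, "centered")
        np.testing.assert_allclose(K.values[0], K.values[1])
        np.testing.assert_allclose(K.values[:, 0], K.values[:, 1])

    def test_centered_row_sums_zero(self):
        rng = split_rng(1, "k_rows")
        gm = _gm(rng.integers(0, 3, (15, 50)))
        K = compute_kinship(gm, "centered")
        np.testing.assert_allclose(K.values.sum(axis=1), 0.0, atol=1e-8 * 15)

    def test_hand_matrix_three_samples_two_markers(self):
        X = np.array([[0.0, 2.0], [1.0, 1.0], [2.0, 0.0]])
        Xc = X - X.mean(axis=0)
        expected = Xc @ Xc.T / 2
        K = compute_kinship(_gm(X), "centered")
        np.testing.assert_allclose(K.values, expected, atol=1e-12)

    def test_standardized_mean_diagonal_near_one(self):
        rng = split_rng(2, "k_diag")
        freq = rng.uniform(0.1, 0.9, 300)
        dos = (rng.random((60, 300)) < freq) + (rng.random((60, 300)) < freq)
        K = compute_kinship(_gm(dos.astype(float)), "standardized")
        assert np.mean(np.diag(K.values)) == pytest.approx(1.0, abs=0.1)

    def test_all_constant_markers_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            compute_kinship(_gm(np.ones((5, 4))), "centered")


class TestNullFit:
    def test_no_genetic_variance_gives_small_lambda(self):
        """y with σ²_g = 0: λ̂ stays near the boundary in ≥ 90% of seeds.

        The clone-replicate covariance (100 clones × 5 ramets, the field
        scale of a clonal trial) identifies the variance ratio well enough
        for the boundary estimate to be stable.
        """
        q, r = 120, 8
        Z = np.kron(np.eye(q), np.ones((r, 1)))
        H = Z @ Z.T
        K = KinshipMatrix(H, "centered", [f"O{i}" for i in range(q * r)])
        ok = 0
        for seed in range(20):
            rng = split_rng(seed, "null_lam_y")
            y = rng.standard_normal(q * r)
            fit = lmm_fit_null(y, np.ones((q * r, 1)), K)
            ok += fit.lambda_ < 0.05
        assert ok >= 18

    def test_identity_kinship_matches_anova_closed_form(self):
        """K from a replicated-group design: λ̂ agrees with one-way ANOVA REML."""
        rng = split_rng(4, "anova")
        q, r = 25, 4
        s2g_true, s2e_true = 2.0, 1.0
        g = rng.normal(0, np.sqrt(s2g_true), q)
        y = np.repeat(g, r) + rng.normal(0, np.sqrt(s2e_true), q * r)
        Z = np.kron(np.eye(q), np.ones((r, 1)))
        H = Z @ Z.T  # genotype-replicate covariance structure
        fit = lmm_fit_null(y, np.ones((q * r, 1)),
                           KinshipMatrix(H, "centered", [f"O{i}" for i in range(q * r)]))
        # balanced one-way REML closed form: σ̂²_e = MSW, σ̂²_g = (MSB − MSW)/r
        ym = y.reshape(q, r)
        msw = np.sum((ym - ym.mean(1, keepdims=True)) ** 2) / (q * (r - 1))
        msb = r * np.sum((ym.mean(1) - ym.mean()) ** 2) / (q - 1)
        lam_closed = max(0.0, (msb - msw) / r) / msw
        assert fit.lambda_ == pytest.approx(lam_closed, rel=1e-3, abs=1e-3)

    def test_block_doubling_invariance(self):
        rng = split_rng(6, "double")
        n = 30
        A = rng.standard_normal((n, n))
        Kv = A @ A.T / n
        y = rng.standard_normal(n)
        samples = [f"S{i}" for i in range(n)]
        fit1 = lmm_fit_null(y, np.ones((n, 1)), KinshipMatrix(Kv, "centered", samples))
        K2 = np.block([[Kv, np.zeros((n, n))], [np.zeros((n, n)), Kv]])
        fit2 = lmm_fit_null(np.concatenate([y, y]), np.ones((2 * n, 1)),
                            KinshipMatrix(K2, "centered", samples + samples))
        # REML (unlike ML) is only asymptotically invariant to duplication:
        # the restricted-likelihood correction terms do not scale with n
        assert fit2.lambda_ == pytest.approx(fit1.lambda_, rel=0.05)

    def test_non_finite_y_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            lmm_fit_null(np.array([1.0, np.nan, 2.0]), np.ones((3, 1)),
                         KinshipMatrix(np.eye(3), "centered", ["a", "b", "c"]))


class TestGwas:
    def _setup(self, n=40, m=25, seed=0):
        rng = split_rng(seed, "gwas_toy")
        freq = rng.uniform(0.2, 0.8, m)
        dos = ((rng.random((n, m)) < freq) + (rng.random((n, m)) < freq)).astype(float)
        gm = _gm(dos)
        vt = toy_variant_table(np.arange(1, m + 1) * 1000)
        y = rng.standard_normal(n)
        K = KinshipMatrix(np.eye(n), "centered", gm.samples)
        return y, np.ones((n, 1)), K, gm, vt

    def test_lambda_zero_identity_k_collapses_to_ols(self):
        y, W, K, gm, vt = self._setup()
        track = lmm_gwas(y, W, K, gm, vt, fixed_lambda=0.0)
        import statsmodels.api as sm

        for j in range(gm.n_variants):
            X = sm.add_constant(gm.dosages[:, j])
            res = sm.OLS(y, X).fit()
            assert track["p"].iloc[j] == pytest.approx(res.pvalues[1], abs=1e-8)
            assert track["beta"].iloc[j] == pytest.approx(res.params[1], abs=1e-8)

    def test_orthogonal_snp_gives_zero_beta(self):
        y, W, K, gm, vt = self._setup()
        # construct x exactly orthogonal to y after centering
        y = y - y.mean()
        x = np.linalg.svd(np.outer(y, y))[0][:, -1]
        x = x - x.mean()
        x -= (x @ y) / (y @ y) * y
        gm2 = GenotypeMatrix(gm.samples, x[:, None])
        track = lmm_gwas(y, W, K, gm2, toy_variant_table([100]), fixed_lambda=0.0)
        assert track["beta"].iloc[0] == pytest.approx(0.0, abs=1e-10)
        assert track["p"].iloc[0] == pytest.approx(1.0, abs=1e-8)

    def test_wald_matches_explicit_gls_on_fixed_toy(self):
        """n=6 toy with known V: β̂ and SE equal the explicit GLS formulas."""
        y = np.array([1.2, -0.4, 0.3, 2.1, -1.0, 0.8])
        x = np.array([0.0, 1.0, 2.0, 1.0, 0.0, 2.0])
        Kv = np.array(
            [[1.0, 0.5, 0.0, 0.0, 0.0, 0.0],
             [0.5, 1.0, 0.0, 0.0, 0.0, 0.0],
             [0.0, 0.0, 1.0, 0.3, 0.0, 0.0],
             [0.0, 0.0, 0.3, 1.0, 0.0, 0.0],
             [0.0, 0.0, 0.0, 0.0, 1.0, 0.0],
             [0.0, 0.0, 0.0, 0.0, 0.0, 1.0]]
        )
        lam = 0.7
        V = lam * Kv + np.eye(6)
        X = np.column_stack([np.ones(6), x])
        Vinv = np.linalg.inv(V)
        beta_gls = np.linalg.inv(X.T @ Vinv @ X) @ X.T @ Vinv @ y
        r = y - X @ beta_gls
        sigma2 = (r @ Vinv @ r) / (6 - 1 - 1)
        se_gls = np.sqrt(sigma2 * np.linalg.inv(X.T @ Vinv @ X)[1, 1])
        gm = GenotypeMatrix([f"S{i}" for i in range(6)], x[:, None])
        K = KinshipMatrix(Kv, "centered", gm.samples)
        track = lmm_gwas(y, np.ones((6, 1)), K, gm, toy_variant_table([500]),
                         fixed_lambda=lam)
        assert track["beta"].iloc[0] == pytest.approx(beta_gls[1], abs=1e-10)
        assert track["se"].iloc[0] == pytest.approx(se_gls, abs=1e-10)

    def test_constant_snp_missing_with_reason(self):
        y, W, K, gm, vt = self._setup()
        gm.dosages[:, 0] = 1.0
        track = lmm_gwas(y, W, K, gm, vt, per_snp_lambda=False)
        assert np.isnan(track["p"].iloc[0])
        assert track["reason"].iloc[0] == "constant"
        assert track["p"].iloc[1:].notna().all()

    def test_per_snp_lambda_close_to_shared_on_null_data(self):
        y, W, K, gm, vt = self._setup(n=30, m=10, seed=3)
        a = lmm_gwas(y, W, K, gm, vt, per_snp_lambda=True)
        b = lmm_gwas(y, W, K, gm, vt, per_snp_lambda=False)
        # identical model when λ̂ ≈ 0 on unstructured null data
        np.testing.assert_allclose(a["p"], b["p"], atol=0.05)


def test_kinship_mitigates_structure_inflation(neutral_pop):
    """With family structure and a polygenic trait, the genomic inflation
    factor with the kinship term is no larger than without it."""
    hs, vt, gmap = neutral_pop
    design = default_cross_design(hs.samples, seed=31)
    off, _ = make_crosses(hs, vt, gmap, design, seed=31)
    gm = off.to_dosages()
    rng = split_rng(31, "poly")
    causal = rng.choice(gm.n_variants, 60, replace=False)
    g = gm.dosages[:, causal] @ rng.normal(0, 1, 60)
    g = (g - g.mean()) / g.std()
    y = g + rng.standard_normal(gm.n_samples) * 1.0
    W = np.ones((gm.n_samples, 1))
    K = compute_kinship(gm, "centered")
    Kid = KinshipMatrix(np.eye(gm.n_samples), "centered", gm.samples)
    with_k = lmm_gwas(y, W, K, gm, vt, per_snp_lambda=False)
    without = lmm_gwas(y, W, Kid, gm, vt, fixed_lambda=0.0)

    def gif(track):
        chi = stats.chi2.isf(track["p"].dropna(), 1)
        return np.median(chi) / stats.chi2.ppf(0.5, 1)

    assert gif(with_k) <= gif(without)
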