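"""GBLUP mixed model: MME oracle, REML, backsolving and marker selection."""

import numpy as np
import pytest
from scipy import linalg, stats

from milkpred.gblup import (
    GBLUP,
    GBLUPResults,
    MixedModelError,
    SnpAssociation,
    backsolve_snp_effects,
    estimate_variance_components,
    gwas_design,
    select_markers,
    snp_pvalues,
    solve_mme,
)
from milkpred.genomics import Grm, grm_vanraden

from conftest import make_genotype_data


def _fixture(n=30, p=80, seed=0, s2a=0.5, s2h=0.2, s2e=0.8, n_batches=4):
    """Small herd with an invertible G (external allele frequencies)."""
    rng = np.random.default_rng(seed)
    geno = rng.binomial(2, rng.uniform(0.1, 0.5, p), size=(n, p)).astype(float)
    gd = make_genotype_data(geno)
    grm = grm_vanraden(gd, frequencies=rng.uniform(0.1, 0.5, p))
    dim = rng.integers(1, 7, n)
    par = rng.integers(1, 4, n)
    batch = rng.integers(0, n_batches, n)
    X, _ = gwas_design(dim, par)
    W = np.zeros((n, n_batches))
    W[np.arange(n), batch] = 1.0
    bv = rng.multivariate_normal(np.zeros(n), grm.G * s2a)
    y = (
        X @ rng.normal(size=X.shape[1])
        + W @ (rng.normal(size=n_batches) * np.sqrt(s2h))
        + bv
        + rng.normal(size=n) * np.sqrt(s2e)
    )
    return y, X, batch, W, grm


def _direct_blup(y, X, W, G, s2a, s2h, s2e):
    """Oracle: GLS fixed effects + BLUP via explicit inversion of V."""
    n = y.size
    V = G * s2a + W @ W.T * s2h + np.eye(n) * s2e
    Vi = linalg.inv(V)
    b = linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    r = y - X @ b
    return b, s2h * W.T @ Vi @ r, s2a * G @ Vi @ r


class TestSolveMme:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_direct_inversion_oracle(self, seed):
        y, X, batch, W, grm = _fixture(seed=seed)
        vc = (0.5, 0.2, 0.8)
        fit = solve_mme(y, X, batch, grm, varcomps=vc)
        b, h, a = _direct_blup(y, X, W, grm.G, *vc)
        assert np.abs(fit.fe_params - b).max() < 1e-8
        assert np.abs(fit.batch_effects - h).max() < 1e-8
        assert np.abs(fit.gebv - a).max() < 1e-8
        assert fit.mme_residual() < 1e-8

    def test_shrinkage_limit_gebv_to_zero(self):
        y, X, batch, W, grm = _fixture(seed=3)
        fit = solve_mme(y, X, batch, grm, varcomps=(1e-10, 0.2, 0.8))
        assert np.abs(fit.gebv).max() < 1e-6
        b, _, _ = _direct_blup(y, X, W, grm.G, 0.0, 0.2, 0.8)
        assert np.abs(fit.fe_params - b).max() < 1e-6

    def test_noiseless_limit_recovers_fixed_effects(self):
        y, X, batch, W, grm = _fixture(seed=4)
        b0 = np.arange(1.0, X.shape[1] + 1.0)
        fit = solve_mme(X @ b0, X, batch, grm, varcomps=(1e-10, 1e-10, 1.0))
        assert np.abs(fit.fe_params - b0).max() < 1e-6

    def test_nonconformable_raises(self):
        y, X, batch, W, grm = _fixture(seed=5)
        with pytest.raises(MixedModelError):
            GBLUP(y[:-1], X, batch, grm)


class TestReml:
    def test_single_replicate_recovery(self):
        from milkpred.simulate import SimConfig, simulate_genotypes, simulate_phenotypes

        cfg = SimConfig(n_cows=600, n_snps=700, n_qtl=50, heritability=0.4,
                        batch_variance_fraction=0.1, seed=12)
        gd = simulate_genotypes(cfg)
        ph = simulate_phenotypes(gd, cfg)
        grm = grm_vanraden(gd).blend()
        X, _ = gwas_design(ph["dim_class"], ph["parity_class"])
        (s2a, s2h, s2e), converged = estimate_variance_components(
            ph["phenotypes"][:, 0], X, ph["batch"], grm
        )
        h2 = s2a / (s2a + s2h + s2e)
        assert converged
        assert abs(h2 - 0.4) < 0.15

    def test_pure_noise_gives_small_genetic_fraction(self):
        import warnings

        rng = np.random.default_rng(13)
        y, X, batch, W, grm = _fixture(n=400, p=600, seed=13)
        y = rng.normal(size=400)  # no structure at all
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # boundary estimates may not converge
            (s2a, s2h, s2e), _ = estimate_variance_components(y, X, batch, grm)
        assert s2a / (s2a + s2h + s2e) < 0.1

    def test_zero_variance_response_raises(self):
        y, X, batch, W, grm = _fixture(seed=14)
        with pytest.raises(MixedModelError):
            estimate_variance_components(np.ones_like(y), X, batch, grm)


class _nullcontext:
    def __enter__(self):
        return self

    def __exit__(self, *a):
        return False


class TestBacksolve:
    def test_identity_m_u_equals_a(self):
        y, X, batch, W, grm = _fixture(seed=6)
        fit = solve_mme(y, X, batch, grm, varcomps=(0.5, 0.2, 0.8))
        assoc = fit.snp_effects(grm)
        assert np.abs(grm.centered @ assoc.effects - fit.gebv).max() < 1e-8

    def test_zero_gebv_gives_zero_effects(self):
        y, X, batch, W, grm = _fixture(seed=7)
        fit = solve_mme(y, X, batch, grm, varcomps=(0.5, 0.2, 0.8))
        fit.gebv = np.zeros_like(fit.gebv)
        assert np.abs(fit.snp_effects(grm).effects).max() == 0.0

    def test_single_snp_recovers_regression_slope(self):
        # one marker, G = mm'/c + tiny ridge: the backsolved effect tends to
        # the no-intercept regression slope of the GEBVs on the centred codes
        rng = np.random.default_rng(8)
        n = 20
        m = (rng.binomial(2, 0.4, n) - 2 * 0.4)[:, None]
        c = 2 * 0.4 * 0.6
        G = m @ m.T / c + 1e-8 * np.eye(n)
        grm = Grm(G=G, c=c, frequencies=np.array([0.4]), centered=m)
        a = 0.7 * m[:, 0] + 0.001 * rng.normal(size=n)
        fit = GBLUPResults(
            model=None, fe_params=None, batch_effects=None, gebv=a,
            varcomps={"sigma2_a": 1.0, "sigma2_batch": 0.0, "sigma2_e": 1.0},
            ginv=np.linalg.inv(G),
        )
        u = backsolve_snp_effects(fit, m, c).effects[0]
        slope = (m[:, 0] @ a) / (m[:, 0] @ m[:, 0])
        assert u == pytest.approx(slope, abs=1e-5)

    def test_mismatched_matrix_raises(self):
        y, X, batch, W, grm = _fixture(seed=9)
        fit = solve_mme(y, X, batch, grm, varcomps=(0.5, 0.2, 0.8))
        with pytest.raises(MixedModelError):
            backsolve_snp_effects(fit, grm.centered[:-1], grm.c)


class TestPvalues:
    def test_zero_effect_gives_p_one(self):
        u = np.array([0.0, 1.0, -1.0, 2.0])
        fit = GBLUPResults(model=None, fe_params=None, batch_effects=None,
                           gebv=None, varcomps={})
        assoc = snp_pvalues(SnpAssociation(effects=u), fit, method="empirical-sd")
        assert assoc.pvalues[0] == 1.0

    def test_printed_formula_empirical_sd(self):
        u = np.random.default_rng(10).normal(size=50)
        fit = GBLUPResults(model=None, fe_params=None, batch_effects=None,
                           gebv=None, varcomps={})
        assoc = snp_pvalues(SnpAssociation(effects=u), fit, method="empirical-sd")
        expected = 2 * (1 - stats.norm.cdf(np.abs(u) / np.std(u)))
        np.testing.assert_allclose(assoc.pvalues, expected, atol=1e-12)

    def test_standardised_effect_of_1p96_gives_p_005(self):
        # +-1 effects have population SD exactly 1, so each sits at |z| = 1;
        # scaling the whole vector leaves z untouched -> check the quantile
        u = 1.959964 * np.array([1.0, -1.0, 1.0, -1.0])
        fit = GBLUPResults(model=None, fe_params=None, batch_effects=None,
                           gebv=None, varcomps={})
        assoc = snp_pvalues(SnpAssociation(effects=u), fit, method="empirical-sd")
        # all |u_i|/sd = 1 here; the 5% quantile itself:
        assert 2 * stats.norm.sf(1.959964) == pytest.approx(0.05, abs=1e-6)
        np.testing.assert_allclose(assoc.pvalues, 2 * stats.norm.sf(1.0), atol=1e-12)

    def test_per_snp_pev_reasonable(self):
        y, X, batch, W, grm = _fixture(seed=11)
        fit = solve_mme(y, X, batch, grm, varcomps=(0.5, 0.2, 0.8))
        assoc = fit.snp_pvalues(method="per-snp-pev")
        assert np.all(assoc.sd > 0)
        assert np.all((assoc.pvalues > 0) & (assoc.pvalues <= 1))


class TestSelectMarkers:
    @staticmethod
    def _assoc(scores):
        p = 10.0 ** (-np.asarray(scores))
        return SnpAssociation(effects=np.zeros(len(scores)), pvalues=p)

    def test_strictly_greater(self):
        idx = select_markers(self._assoc([1.5, 2.1, 3.2]), 2.0)
        np.testing.assert_array_equal(idx, [1, 2])

    def test_nested_thresholds(self):
        rng = np.random.default_rng(15)
        assoc = self._assoc(rng.uniform(0, 4, 200))
        s20 = set(select_markers(assoc, 2.0))
        s25 = set(select_markers(assoc, 2.5))
        s30 = set(select_markers(assoc, 3.0))
        assert s30 <= s25 <= s20

    def test_minus_inf_selects_all(self):
        assoc = self._assoc([0.1, 1.0, 2.0])
        assert select_markers(assoc, -np.inf).size == 3

    def test_empty_selection_warns(self):
        with pytest.warns(UserWarning):
            idx = select_markers(self._assoc([0.5, 1.0]), 3.0)
        assert idx.size == 0
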