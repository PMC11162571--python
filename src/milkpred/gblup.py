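"""Single-trait GBLUP animal model with a random batch effect.

The model is ``y = X b + W h + Z a + e`` with ``a ~ N(0, G sigma2_a)``
(``G`` the VanRaden genomic relationship matrix), ``h ~ N(0, I sigma2_batch)``
for the blood-sampling-batch effect and ``e ~ N(0, I sigma2_e)``. Fixed
effects are an intercept plus reference-coded days-in-milk (6 classes) and
parity (3 classes) dummies. With one record per cow, ``Z`` is the identity
after aligning cow order.

Estimation follows the classical two-step practice: variance components by
EM-REML (accelerated through the eigendecomposition of ``G``, which makes
the animal block of the mixed-model equations diagonal), then solutions of
Henderson's mixed-model equations at those components. SNP marker effects
are recovered from the genomic breeding values by backsolving
``u = M' G^{-1} a / c`` and converted to GWAS p-values by effect
standardisation, from which markers are preselected at -log10(p) thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .genomics import Grm

__all__ = [
    "GBLUP",
    "GBLUPResults",
    "SnpAssociation",
    "gwas_design",
    "solve_mme",
    "estimate_variance_components",
    "backsolve_snp_effects",
    "snp_pvalues",
    "select_markers",
]


class MixedModelError(ValueError):
    pass


def gwas_design(
    dim_class: np.ndarray, parity_class: np.ndarray
) -> tuple[np.ndarray, list[str]]:
    """Reference-coded fixed-effect design: intercept + DIM + parity dummies.

    The first DIM band and first parity class are the baseline (at most
    1 + 5 + 2 columns); dummies for classes absent from the data are
    dropped so the design keeps full column rank.
    """
    dim_class = np.asarray(dim_class, dtype=int)
    parity_class = np.asarray(parity_class, dtype=int)
    n = dim_class.size
    cols = [np.ones(n)]
    names = ["intercept"]
    for label, classes in (("dim", dim_class), ("parity", parity_class)):
        present = np.unique(classes)
        for c in present[1:]:  # smallest present class is the reference
            cols.append((classes == c).astype(float))
            names.append(f"{label}_{c}")
    return np.column_stack(cols), names


def _batch_incidence(batch: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    levels, inv = np.unique(np.asarray(batch), return_inverse=True)
    W = np.zeros((len(inv), len(levels)))
    W[np.arange(len(inv)), inv] = 1.0
    return W, levels


@dataclass
class SnpAssociation:
    """Backsolved SNP effects with standard deviations and p-values."""

    effects: np.ndarray
    sd: np.ndarray = None
    pvalues: np.ndarray = None
    marker_map: pd.DataFrame = None
    method: str = ""

    @property
    def neglog10p(self) -> np.ndarray:
        return -np.log10(self.pvalues)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "effect": self.effects,
                "sd": self.sd,
                "p": self.pvalues,
                "neglog10p": self.neglog10p,
            }
        )
        if self.marker_map is not None:
            out = pd.concat(
                [self.marker_map[["snp_id", "chrom", "pos"]].reset_index(drop=True), out],
                axis=1,
            )
        return out


class GBLUP:
    """Single-trait genomic BLUP model.

    Parameters
    ----------
    endog : (n,) response vector (one metabolite).
    exog : (n, p_f) fixed-effect design, full column rank.
    batch : (n,) batch labels, modelled as an i.i.d. random effect.
    grm : Grm
        Genomic relationship matrix for the same cows, in the same order.
    """

    def __init__(self, endog, exog, batch, grm: Grm):
        self.y = np.asarray(endog, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(exog, dtype=float))
        self.grm = grm
        n = self.y.size
        if self.X.shape[0] != n or grm.G.shape[0] != n:
            raise MixedModelError(
                f"non-conformable dimensions: y has {n} rows, X {self.X.shape[0]}, "
                f"G {grm.G.shape[0]}"
            )
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise MixedModelError("fixed-effect design is rank deficient")
        self.W, self.batch_levels = _batch_incidence(batch)
        # eigendecomposition of G, shared by REML and the MME solver
        evals, evecs = np.linalg.eigh(np.asarray(grm.G, dtype=float))
        if evals.min() < 1e-8:
            raise MixedModelError(
                "G is singular or near-singular; apply Grm.blend() before fitting"
            )
        self._evals, self._evecs = evals, evecs

    @classmethod
    def from_classes(cls, endog, dim_class, parity_class, batch, grm: Grm) -> "GBLUP":
        X, names = gwas_design(dim_class, parity_class)
        model = cls(endog, X, batch, grm)
        model.exog_names = names
        return model

    # ------------------------------------------------------------------ REML
    def _reml_em(self, tol: float = 1e-8, max_iter: int = 500):
        """EM-REML for (sigma2_a, sigma2_batch, sigma2_e).

        Works in the eigenbasis of G, where the animal equations are
        diagonal and each EM step costs O(n * m^2) for m fixed+batch
        effects. Iterates until the relative REML log-likelihood change
        falls below ``tol``.
        """
        U, d = self._evecs, self._evals
        y_t = U.T @ self.y
        X_t = U.T @ self.X
        W_t = U.T @ self.W
        F = np.hstack([X_t, W_t])
        n = y_t.size
        p_f = self.X.shape[1]
        q = self.W.shape[1]
        vy = self.y.var()
        if vy == 0:
            raise MixedModelError("response has zero variance")
        s2a, s2h, s2e = 0.3 * vy, 0.1 * vy, 0.6 * vy
        floor = 1e-10 * vy

        FtF = F.T @ F
        Fty = F.T @ y_t
        prior_f = np.zeros((p_f + q, p_f + q))

        def loglik(s2a, s2h, s2e):
            delta = s2a * d + s2e
            if s2h > 0:
                K = np.eye(q) / s2h + (W_t.T / delta) @ W_t
                Kinv = np.linalg.inv(K)

                def vinv(M):
                    Md = M / delta[:, None]
                    return Md - (W_t / delta[:, None]) @ (Kinv @ (W_t.T @ Md))

                logdet = np.sum(np.log(delta)) + np.linalg.slogdet(
                    np.eye(q) + s2h * (W_t.T / delta) @ W_t
                )[1]
            else:

                def vinv(M):
                    return M / delta[:, None]

                logdet = np.sum(np.log(delta))
            ViX = vinv(X_t)
            XtViX = X_t.T @ ViX
            Viy = vinv(y_t[:, None]).ravel()
            beta = np.linalg.solve(XtViX, X_t.T @ Viy)
            r = y_t - X_t @ beta
            quad = r @ vinv(r[:, None]).ravel()
            return -0.5 * (logdet + np.linalg.slogdet(XtViX)[1] + quad)

        ll = loglik(s2a, s2h, s2e)
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            E = 1.0 / s2e + 1.0 / (d * s2a)  # diagonal animal block
            A = FtF / s2e + prior_f
            A[p_f:, p_f:] += np.eye(q) / s2h
            B = F.T / s2e  # (m, n)
            BEinv = B / E
            S = A - BEinv @ B.T
            rhs_f = Fty / s2e
            rhs_a = y_t / s2e
            Sinv = np.linalg.inv(S)
            s_f = Sinv @ (rhs_f - BEinv @ rhs_a)
            a_t = (rhs_a - B.T @ s_f) / E

            # C^{-1} traces via the Schur complement (animal block diagonal)
            R = BEinv  # (m, n)
            caa_corr = np.einsum("mi,mk,ki->i", R, Sinv, R)
            tr_dinv_caa = np.sum((1.0 / d) * (1.0 / E + caa_corr))
            tr_chh = np.trace(Sinv[p_f:, p_f:])
            h_hat = s_f[p_f:]

            s2a_new = max((a_t @ (a_t / d) + tr_dinv_caa) / n, floor)
            s2h_new = max((h_hat @ h_hat + tr_chh) / q, floor)
            resid = y_t - F @ s_f - a_t
            s2e_new = max((resid @ y_t) / (n - p_f), floor)

            # step-lengthening: EM crawls near variance boundaries, so try
            # extrapolating the EM step on the log scale and keep whichever
            # candidate has the best restricted likelihood (monotone ascent)
            old = np.array([s2a, s2h, s2e])
            new = np.array([s2a_new, s2h_new, s2e_new])
            step = np.log(new) - np.log(old)
            best = (loglik(*new), new)
            for s in (2.0, 4.0, 8.0):
                cand = np.maximum(np.exp(np.log(old) + s * step), floor)
                ll_c = loglik(*cand)
                if ll_c > best[0]:
                    best = (ll_c, cand)
                else:
                    break
            ll_new, (s2a, s2h, s2e) = best[0], best[1]
            if abs(ll_new - ll) < tol * (abs(ll) + 1.0):
                ll = ll_new
                converged = True
                break
            ll = ll_new
        if not converged:
            warnings.warn(
                f"EM-REML did not converge in {max_iter} iterations; "
                "returning the last iterate"
            )
        return (s2a, s2h, s2e), ll, converged, it

    # ------------------------------------------------------------------- fit
    def fit(
        self,
        varcomps: tuple[float, float, float] | None = None,
        reml_tol: float = 1e-8,
        reml_max_iter: int = 500,
    ) -> "GBLUPResults":
        """Fit the model.

        When ``varcomps`` is None the three variance components are
        estimated by EM-REML first; otherwise the supplied
        ``(sigma2_a, sigma2_batch, sigma2_e)`` are used as known.
        """
        if varcomps is None:
            varcomps, ll, converged, n_iter = self._reml_em(reml_tol, reml_max_iter)
        else:
            ll, converged, n_iter = np.nan, True, 0
        s2a, s2h, s2e = varcomps
        if s2e <= 0 or s2a < 0 or s2h < 0:
            raise MixedModelError("variance components must be non-negative, sigma2_e > 0")

        n = self.y.size
        p_f = self.X.shape[1]
        q = self.W.shape[1]
        # Henderson's MME with Z = I; scaled so C^{-1} is the PEV matrix
        T = np.hstack([self.X, self.W, np.eye(n)])
        C = T.T @ T / s2e
        if s2h > 0:
            C[p_f : p_f + q, p_f : p_f + q] += np.eye(q) / s2h
        else:
            C[p_f : p_f + q, p_f : p_f + q] += np.eye(q) * 1e12
        Ginv = self._evecs @ ((self._evecs / self._evals).T)
        s2a_eff = max(s2a, 1e-12 * s2e)
        C[p_f + q :, p_f + q :] += Ginv / s2a_eff
        rhs = T.T @ self.y / s2e
        try:
            Cinv = linalg.inv(C, check_finite=False)
        except linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise MixedModelError(
                "singular MME coefficient matrix; consider Grm.blend()"
            ) from exc
        sol = Cinv @ rhs
        return GBLUPResults(
            model=self,
            fe_params=sol[:p_f],
            batch_effects=sol[p_f : p_f + q],
            gebv=sol[p_f + q :],
            varcomps={"sigma2_a": s2a, "sigma2_batch": s2h, "sigma2_e": s2e},
            caa=Cinv[p_f + q :, p_f + q :],
            ginv=Ginv,
            loglik=ll,
            converged=converged,
            n_iter=n_iter,
        )


@dataclass
class GBLUPResults:
    """Solutions of the GBLUP mixed-model equations for one trait."""

    model: GBLUP
    fe_params: np.ndarray
    batch_effects: np.ndarray
    gebv: np.ndarray
    varcomps: dict
    caa: np.ndarray = field(repr=False, default=None)  # PEV block of the GEBVs
    ginv: np.ndarray = field(repr=False, default=None)
    loglik: float = np.nan
    converged: bool = True
    n_iter: int = 0

    @property
    def heritability(self) -> float:
        v = self.varcomps
        tot = v["sigma2_a"] + v["sigma2_batch"] + v["sigma2_e"]
        return v["sigma2_a"] / tot

    def fittedvalues(self) -> np.ndarray:
        m = self.model
        return m.X @ self.fe_params + m.W @ self.batch_effects + self.gebv

    def mme_residual(self) -> float:
        """Relative residual of the mixed-model equations (diagnostic)."""
        m = self.model
        v = self.varcomps
        n, p_f, q = m.y.size, m.X.shape[1], m.W.shape[1]
        T = np.hstack([m.X, m.W, np.eye(n)])
        C = T.T @ T / v["sigma2_e"]
        C[p_f : p_f + q, p_f : p_f + q] += np.eye(q) / max(v["sigma2_batch"], 1e-300)
        C[p_f + q :, p_f + q :] += self.ginv / max(v["sigma2_a"], 1e-300)
        sol = np.concatenate([self.fe_params, self.batch_effects, self.gebv])
        rhs = T.T @ m.y / v["sigma2_e"]
        return float(
            np.max(np.abs(C @ sol - rhs)) / max(np.max(np.abs(rhs)), 1.0)
        )

    # ----------------------------------------------------- GWAS backsolving
    def snp_effects(self, grm: Grm | None = None) -> SnpAssociation:
        """Backsolve SNP effects u = M' G^{-1} a / c from the GEBVs."""
        grm = self.model.grm if grm is None else grm
        return backsolve_snp_effects(self, grm.centered, grm.c)

    def snp_pvalues(
        self, assoc: SnpAssociation | None = None, method: str = "per-snp-pev"
    ) -> SnpAssociation:
        if assoc is None:
            assoc = self.snp_effects()
        return snp_pvalues(assoc, self, method=method)

    def summary(self) -> str:
        v = self.varcomps
        lines = [
            "GBLUP single-trait animal model",
            "=" * 46,
            f"n animals          {self.gebv.size:>10d}",
            f"n batches          {self.batch_effects.size:>10d}",
            f"sigma2_a           {v['sigma2_a']:>10.4f}",
            f"sigma2_batch       {v['sigma2_batch']:>10.4f}",
            f"sigma2_e           {v['sigma2_e']:>10.4f}",
            f"h2 (of random var) {self.heritability:>10.4f}",
            f"REML loglik        {self.loglik:>10.4f}"
            if np.isfinite(self.loglik)
            else "variance components supplied (no REML)",
            f"converged          {str(self.converged):>10s}",
        ]
        for i, b in enumerate(self.fe_params):
            name = getattr(self.model, "exog_names", None)
            label = name[i] if name else f"beta_{i}"
            lines.append(f"{label:<18s} {b:>10.4f}")
        return "\n".join(lines)


# ------------------------------------------------------------ spec-level ops


def solve_mme(
    endog,
    exog,
    batch,
    grm: Grm,
    varcomps: tuple[float, float, float],
) -> GBLUPResults:
    """Solve Henderson's mixed-model equations at known variance components."""
    return GBLUP(endog, exog, batch, grm).fit(varcomps=varcomps)


def estimate_variance_components(
    endog, exog, batch, grm: Grm, tol: float = 1e-8, max_iter: int = 500
) -> tuple[tuple[float, float, float], bool]:
    """EM-REML estimates of (sigma2_a, sigma2_batch, sigma2_e)."""
    model = GBLUP(endog, exog, batch, grm)
    varcomps, _, converged, _ = model._reml_em(tol, max_iter)
    return varcomps, converged


def backsolve_snp_effects(
    fit: GBLUPResults, M: np.ndarray, c: float
) -> SnpAssociation:
    """SNP effects from GEBVs: u = (1/c) M' G^{-1} a.

    ``M`` must be the allele-frequency-centred genotype matrix that built
    the G used in the fit (so that M M' / c = G and M u = a exactly).
    """
    if M is None:
        raise MixedModelError("centred genotype matrix unavailable")
    M = np.asarray(M, dtype=float)
    if M.shape[0] != fit.gebv.size:
        raise MixedModelError(
            f"genotype matrix rows ({M.shape[0]}) do not match GEBVs ({fit.gebv.size})"
        )
    ginv_a = fit.ginv @ fit.gebv
    u = (M.T @ ginv_a) / c
    return SnpAssociation(effects=u)


def snp_pvalues(
    assoc: SnpAssociation,
    fit: GBLUPResults,
    method: str = "per-snp-pev",
    marker_map: pd.DataFrame | None = None,
) -> SnpAssociation:
    """Two-sided p-values from standardised SNP effects.

    ``per-snp-pev`` uses each marker's own sampling variance
    ``var(u_i) = m_i' G^{-1} (G sigma2_a - Caa) G^{-1} m_i / c^2`` derived
    from the prediction-error variance of the GEBVs; ``empirical-sd`` uses
    one constant scale, the SD of the backsolved effect vector. Either way
    ``p = 2 (1 - Phi(|u_i| / sd_i))``.
    """
    u = assoc.effects
    if method == "per-snp-pev":
        grm = fit.model.grm
        M = grm.centered
        s2a = fit.varcomps["sigma2_a"]
        Q = s2a * fit.ginv - fit.ginv @ fit.caa @ fit.ginv
        Q = (Q + Q.T) / 2.0
        var_u = np.einsum("ij,jk,ik->i", M.T, Q, M.T) / grm.c**2
        # guard against roundoff: tiny negative variances are numerical zeros
        tol_neg = 1e-10 * max(var_u.max(), 1.0e-300)
        if np.any(var_u <= -tol_neg):
            bad = int(np.argmin(var_u))
            raise MixedModelError(
                f"non-positive sampling variance for SNP {bad} (method per-snp-pev)"
            )
        var_u = np.maximum(var_u, tol_neg)
        sd = np.sqrt(var_u)
    elif method == "empirical-sd":
        sd_val = float(np.std(u))
        if sd_val <= 0:
            raise MixedModelError("zero SD of SNP effects (method empirical-sd)")
        sd = np.full(u.size, sd_val)
    else:
        raise ValueError(f"unknown method {method!r}")
    z = np.abs(u) / sd
    p = 2.0 * stats.norm.sf(z)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return SnpAssociation(
        effects=u, sd=sd, pvalues=p, marker_map=marker_map, method=method
    )


def select_markers(assoc: SnpAssociation, threshold: float) -> np.ndarray:
    """Indices of markers with -log10(p) strictly above ``threshold``.

    Returned in marker-map order; an empty selection triggers a warning so
    callers can fall back to the all-marker model.
    """
    if assoc.pvalues is None:
        raise MixedModelError("p-values not computed")
    idx = np.flatnonzero(assoc.neglog10p > threshold)
    if idx.size == 0:
        warnings.warn(
            f"no markers exceed -log10(p) > {threshold}; callers should fall "
            "back to the all-marker model"
        )
    return idx
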