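"""Milk NIR spectra preprocessing.

The in-line spectrometer records ~70 sub-observations per cow per milking
(one every 200 mL of milk), each with a milk-quantity weight, over 32
discrete visible/NIR channels (400-1,000 nm). The preprocessing chain is:

1. milk-weighted aggregation of a cow's sub-observations into one spectrum;
2. first derivative across channels (difference of consecutive channels);
3. Standard Normal Variate (SNV) normalisation of each derivative spectrum
   to zero mean and unit population SD;
4. outlier screening by PCA scores + Mahalanobis distance with a chi-square
   upper-tail probability threshold.

Cows flagged at step 3 (degenerate spectrum) or 4 (outlier) are excluded
from modelling; the flags and reason codes travel with the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SpectraSet",
    "PreprocessedSpectra",
    "aggregate_cow_spectrum",
    "first_derivative",
    "snv_normalize",
    "mahalanobis_qc",
    "preprocess_spectra",
]


class SpectraValidationError(ValueError):
    pass


@dataclass
class SpectraSet:
    """Raw per-cow spectral sub-observations with milk-quantity weights."""

    cow_ids: list[str]
    sub_spectra: list[np.ndarray]  # per cow: (k_i, n_channels)
    weights: list[np.ndarray]  # per cow: (k_i,), strictly positive
    wavelengths: np.ndarray  # (n_channels,) in nm

    def __post_init__(self) -> None:
        if not (len(self.cow_ids) == len(self.sub_spectra) == len(self.weights)):
            raise SpectraValidationError("cow_ids/sub_spectra/weights length mismatch")
        m = len(self.wavelengths)
        for cid, s, w in zip(self.cow_ids, self.sub_spectra, self.weights):
            s = np.asarray(s)
            if s.ndim != 2 or s.shape[1] != m:
                raise SpectraValidationError(
                    f"cow {cid}: sub-observations must be (k, {m})"
                )
            if len(w) != s.shape[0]:
                raise SpectraValidationError(f"cow {cid}: weight count mismatch")

    @property
    def n_cows(self) -> int:
        return len(self.cow_ids)

    @property
    def n_channels(self) -> int:
        return len(self.wavelengths)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: cow_id, obs_index, milk_weight, c1..c<m>."""
        rows = []
        for cid, s, w in zip(self.cow_ids, self.sub_spectra, self.weights):
            for j in range(s.shape[0]):
                rows.append((cid, j, w[j], *s[j]))
        cols = ["cow_id", "obs_index", "milk_weight"] + [
            f"c{i + 1}" for i in range(self.n_channels)
        ]
        return pd.DataFrame(rows, columns=cols)


@dataclass
class PreprocessedSpectra:
    """Derivative-SNV spectra with QC flags.

    ``matrix`` holds one row per cow (length = channels - 1); rows of
    flagged cows are retained for inspection but must not enter modelling.
    """

    cow_ids: list[str]
    matrix: np.ndarray  # (n_cows, n_channels - 1)
    flags: np.ndarray  # bool, True = excluded
    reasons: list[str]  # "" when retained
    qc_distances: np.ndarray = field(default=None)  # squared Mahalanobis D2
    qc_pvalues: np.ndarray = field(default=None)
    n_components: int = 0  # PCs retained in QC

    @property
    def retained_ids(self) -> list[str]:
        return [c for c, f in zip(self.cow_ids, self.flags) if not f]

    def retained_matrix(self) -> np.ndarray:
        return self.matrix[~self.flags]

    def qc_report(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cow_id": self.cow_ids,
                "D2": self.qc_distances,
                "p": self.qc_pvalues,
                "flag": self.flags,
                "reason": self.reasons,
            }
        )


def aggregate_cow_spectrum(subobs: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Milk-quantity-weighted mean spectrum of one cow's sub-observations."""
    subobs = np.asarray(subobs, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if subobs.ndim != 2 or subobs.shape[0] == 0:
        raise SpectraValidationError("need at least one sub-observation")
    if weights.shape[0] != subobs.shape[0]:
        raise SpectraValidationError("one weight per sub-observation required")
    if np.any(weights <= 0) or not np.all(np.isfinite(weights)):
        raise SpectraValidationError("milk weights must be strictly positive")
    w = weights / weights.sum()
    return w @ subobs


def first_derivative(x: np.ndarray) -> np.ndarray:
    """First derivative of a spectrum: differences of consecutive channels.

    A length-``m`` spectrum yields a length-``m - 1`` derivative, element
    ``i`` being ``x[i + 1] - x[i]`` in wavelength order.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise SpectraValidationError("spectrum must be 1-D with >= 2 channels")
    return np.diff(x)


def snv_normalize(d: np.ndarray) -> np.ndarray:
    """Standard Normal Variate: centre and scale one spectrum to unit SD.

    The SD is the population SD over the spectrum's own channels (divisor =
    number of elements). A constant spectrum has no SNV transform and raises.
    """
    d = np.asarray(d, dtype=float)
    sd = d.std()  # population SD, ddof=0
    if sd == 0 or not np.isfinite(sd):
        raise SpectraValidationError("degenerate spectrum: zero variance")
    return (d - d.mean()) / sd


def mahalanobis_qc(
    vectors: np.ndarray,
    alpha_qc: float = 0.05,
    var_retained: float = 0.95,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Flag outlier spectra by PCA-score Mahalanobis distance.

    PCA keeps the fewest components explaining at least ``var_retained`` of
    the variance; each cow's squared Mahalanobis distance is computed from
    its score vector against the score covariance, and cows whose chi-square
    upper-tail probability (df = retained components) falls below
    ``alpha_qc`` are flagged.

    Returns
    -------
    flags : bool array
    d2 : squared Mahalanobis distances
    pvals : chi-square upper-tail probabilities
    k : number of retained components
    """
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise SpectraValidationError("QC needs at least 3 spectra")
    if not 0 <= alpha_qc < 1:
        raise SpectraValidationError("alpha_qc must lie in [0, 1)")
    Xc = X - X.mean(axis=0)
    # PCA via SVD of the centred matrix
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    total = var.sum()
    if total == 0:
        # all spectra identical: nothing can be an outlier
        zeros = np.zeros(X.shape[0])
        return np.zeros(X.shape[0], dtype=bool), zeros, np.ones(X.shape[0]), 0
    frac = np.cumsum(var) / total
    k = int(np.searchsorted(frac, var_retained - 1e-12) + 1)
    scores = Xc @ vt[:k].T
    cov = np.cov(scores, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    try:
        cov_inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        import warnings

        warnings.warn("singular score covariance; falling back to diagonal")
        cov_inv = np.diag(1.0 / np.maximum(np.diag(cov), 1e-30))
    d2 = np.einsum("ij,jk,ik->i", scores, cov_inv, scores)
    pvals = stats.chi2.sf(d2, df=k)
    flags = pvals < alpha_qc
    return flags, d2, pvals, k


def preprocess_spectra(
    spectra: SpectraSet,
    alpha_qc: float = 0.05,
    var_retained: float = 0.95,
) -> PreprocessedSpectra:
    """Full chain: aggregate -> derivative -> SNV -> Mahalanobis QC."""
    n = spectra.n_cows
    m = spectra.n_channels
    mat = np.zeros((n, m - 1))
    flags = np.zeros(n, dtype=bool)
    reasons = [""] * n
    for i, (s, w) in enumerate(zip(spectra.sub_spectra, spectra.weights)):
        mean_spec = aggregate_cow_spectrum(s, w)
        d = first_derivative(mean_spec)
        try:
            mat[i] = snv_normalize(d)
        except SpectraValidationError:
            flags[i] = True
            reasons[i] = "degenerate spectrum"

    d2 = np.full(n, np.nan)
    pv = np.full(n, np.nan)
    k = 0
    ok = ~flags
    if ok.sum() >= 3:
        qflags, qd2, qpv, k = mahalanobis_qc(mat[ok], alpha_qc, var_retained)
        idx = np.flatnonzero(ok)
        d2[idx] = qd2
        pv[idx] = qpv
        for j, f in zip(idx, qflags):
            if f:
                flags[j] = True
                reasons[j] = "mahalanobis outlier"
    return PreprocessedSpectra(
        cow_ids=list(spectra.cow_ids),
        matrix=mat,
        flags=flags,
        reasons=reasons,
        qc_distances=d2,
        qc_pvalues=pv,
        n_components=k,
    )
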