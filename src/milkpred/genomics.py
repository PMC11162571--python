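"""Genotype handling: quality control, allele frequencies, the VanRaden
genomic relationship matrix and population-structure PCA.

Genotypes are coded 0/1/2 as counts of the second (alternate) allele, with
``nan`` marking missing calls. QC mirrors routine SNP-chip filtering:
non-autosomal markers, minor allele frequency, a 1-df chi-square
Hardy-Weinberg test and SNP/sample call rate, followed by mean imputation
of the surviving missing calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeData",
    "Grm",
    "allele_frequencies",
    "hwe_test",
    "qc_filter",
    "grm_vanraden",
    "pca_structure",
]

AUTOSOMES = {str(i) for i in range(1, 30)}  # Bos taurus: 29 autosomes


class GenotypeError(ValueError):
    pass


@dataclass
class GenotypeData:
    """Coded SNP matrix (cows x markers) with its marker map."""

    matrix: np.ndarray  # float, values {0,1,2} or nan for missing
    marker_map: pd.DataFrame  # columns: snp_id, chrom, pos, ref, alt
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise GenotypeError("genotype matrix must be 2-D")
        if len(self.marker_map) != self.matrix.shape[1]:
            raise GenotypeError("marker map length must equal SNP count")
        if len(self.sample_ids) != self.matrix.shape[0]:
            raise GenotypeError("sample_ids length must equal cow count")

    @property
    def n_cows(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_snps(self) -> int:
        return self.matrix.shape[1]

    def snp_call_rates(self) -> np.ndarray:
        return 1.0 - np.isnan(self.matrix).mean(axis=0)

    def sample_call_rates(self) -> np.ndarray:
        return 1.0 - np.isnan(self.matrix).mean(axis=1)

    def subset(self, rows=None, cols=None) -> "GenotypeData":
        rows = np.arange(self.n_cows) if rows is None else np.asarray(rows)
        cols = np.arange(self.n_snps) if cols is None else np.asarray(cols)
        return GenotypeData(
            matrix=self.matrix[np.ix_(rows, cols)],
            marker_map=self.marker_map.iloc[cols].reset_index(drop=True),
            sample_ids=[self.sample_ids[i] for i in rows],
        )


@dataclass
class Grm:
    """VanRaden genomic relationship matrix with its scaling constant."""

    G: np.ndarray
    c: float  # 2 * sum p_j (1 - p_j)
    frequencies: np.ndarray
    centered: np.ndarray = field(repr=False, default=None)  # M with 2p_j removed
    blended: bool = False

    def blend(self, weight: float = 0.99) -> "Grm":
        """Ridge-blend toward the identity to guarantee invertibility."""
        n = self.G.shape[0]
        return Grm(
            G=weight * self.G + (1.0 - weight) * np.eye(n),
            c=self.c,
            frequencies=self.frequencies,
            centered=self.centered,
            blended=True,
        )


def allele_frequencies(matrix: np.ndarray) -> np.ndarray:
    """Second-allele frequency per SNP: half the mean of non-missing codes."""
    M = np.asarray(matrix, dtype=float)
    miss = np.isnan(M)
    n_called = (~miss).sum(axis=0)
    if np.any(n_called == 0):
        bad = np.flatnonzero(n_called == 0)
        raise GenotypeError(f"SNP column(s) {bad.tolist()} have no called genotypes")
    totals = np.nansum(M, axis=0)
    return totals / (2.0 * n_called)


def hwe_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """1-df chi-square goodness-of-fit p-value for Hardy-Weinberg equilibrium.

    Expected genotype counts come from the estimated allele frequency;
    monomorphic SNPs return p = 1 by convention (no deviation is testable).
    """
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise GenotypeError("need at least one genotype call")
    p = (2 * n_bb + n_ab) / (2 * n)
    if p == 0.0 or p == 1.0:
        return 1.0
    q = 1.0 - p
    expected = np.array([q * q * n, 2 * p * q * n, p * p * n])
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = np.sum((observed - expected) ** 2 / expected)
    return float(stats.chi2.sf(chi2, df=1))


def hwe_pvalues(matrix: np.ndarray) -> np.ndarray:
    """Vectorised HWE p-value per SNP column (missing calls skipped)."""
    M = np.asarray(matrix, dtype=float)
    out = np.ones(M.shape[1])
    for j in range(M.shape[1]):
        col = M[:, j]
        col = col[~np.isnan(col)]
        n_aa = int(np.sum(col == 0))
        n_ab = int(np.sum(col == 1))
        n_bb = int(np.sum(col == 2))
        out[j] = hwe_test(n_aa, n_ab, n_bb)
    return out


def qc_filter(
    gd: GenotypeData,
    maf_min: float = 0.05,
    hwe_p: float = 1e-5,
    call_rate: float = 0.95,
    autosomes_only: bool = True,
) -> tuple[GenotypeData, pd.DataFrame]:
    """Standard SNP-chip quality control with an exclusion report.

    Filter order: non-autosomal markers, MAF < ``maf_min``, HWE p <=
    ``hwe_p``, SNP call rate < ``call_rate``, then cows with call rate <
    ``call_rate``. Surviving missing genotypes are imputed to the column
    mean ``2 p_j``. The report lists every excluded SNP/cow with its reason;
    counts reconcile with the input dimensions.
    """
    records: list[tuple[str, str, str]] = []
    keep_snps = np.ones(gd.n_snps, dtype=bool)
    snp_ids = gd.marker_map["snp_id"].to_numpy()

    if autosomes_only:
        autosomal = gd.marker_map["chrom"].astype(str).isin(AUTOSOMES).to_numpy()
        for j in np.flatnonzero(~autosomal & keep_snps):
            records.append(("snp", snp_ids[j], "non-autosomal"))
        keep_snps &= autosomal

    with np.errstate(invalid="ignore"):
        freqs = np.full(gd.n_snps, np.nan)
        called = (~np.isnan(gd.matrix)).sum(axis=0)
        ok = called > 0
        freqs[ok] = np.nansum(gd.matrix[:, ok], axis=0) / (2.0 * called[ok])
    maf = np.minimum(freqs, 1.0 - freqs)
    low_maf = (maf < maf_min) | np.isnan(maf)
    for j in np.flatnonzero(low_maf & keep_snps):
        records.append(("snp", snp_ids[j], "MAF"))
    keep_snps &= ~low_maf

    if keep_snps.any():
        hwe = np.ones(gd.n_snps)
        hwe[keep_snps] = hwe_pvalues(gd.matrix[:, keep_snps])
        bad_hwe = hwe <= hwe_p
        for j in np.flatnonzero(bad_hwe & keep_snps):
            records.append(("snp", snp_ids[j], "HWE"))
        keep_snps &= ~bad_hwe

    snp_cr = gd.snp_call_rates()
    low_cr = snp_cr < call_rate
    for j in np.flatnonzero(low_cr & keep_snps):
        records.append(("snp", snp_ids[j], "call_rate"))
    keep_snps &= ~low_cr

    if not keep_snps.any():
        raise GenotypeError("quality control removed every SNP")

    sub = gd.matrix[:, keep_snps]
    cow_cr = 1.0 - np.isnan(sub).mean(axis=1)
    keep_cows = cow_cr >= call_rate
    for i in np.flatnonzero(~keep_cows):
        records.append(("cow", gd.sample_ids[i], "call_rate"))
    if not keep_cows.any():
        raise GenotypeError("quality control removed every cow")

    out = gd.subset(np.flatnonzero(keep_cows), np.flatnonzero(keep_snps))
    # impute remaining missing calls to the column mean 2 p_j
    freqs_out = allele_frequencies(out.matrix)
    miss = np.isnan(out.matrix)
    if miss.any():
        fill = np.broadcast_to(2.0 * freqs_out, out.matrix.shape)
        out.matrix[miss] = fill[miss]
    report = pd.DataFrame(records, columns=["kind", "id", "reason"])
    return out, report


def grm_vanraden(gd: GenotypeData, frequencies: np.ndarray | None = None) -> Grm:
    """VanRaden genomic relationship matrix G = MM' / (2 sum p_j (1 - p_j)).

    ``M`` is the coded matrix with column ``j`` centred by ``2 p_j``. By
    default the allele frequencies are computed from the data itself; passing
    ``frequencies`` (e.g. training-fold frequencies) overrides that.
    """
    X = np.asarray(gd.matrix, dtype=float)
    if np.isnan(X).any():
        raise GenotypeError("GRM requires imputed (complete) genotypes")
    p = allele_frequencies(X) if frequencies is None else np.asarray(frequencies)
    c = float(2.0 * np.sum(p * (1.0 - p)))
    if c <= 0:
        raise GenotypeError("all SNPs monomorphic: GRM scaling constant is zero")
    M = X - 2.0 * p
    G = (M @ M.T) / c
    G = (G + G.T) / 2.0
    return Grm(G=G, c=c, frequencies=p, centered=M)


def pca_structure(gd: GenotypeData, k: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Population-structure PCA: top-k eigenpairs of the VanRaden G.

    Returns (scores, explained_variance_fraction); ``k = 0`` yields empty
    arrays.
    """
    if k < 0 or k > gd.n_cows:
        raise GenotypeError(f"k must lie in [0, {gd.n_cows}]")
    if k == 0:
        return np.zeros((gd.n_cows, 0)), np.zeros(0)
    grm = grm_vanraden(gd)
    vals, vecs = np.linalg.eigh(grm.G)
    order = np.argsort(vals)[::-1]
    vals = np.maximum(vals[order], 0.0)
    vecs = vecs[:, order]
    total = vals.sum()
    explained = vals[:k] / total if total > 0 else np.zeros(k)
    scores = vecs[:, :k] * np.sqrt(vals[:k])
    return scores, explained
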