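"""Cross-validated model ladder: spectra-only (M1), + on-farm covariates
(M2), + genomic markers (M3), with GBLUP-GWAS marker preselection nested
inside each training fold.

For every fold and metabolite the pipeline (1) recomputes allele
frequencies, the genomic relationship matrix, REML variance components and
GWAS p-values on the training cows only, (2) selects markers above the
requested -log10(p) thresholds, (3) tunes and fits the elastic net on the
training cows (inner seeded 80:20 split) and (4) scores the held-out fold.
Nothing computed from validation cows ever reaches training — permuting
validation responses leaves selected markers and coefficients bit-identical.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enet import tune_random_grid
from .gblup import GBLUP, gwas_design, select_markers
from .genomics import GenotypeData, grm_vanraden
from .spectra import preprocess_spectra

__all__ = [
    "ModelLadderSpec",
    "PipelineConfig",
    "HerdDataset",
    "CvReport",
    "make_folds",
    "build_design_matrix",
    "run_cv",
    "compute_metrics",
    "relative_difference",
    "report",
]

N_DIM_CLASSES = 6
N_PARITY_CLASSES = 3


class PipelineError(ValueError):
    pass


@dataclass(frozen=True)
class ModelLadderSpec:
    """One rung of the model ladder.

    ``model_id`` is "M1" (spectra only), "M2" (+ DIM/parity one-hot) or
    "M3" (+ genotype block); ``threshold`` applies to M3 only and is either
    None (all markers) or a -log10(p) cut for GWAS preselection.
    """

    model_id: str
    threshold: float | None = None

    def __post_init__(self):
        if self.model_id not in {"M1", "M2", "M3"}:
            raise PipelineError(f"unknown model id {self.model_id!r}")
        if self.threshold is not None and self.model_id != "M3":
            raise PipelineError("thresholds apply to M3 only")

    @property
    def label(self) -> str:
        if self.model_id != "M3":
            return self.model_id
        return "M3_all" if self.threshold is None else f"M3_t{self.threshold:g}"


@dataclass
class PipelineConfig:
    """Run-wide settings: folds, seeds, GWAS method and elastic-net search."""

    k_folds: int = 5
    seed: int = 0
    pvalue_method: str = "per-snp-pev"
    grid_step: float = 0.1
    n_candidates: int | None = None  # None = full 121-pair grid
    # The 0-1 lambda grid is searched in glmnet's 1/(2N)-scaled convention
    # (the scaling under which that range is a meaningful penalty) and
    # converted exactly onto the unscaled objective before fitting.
    enet_parameterization: str = "glmnet"
    enet_tol: float = 1e-7
    enet_max_iter: int = 10_000
    reml_tol: float = 1e-8
    reml_max_iter: int = 500
    # With fold-internal allele frequencies the centred genotype columns sum
    # to zero, so G is rank-deficient by construction; blending restores
    # invertibility for the backsolve (0.99 G + 0.01 I).
    grm_blend: bool = True


@dataclass
class HerdDataset:
    """QC'd, preprocessed, cow-aligned inputs for the cross-validation."""

    cow_ids: list[str]
    spectra_matrix: np.ndarray  # (n, channels - 1) derivative-SNV
    dim_class: np.ndarray
    parity_class: np.ndarray
    batch: np.ndarray
    genotypes: GenotypeData  # QC'd, imputed, same cow order
    phenotypes: pd.DataFrame  # one column per metabolite
    n_removed_spectra_qc: int = 0

    def __post_init__(self):
        n = len(self.cow_ids)
        for name, arr in (
            ("spectra_matrix", self.spectra_matrix),
            ("dim_class", self.dim_class),
            ("parity_class", self.parity_class),
            ("batch", self.batch),
        ):
            if len(arr) != n:
                raise PipelineError(f"{name} is not aligned with cow_ids")
        if self.genotypes.n_cows != n:
            raise PipelineError("genotypes are not aligned with cow_ids")
        if len(self.phenotypes) != n:
            raise PipelineError("phenotypes are not aligned with cow_ids")

    @property
    def n_cows(self) -> int:
        return len(self.cow_ids)

    @property
    def metabolite_names(self) -> list[str]:
        return list(self.phenotypes.columns)

    @classmethod
    def from_herd(cls, herd, alpha_qc: float = 0.05, qc_kwargs: dict | None = None):
        """Build a dataset from a synthetic herd: spectra preprocessing +
        QC, genotype QC, and alignment on the surviving cows."""
        from .genomics import qc_filter

        pre = preprocess_spectra(herd.spectra, alpha_qc=alpha_qc)
        gd_qc, _ = qc_filter(herd.genotypes, **(qc_kwargs or {}))
        spec_keep = {c for c, f in zip(pre.cow_ids, pre.flags) if not f}
        geno_keep = set(gd_qc.sample_ids)
        keep_ids = [c for c in herd.cow_ids if c in spec_keep and c in geno_keep]
        herd_pos = {c: i for i, c in enumerate(herd.cow_ids)}
        spec_pos = {c: i for i, c in enumerate(pre.cow_ids)}
        geno_pos = {c: i for i, c in enumerate(gd_qc.sample_ids)}
        hi = [herd_pos[c] for c in keep_ids]
        phen = pd.DataFrame(
            herd.phenotypes[hi], columns=herd.metabolite_names
        ).reset_index(drop=True)
        return cls(
            cow_ids=keep_ids,
            spectra_matrix=pre.matrix[[spec_pos[c] for c in keep_ids]],
            dim_class=herd.dim_class[hi],
            parity_class=herd.parity_class[hi],
            batch=herd.batch[hi],
            genotypes=gd_qc.subset(rows=[geno_pos[c] for c in keep_ids]),
            phenotypes=phen,
            n_removed_spectra_qc=int(pre.flags.sum()),
        )


def make_folds(n: int, k: int = 5, seed: int = 0) -> np.ndarray:
    """Random k-fold assignment; fold sizes differ by at most one."""
    if n < k:
        raise PipelineError(f"cannot split {n} cows into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    folds[perm] = np.arange(n) % k
    return folds


def _one_hot(values: np.ndarray, n_classes: int, prefix: str):
    values = np.asarray(values, dtype=int)
    mat = np.zeros((values.size, n_classes))
    mat[np.arange(values.size), values - 1] = 1.0
    names = [f"{prefix}_{c}" for c in range(1, n_classes + 1)]
    return mat, names


def build_design_matrix(
    spec: ModelLadderSpec,
    spectra_matrix: np.ndarray,
    dim_class: np.ndarray,
    parity_class: np.ndarray,
    genotype_matrix: np.ndarray | None = None,
    selected_markers: np.ndarray | None = None,
) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Column-wise block concatenation: spectra | DIM | parity | SNPs.

    Returns the matrix and per-column metadata ``(name, block)``. On-farm
    classes are full one-hot coded (6 + 3 columns); the genotype block is
    either all markers or the GWAS-selected subset.
    """
    blocks = [np.asarray(spectra_matrix, dtype=float)]
    meta = [(f"d{i + 1}", "spectra") for i in range(spectra_matrix.shape[1])]
    if spec.model_id in {"M2", "M3"}:
        dim_oh, dim_names = _one_hot(dim_class, N_DIM_CLASSES, "dim")
        par_oh, par_names = _one_hot(parity_class, N_PARITY_CLASSES, "parity")
        blocks += [dim_oh, par_oh]
        meta += [(n, "dim") for n in dim_names] + [(n, "parity") for n in par_names]
    if spec.model_id == "M3":
        if genotype_matrix is None:
            raise PipelineError("M3 requires the genotype block")
        G = np.asarray(genotype_matrix, dtype=float)
        if selected_markers is not None:
            G = G[:, selected_markers]
            meta += [(f"snp_sel{j}", "snp") for j in range(G.shape[1])]
        else:
            meta += [(f"snp{j}", "snp") for j in range(G.shape[1])]
        blocks.append(G)
    return np.hstack(blocks), meta


def compute_metrics(y_obs, y_pred) -> tuple[float, float, float]:
    """(Pearson r, RMSE, slope of the regression of y_pred on y_obs)."""
    y = np.asarray(y_obs, dtype=float).ravel()
    yhat = np.asarray(y_pred, dtype=float).ravel()
    if y.size != yhat.size or y.size < 3:
        raise PipelineError("need equal-length vectors with at least 3 entries")
    rmse = float(np.sqrt(np.mean((y - yhat) ** 2)))
    if np.std(y) == 0:
        warnings.warn("constant observed values: r and slope undefined")
        return np.nan, rmse, np.nan
    slope = float(np.cov(y, yhat, ddof=1)[0, 1] / np.var(y, ddof=1))
    if np.std(yhat) == 0:
        return np.nan, rmse, slope
    r = float(np.corrcoef(y, yhat)[0, 1])
    return r, rmse, slope


def relative_difference(r_m1: float, r_mn: float) -> float:
    """RD = (r_mn - r_m1) / r_m1 * 100, undefined (nan) when r_m1 = 0."""
    if r_m1 == 0 or not np.isfinite(r_m1):
        warnings.warn("RD undefined for r_m1 = 0")
        return np.nan
    return (r_mn - r_m1) / r_m1 * 100.0


@dataclass
class CvReport:
    """Per-fold metrics plus the per-fold artifacts needed for audits."""

    folds: pd.DataFrame  # metabolite, model, threshold, fold, r, rmse, slope, n_markers
    selected: dict = field(default_factory=dict)  # (metabolite, fold, thr) -> indices
    coefficients: dict = field(default_factory=dict)  # (metabolite, label, fold) -> beta
    tuned: dict = field(default_factory=dict)  # (metabolite, label, fold) -> (alpha, lam)
    config: PipelineConfig = None
    fold_assignment: np.ndarray = None

    def summary(self) -> pd.DataFrame:
        """Mean +/- SD across folds, with RD of each model versus M1."""
        g = (
            self.folds.groupby(["metabolite", "model"], sort=False)
            .agg(
                r_mean=("r", "mean"),
                r_sd=("r", "std"),
                rmse_mean=("rmse", "mean"),
                rmse_sd=("rmse", "std"),
                slope_mean=("slope", "mean"),
                slope_sd=("slope", "std"),
                n_markers_mean=("n_markers", "mean"),
                n_folds=("fold", "count"),
            )
            .reset_index()
        )
        rd = []
        for _, row in g.iterrows():
            base = g[(g["metabolite"] == row["metabolite"]) & (g["model"] == "M1")]
            if row["model"] == "M1" or base.empty:
                rd.append(np.nan)
            else:
                r1 = float(base["r_mean"].iloc[0])
                rd.append(relative_difference(r1, row["r_mean"]) if r1 != 0 else np.nan)
        g["rd_vs_m1"] = rd
        return g


def run_cv(
    dataset: HerdDataset,
    models: list[ModelLadderSpec],
    config: PipelineConfig | None = None,
) -> CvReport:
    """Run the full nested cross-validation over the model ladder."""
    config = config or PipelineConfig()
    n = dataset.n_cows
    folds = make_folds(n, config.k_folds, seed=config.seed)
    thresholds = sorted(
        {m.threshold for m in models if m.model_id == "M3" and m.threshold is not None}
    )
    need_gwas = bool(thresholds)
    geno = dataset.genotypes.matrix

    rows = []
    selected_store: dict = {}
    coef_store: dict = {}
    tuned_store: dict = {}
    for fold in range(config.k_folds):
        val = folds == fold
        tr = ~val
        tr_idx = np.flatnonzero(tr)
        val_idx = np.flatnonzero(val)
        for t_i, met in enumerate(dataset.metabolite_names):
            y = dataset.phenotypes[met].to_numpy(dtype=float)
            sel_by_thr: dict[float, np.ndarray] = {}
            if need_gwas:
                try:
                    sel_by_thr = _fold_gwas(
                        dataset, tr_idx, y[tr_idx], thresholds, config
                    )
                except Exception as exc:
                    raise PipelineError(
                        f"GWAS stage failed (fold {fold}, metabolite {met}): {exc}"
                    ) from exc
            for m_i, spec in enumerate(models):
                sel = None
                if spec.model_id == "M3" and spec.threshold is not None:
                    sel = sel_by_thr[spec.threshold]
                    if sel.size == 0:
                        warnings.warn(
                            f"empty selection at threshold {spec.threshold} "
                            f"(fold {fold}, {met}); falling back to all markers"
                        )
                        sel = None
                X, _ = build_design_matrix(
                    spec,
                    dataset.spectra_matrix,
                    dataset.dim_class,
                    dataset.parity_class,
                    genotype_matrix=geno if spec.model_id == "M3" else None,
                    selected_markers=sel,
                )
                tune_seed = (
                    config.seed * 1_000_003 + fold * 10_007 + t_i * 101 + m_i
                ) % (2**31)
                try:
                    tuned = tune_random_grid(
                        X[tr_idx],
                        y[tr_idx],
                        grid_step=config.grid_step,
                        n_candidates=config.n_candidates,
                        seed=tune_seed,
                        tol=config.enet_tol,
                        max_iter=config.enet_max_iter,
                        parameterization=config.enet_parameterization,
                    )
                except Exception as exc:
                    raise PipelineError(
                        f"elastic-net stage failed (fold {fold}, metabolite {met}, "
                        f"model {spec.label}): {exc}"
                    ) from exc
                pred = tuned.results.predict(X[val_idx])
                r, rmse, slope = compute_metrics(y[val_idx], pred)
                n_markers = (
                    (sel.size if sel is not None else geno.shape[1])
                    if spec.model_id == "M3"
                    else 0
                )
                rows.append(
                    (met, spec.label, spec.threshold, fold, r, rmse, slope, n_markers)
                )
                coef_store[(met, spec.label, fold)] = tuned.results.params.copy()
                tuned_store[(met, spec.label, fold)] = (tuned.alpha, tuned.lam)
            for thr, sel in sel_by_thr.items():
                selected_store[(met, fold, thr)] = sel
    folds_df = pd.DataFrame(
        rows,
        columns=[
            "metabolite",
            "model",
            "threshold",
            "fold",
            "r",
            "rmse",
            "slope",
            "n_markers",
        ],
    )
    return CvReport(
        folds=folds_df,
        selected=selected_store,
        coefficients=coef_store,
        tuned=tuned_store,
        config=config,
        fold_assignment=folds,
    )


def _fold_gwas(
    dataset: HerdDataset,
    tr_idx: np.ndarray,
    y_tr: np.ndarray,
    thresholds: list[float],
    config: PipelineConfig,
) -> dict[float, np.ndarray]:
    """Training-only GBLUP-GWAS; returns nested selections per threshold."""
    gd_tr = dataset.genotypes.subset(rows=tr_idx)
    grm = grm_vanraden(gd_tr)
    if config.grm_blend:
        grm = grm.blend()
    X, _ = gwas_design(dataset.dim_class[tr_idx], dataset.parity_class[tr_idx])
    model = GBLUP(y_tr, X, dataset.batch[tr_idx], grm)
    fit = model.fit(reml_tol=config.reml_tol, reml_max_iter=config.reml_max_iter)
    assoc = fit.snp_pvalues(fit.snp_effects(grm), method=config.pvalue_method)
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty selections handled by caller
        for thr in thresholds:
            out[thr] = select_markers(assoc, thr)
    return out


def report(cvreport: CvReport, directory) -> list[str]:
    """Write fold-level and summary CSVs, bar plots and a run manifest."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []

    folds_path = directory / "cv_folds.csv"
    cvreport.folds.to_csv(folds_path, index=False)
    written.append(folds_path.name)

    summary = cvreport.summary()
    summary_path = directory / "cv_summary.csv"
    summary.to_csv(summary_path, index=False)
    written.append(summary_path.name)

    for metric in ("r", "rmse"):
        fig, ax = plt.subplots(figsize=(8, 4))
        piv_m = summary.pivot(index="metabolite", columns="model", values=f"{metric}_mean")
        piv_s = summary.pivot(index="metabolite", columns="model", values=f"{metric}_sd")
        piv_m.plot.bar(ax=ax, yerr=piv_s, capsize=3, rot=0)
        ax.set_ylabel(f"mean {metric} (+/- SD over folds)")
        ax.set_title(f"Cross-validated {metric} by model")
        fig.tight_layout()
        fig_path = directory / f"cv_{metric}.png"
        fig.savefig(fig_path, dpi=120)
        plt.close(fig)
        written.append(fig_path.name)

    manifest = {
        "config": {
            k: (v if not isinstance(v, np.ndarray) else v.tolist())
            for k, v in vars(cvreport.config).items()
        }
        if cvreport.config
        else {},
        "n_folds": int(cvreport.folds["fold"].nunique()),
        "models": sorted(cvreport.folds["model"].unique().tolist()),
        "files": written,
    }
    with open(directory / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    written.append("run_manifest.json")
    return written
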