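"""End-to-end synthetic study runner.

Reproduces the *form* of the field study on generated herds: simulate a
herd, preprocess spectra, QC genotypes, then run the M1/M2/M3 ladder under
5-fold cross-validation with per-fold GWAS marker preselection, repeated
over several master seeds. Used by the acceptance script and the
directional-replication tests.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .pipeline import CvReport, HerdDataset, ModelLadderSpec, PipelineConfig, run_cv
from .simulate import SimConfig, simulate_herd

__all__ = ["run_synthetic_study", "default_models"]


def default_models(
    thresholds=(2.0,), include_all_markers: bool = True
) -> list[ModelLadderSpec]:
    models = [ModelLadderSpec("M1"), ModelLadderSpec("M2")]
    if include_all_markers:
        models.append(ModelLadderSpec("M3"))
    for thr in thresholds:
        models.append(ModelLadderSpec("M3", threshold=thr))
    return models


def run_synthetic_study(
    base_config: SimConfig,
    seeds,
    models: list[ModelLadderSpec] | None = None,
    pipeline_config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, list[CvReport]]:
    """Run the cross-validated ladder once per master seed.

    Each seed re-simulates the herd (same design, new realisation) and
    re-runs the full pipeline with fold/tuning seeds derived from it.
    Returns the concatenated per-fold metric table (with a ``seed`` column)
    and the individual :class:`CvReport` objects.
    """
    models = models or default_models()
    frames = []
    reports = []
    for seed in seeds:
        cfg = replace(base_config, seed=int(seed))
        herd = simulate_herd(cfg)
        dataset = HerdDataset.from_herd(herd)
        pcfg = pipeline_config or PipelineConfig()
        pcfg = replace(pcfg, seed=int(seed))
        rep = run_cv(dataset, models, pcfg)
        df = rep.folds.copy()
        df.insert(0, "seed", int(seed))
        # attach the simulated heritability of each metabolite
        h2 = dict(zip(cfg.metabolite_names, np.atleast_1d(cfg.heritabilities)))
        df["heritability"] = df["metabolite"].map(h2)
        frames.append(df)
        reports.append(rep)
    return pd.concat(frames, ignore_index=True), reports
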