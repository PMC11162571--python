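"""Reading and writing the on-disk dataset formats.

Genotypes travel as VCF v4.2 (GT-only) or as a whitespace-delimited coded
matrix; spectra as a long-format CSV (one row per sub-observation) and
phenotypes as a wide CSV with herd covariates. ``write_dataset`` emits all
of them plus a JSON manifest with row/column counts.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .genomics import GenotypeData
from .spectra import SpectraSet

__all__ = [
    "write_dataset",
    "write_vcf",
    "read_genotypes_vcf",
    "write_coded_matrix",
    "read_coded_matrix",
    "read_spectra_csv",
    "read_phenotypes_csv",
    "write_grm",
    "read_grm",
]


class DatasetIOError(OSError):
    pass


def write_vcf(gd: GenotypeData, path: Path) -> None:
    """Write genotypes as a minimal VCF v4.2 with GT fields only."""
    path = Path(path)
    code_to_gt = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(gd.marker_map["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gd.sample_ids)
            + "\n"
        )
        mm = gd.marker_map
        for j in range(gd.n_snps):
            gts = []
            for v in gd.matrix[:, j]:
                gts.append("./." if np.isnan(v) else code_to_gt[int(round(v))])
            fh.write(
                f"{mm['chrom'].iloc[j]}\t{mm['pos'].iloc[j]}\t{mm['snp_id'].iloc[j]}"
                f"\t{mm['ref'].iloc[j]}\t{mm['alt'].iloc[j]}\t.\t.\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_genotypes_vcf(path: Path) -> GenotypeData:
    """Read a (possibly gzipped) VCF into a coded 0/1/2 genotype matrix."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    recs = []
    # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
    lut = np.array([0.0, 1.0, np.nan, 2.0])
    for var in vcf:
        rows.append(lut[np.asarray(var.gt_types)])
        recs.append(
            (
                var.ID if var.ID else f"{var.CHROM}_{var.POS}",
                str(var.CHROM),
                int(var.POS),
                var.REF,
                var.ALT[0] if var.ALT else ".",
            )
        )
    if not rows:
        raise DatasetIOError(f"no variant records in {path}")
    marker_map = pd.DataFrame(recs, columns=["snp_id", "chrom", "pos", "ref", "alt"])
    return GenotypeData(
        matrix=np.array(rows).T, marker_map=marker_map, sample_ids=samples
    )


def write_coded_matrix(gd: GenotypeData, path: Path) -> None:
    """Whitespace-delimited coded matrix: cow id then one 0/1/2 code per SNP."""
    with open(path, "w") as fh:
        fh.write("cow_id " + " ".join(gd.marker_map["snp_id"]) + "\n")
        for cid, row in zip(gd.sample_ids, gd.matrix):
            codes = " ".join(
                "NA" if np.isnan(v) else str(int(round(v))) for v in row
            )
            fh.write(f"{cid} {codes}\n")


def read_coded_matrix(path: Path, marker_map: pd.DataFrame | None = None) -> GenotypeData:
    df = pd.read_csv(path, sep=r"\s+", na_values="NA")
    sample_ids = df["cow_id"].astype(str).tolist()
    snp_ids = [c for c in df.columns if c != "cow_id"]
    matrix = df[snp_ids].to_numpy(dtype=float)
    if marker_map is None:
        marker_map = pd.DataFrame(
            {
                "snp_id": snp_ids,
                "chrom": "1",
                "pos": np.arange(1, len(snp_ids) + 1),
                "ref": "A",
                "alt": "B",
            }
        )
    return GenotypeData(matrix=matrix, marker_map=marker_map, sample_ids=sample_ids)


def read_spectra_csv(path: Path, wavelengths: np.ndarray | None = None) -> SpectraSet:
    df = pd.read_csv(path)
    channel_cols = [c for c in df.columns if c.startswith("c") and c[1:].isdigit()]
    channel_cols.sort(key=lambda c: int(c[1:]))
    cow_ids, subs, weights = [], [], []
    for cid, grp in df.groupby("cow_id", sort=False):
        cow_ids.append(str(cid))
        grp = grp.sort_values("obs_index")
        subs.append(grp[channel_cols].to_numpy(dtype=float))
        weights.append(grp["milk_weight"].to_numpy(dtype=float))
    if wavelengths is None:
        wavelengths = np.linspace(400.0, 1000.0, len(channel_cols))
    return SpectraSet(
        cow_ids=cow_ids, sub_spectra=subs, weights=weights, wavelengths=wavelengths
    )


def read_phenotypes_csv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"cow_id", "batch", "dim_class", "parity_class"}
    missing = required - set(df.columns)
    if missing:
        raise DatasetIOError(f"phenotype file lacks columns: {sorted(missing)}")
    return df


def write_grm(grm, sample_ids: list[str], path: Path) -> None:
    """Write a GRM as whitespace-delimited lower-triangle text.

    Each line is ``i j value`` (1-based indices, j <= i); a companion
    ``<path>.ids`` file maps indices to cow ids.
    """
    G = np.asarray(grm.G)
    with open(path, "w") as fh:
        for i in range(G.shape[0]):
            for j in range(i + 1):
                fh.write(f"{i + 1} {j + 1} {G[i, j]:.12g}\n")
    with open(str(path) + ".ids", "w") as fh:
        for k, cid in enumerate(sample_ids):
            fh.write(f"{k + 1} {cid}\n")


def read_grm(path: Path) -> tuple[np.ndarray, list[str]]:
    ids = []
    with open(str(path) + ".ids") as fh:
        for line in fh:
            ids.append(line.split()[1])
    n = len(ids)
    G = np.zeros((n, n))
    with open(path) as fh:
        for line in fh:
            i, j, v = line.split()
            G[int(i) - 1, int(j) - 1] = G[int(j) - 1, int(i) - 1] = float(v)
    return G, ids


def write_dataset(herd, directory: Path) -> dict:
    """Write a synthetic herd to ``directory`` and return the file manifest."""
    directory = Path(directory)
    if herd.genotypes.n_cows == 0:
        raise DatasetIOError("refusing to write an empty herd (n = 0)")
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise DatasetIOError(f"cannot create {directory}: {exc}") from exc

    gd = herd.genotypes
    vcf_path = directory / "genotypes.vcf"
    write_vcf(gd, vcf_path)
    mat_path = directory / "genotypes.txt"
    write_coded_matrix(gd, mat_path)

    spectra_df = herd.spectra.to_frame()
    spectra_path = directory / "spectra.csv"
    spectra_df.to_csv(spectra_path, index=False)

    phen = pd.DataFrame(
        {
            "cow_id": herd.cow_ids,
            "batch": herd.batch,
            "dim_class": herd.dim_class,
            "parity_class": herd.parity_class,
        }
    )
    for t, name in enumerate(herd.metabolite_names):
        phen[name] = herd.phenotypes[:, t]
    phen_path = directory / "phenotypes.csv"
    phen.to_csv(phen_path, index=False)

    manifest = {
        "files": {
            "genotypes.vcf": {"records": gd.n_snps, "samples": gd.n_cows},
            "genotypes.txt": {"rows": gd.n_cows, "columns": gd.n_snps},
            "spectra.csv": {
                "rows": int(len(spectra_df)),
                "channels": herd.spectra.n_channels,
            },
            "phenotypes.csv": {
                "rows": gd.n_cows,
                "metabolites": len(herd.metabolite_names),
            },
        }
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
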