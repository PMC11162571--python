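"""Synthetic dairy-herd generator.

Produces herds with the statistical structure the downstream analysis
assumes: SNP genotypes in Hardy-Weinberg proportions with common alleles,
an additive sparse-QTL genetic architecture with configurable heritability,
random sampling-batch effects, days-in-milk (DIM) and parity class effects,
and 32-channel visible/NIR milk spectra driven by latent milk-composition
traits that are correlated with the blood metabolites.

Every quantity is drawn from a single seeded generator so that identical
configurations yield bit-identical herds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "SimConfig",
    "SyntheticHerd",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_spectra",
    "simulate_herd",
]

N_AUTOSOMES = 29  # Bos taurus

#: Marginal DIM-band frequencies (six bands, <60 d through >300 d) chosen to
#: mimic a herd with mostly early/mid lactation cows.
DEFAULT_DIM_PROBS = (0.25, 0.30, 0.20, 0.15, 0.07, 0.03)
#: Parity class frequencies (1st, 2nd, 3rd+), dominated by first-parity cows.
DEFAULT_PARITY_PROBS = (0.70, 0.18, 0.12)


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass
class SimConfig:
    """Configuration of one synthetic herd.

    Parameters
    ----------
    n_cows, n_snps, n_qtl
        Herd size, marker panel size and number of causal loci per trait.
    heritability
        Narrow-sense heritability of each metabolite (scalar, applied to all
        traits, or one value per trait). The number of simulated metabolites
        equals ``len(heritability)`` when a sequence is given.
    batch_variance_fraction
        Fraction of phenotypic variance attributable to the random
        blood-sampling-batch effect.
    spectra_signal_r2
        Fraction of metabolite variance reflected in the latent milk
        fat/protein traits that drive the spectra; 0 decouples spectra
        from the metabolites entirely.
    dim_class_effects, parity_class_effects
        Fixed-effect sizes (phenotypic-SD units) for the six DIM bands and
        three parity classes.
    subobs_sd
        Within-cow standard deviation of the ~70 per-milking spectral
        sub-observations around the cow's mean spectrum.
    ld_block_size, ld_block_rho
        When ``ld_block_size > 1``, genotypes are drawn with a Gaussian-copula
        block-correlation structure (adjacent markers within a block share
        latent correlation ``ld_block_rho``); the default is independent loci.
    """

    n_cows: int = 400
    n_snps: int = 5000
    n_qtl: int = 50
    heritability: float | tuple[float, ...] = (0.1, 0.4, 0.7)
    batch_variance_fraction: float = 0.1
    n_batches: int = 7
    n_channels: int = 32
    spectra_signal_r2: float = 0.3
    noise_sd_channels: float = 0.05
    dim_class_effects: tuple[float, ...] = (0.0, 0.25, 0.45, 0.55, 0.7, 0.8)
    parity_class_effects: tuple[float, ...] = (0.0, 0.15, 0.3)
    seed: int = 0
    maf_range: tuple[float, float] = (0.05, 0.5)
    mean_subobs: float = 70.0
    subobs_sd: float = 0.1
    milk_weight_range: tuple[float, float] = (0.20, 0.33)
    dim_class_probs: tuple[float, ...] = DEFAULT_DIM_PROBS
    parity_class_probs: tuple[float, ...] = DEFAULT_PARITY_PROBS
    ld_block_size: int = 1
    ld_block_rho: float = 0.0

    def __post_init__(self) -> None:
        if self.n_cows < 1 or self.n_snps < 1:
            raise ConfigurationError("n_cows and n_snps must be positive")
        if not 0 <= self.n_qtl <= self.n_snps:
            raise ConfigurationError("need 0 <= n_qtl <= n_snps")
        h2 = np.atleast_1d(np.asarray(self.heritability, dtype=float))
        if not np.all(np.isfinite(h2)) or np.any(h2 < 0) or np.any(h2 > 1):
            raise ConfigurationError("heritability must lie in [0, 1]")
        if not 0 <= self.batch_variance_fraction < 1:
            raise ConfigurationError("batch_variance_fraction must lie in [0, 1)")
        if np.any(h2 + self.batch_variance_fraction >= 1.0 + 1e-12):
            raise ConfigurationError(
                "heritability + batch_variance_fraction must be < 1"
            )
        if self.n_channels < 2:
            raise ConfigurationError("n_channels must be >= 2")
        if len(self.dim_class_effects) != 6:
            raise ConfigurationError("dim_class_effects needs 6 entries")
        if len(self.parity_class_effects) != 3:
            raise ConfigurationError("parity_class_effects needs 3 entries")
        if self.n_batches < 1:
            raise ConfigurationError("n_batches must be positive")
        if not (0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise ConfigurationError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.noise_sd_channels < 0 or self.subobs_sd < 0:
            raise ConfigurationError("noise SDs must be non-negative")

    @property
    def heritabilities(self) -> np.ndarray:
        return np.atleast_1d(np.asarray(self.heritability, dtype=float))

    @property
    def n_metabolites(self) -> int:
        return self.heritabilities.size

    @property
    def metabolite_names(self) -> list[str]:
        return [f"met{i + 1}" for i in range(self.n_metabolites)]


@dataclass
class SyntheticHerd:
    """One realised herd: genotypes, phenotypes and milk spectra."""

    config: SimConfig
    genotypes: "GenotypeData"  # noqa: F821 - forward ref to milkpred.genomics
    qtl_indices: np.ndarray  # (n_traits, n_qtl)
    qtl_effects: np.ndarray  # (n_traits, n_snps), sparse rows
    breeding_values: np.ndarray  # (n_cows, n_traits)
    phenotypes: np.ndarray  # (n_cows, n_traits)
    dim_class: np.ndarray  # values 1..6
    parity_class: np.ndarray  # values 1..3
    batch: np.ndarray  # values 0..n_batches-1
    spectra: "SpectraSet"  # noqa: F821 - forward ref to milkpred.spectra

    @property
    def cow_ids(self) -> list[str]:
        return self.genotypes.sample_ids

    @property
    def metabolite_names(self) -> list[str]:
        return self.config.metabolite_names


def _simulate_block_correlated(
    rng: np.random.Generator, q: np.ndarray, n_cows: int, block: int, rho: float
) -> np.ndarray:
    """Genotypes with Gaussian-copula correlation inside marker blocks."""
    p = q.size
    thresholds = stats.norm.ppf(q)
    geno = np.zeros((n_cows, p), dtype=np.int8)
    for start in range(0, p, block):
        stop = min(start + block, p)
        width = stop - start
        for _gamete in range(2):
            shared = rng.standard_normal(n_cows)[:, None]
            own = rng.standard_normal((n_cows, width))
            z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * own
            geno[:, start:stop] += (z < thresholds[start:stop]).astype(np.int8)
    return geno


def simulate_genotypes(config: SimConfig) -> "GenotypeData":  # noqa: F821
    """Draw SNP genotypes for the herd.

    Per-SNP alternate-allele frequencies are uniform on ``config.maf_range``
    and genotypes are Binomial(2, q) per cow (independent loci by default, or
    block-correlated when ``ld_block_size > 1``). Markers are laid out along
    the 29 bovine autosomes in position order.
    """
    from .genomics import GenotypeData

    if config.n_cows < 2:
        raise ConfigurationError("simulate_genotypes needs n_cows >= 2")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    lo, hi = config.maf_range
    q = rng.uniform(lo, hi, size=config.n_snps)
    if config.ld_block_size > 1:
        geno = _simulate_block_correlated(
            rng, q, config.n_cows, config.ld_block_size, config.ld_block_rho
        )
    else:
        geno = rng.binomial(2, q, size=(config.n_cows, config.n_snps)).astype(np.int8)

    per_chrom = -(-config.n_snps // N_AUTOSOMES)  # ceil
    chrom = np.array(
        [str(i // per_chrom + 1) for i in range(config.n_snps)], dtype=object
    )
    pos = np.array(
        [10_000 * (i % per_chrom + 1) for i in range(config.n_snps)], dtype=np.int64
    )
    marker_map = _make_marker_map(chrom, pos, config.n_snps)
    sample_ids = [f"cow{i + 1:04d}" for i in range(config.n_cows)]
    return GenotypeData(
        matrix=geno.astype(float), marker_map=marker_map, sample_ids=sample_ids
    )


def _make_marker_map(chrom, pos, n_snps):
    import pandas as pd

    return pd.DataFrame(
        {
            "snp_id": [f"snp{i + 1:06d}" for i in range(n_snps)],
            "chrom": chrom,
            "pos": pos,
            "ref": "A",
            "alt": "B",
        }
    )


def simulate_phenotypes(genotypes, config: SimConfig):
    """Simulate metabolite phenotypes on top of a genotype matrix.

    Each trait follows ``y = mu + DIM effect + parity effect + batch + a + e``
    with the additive value ``a`` built from ``n_qtl`` loci carrying normal
    effects, rescaled so the realised genetic variance equals the configured
    heritability on the unit phenotypic-variance scale (heritability + batch
    fraction + residual fraction = 1 before fixed effects are added).

    Returns
    -------
    dict with keys ``phenotypes``, ``breeding_values``, ``qtl_indices``,
    ``qtl_effects``, ``dim_class``, ``parity_class``, ``batch``.
    """
    h2 = config.heritabilities
    if np.any(h2 + config.batch_variance_fraction >= 1.0 + 1e-12):
        raise ConfigurationError("heritability + batch fraction must be < 1")
    geno = np.asarray(genotypes.matrix, dtype=float)
    n, p = geno.shape
    if p < 1 or n < 2:
        raise ConfigurationError("degenerate genotype matrix")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    centered = geno - geno.mean(axis=0)

    n_traits = config.n_metabolites
    qtl_idx = np.zeros((n_traits, config.n_qtl), dtype=np.int64)
    qtl_eff = np.zeros((n_traits, p))
    bv = np.zeros((n, n_traits))
    for t in range(n_traits):
        if config.n_qtl > 0 and h2[t] > 0:
            idx = np.sort(rng.choice(p, size=config.n_qtl, replace=False))
            raw = rng.standard_normal(config.n_qtl)
            a = centered[:, idx] @ raw
            sd = a.std()
            if sd == 0:
                raise ConfigurationError("QTL genotypes are monomorphic")
            scale = np.sqrt(h2[t]) / sd
            qtl_idx[t] = idx
            qtl_eff[t, idx] = raw * scale
            bv[:, t] = a * scale
        else:
            # keep the RNG stream aligned across heritability settings
            if config.n_qtl > 0:
                rng.choice(p, size=config.n_qtl, replace=False)
                rng.standard_normal(config.n_qtl)

    dim_class = rng.choice(
        np.arange(1, 7), size=n, p=np.asarray(config.dim_class_probs) / np.sum(config.dim_class_probs)
    )
    parity_class = rng.choice(
        np.arange(1, 4),
        size=n,
        p=np.asarray(config.parity_class_probs) / np.sum(config.parity_class_probs),
    )
    batch = rng.integers(0, config.n_batches, size=n)

    sd_batch = np.sqrt(config.batch_variance_fraction)
    dim_eff = np.asarray(config.dim_class_effects)[dim_class - 1]
    par_eff = np.asarray(config.parity_class_effects)[parity_class - 1]

    phen = np.zeros((n, n_traits))
    for t in range(n_traits):
        batch_values = rng.standard_normal(config.n_batches) * sd_batch
        resid_sd = np.sqrt(max(1.0 - h2[t] - config.batch_variance_fraction, 0.0))
        e = rng.standard_normal(n) * resid_sd
        phen[:, t] = dim_eff + par_eff + batch_values[batch] + bv[:, t] + e

    return {
        "phenotypes": phen,
        "breeding_values": bv,
        "qtl_indices": qtl_idx,
        "qtl_effects": qtl_eff,
        "dim_class": dim_class,
        "parity_class": parity_class,
        "batch": batch,
    }


def _channel_basis(n_channels: int) -> tuple[np.ndarray, np.ndarray]:
    """Smooth fixed response curves of the channels to the two latent traits.

    Returns (wavelengths_nm, basis) with basis of shape (n_channels, 2):
    Gaussian absorption-like bumps, one peaking in the red/NIR region (fat)
    and one at the long-wavelength end (protein), each on a mild baseline.
    """
    wl = np.linspace(400.0, 1000.0, n_channels)
    fat = 0.8 * np.exp(-0.5 * ((wl - 780.0) / 90.0) ** 2) + 0.1 * np.exp(
        -0.5 * ((wl - 550.0) / 60.0) ** 2
    )
    protein = 0.7 * np.exp(-0.5 * ((wl - 940.0) / 70.0) ** 2) + 0.15 * np.exp(
        -0.5 * ((wl - 480.0) / 50.0) ** 2
    )
    return wl, np.column_stack([fat, protein])


def simulate_spectra(phenotypes: dict, config: SimConfig):
    """Simulate per-milking spectral sub-observations for every cow.

    Two latent milk-composition traits (fat, protein) are linear combinations
    of the metabolites plus noise, mixed so that the latents carry
    ``spectra_signal_r2`` of the metabolite variance. Each cow receives
    ``k ~ Poisson(mean_subobs)`` sub-observations (at least one); every
    sub-observation is the basis expansion of the cow's latent traits plus
    within-cow and channel noise, and carries a positive milk-quantity weight.
    """
    from .spectra import SpectraSet

    if config.n_channels < 2:
        raise ConfigurationError("n_channels must be >= 2")
    phen = np.asarray(phenotypes["phenotypes"], dtype=float)
    n, n_traits = phen.shape
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))

    phen_std = (phen - phen.mean(axis=0)) / np.where(phen.std(axis=0) == 0, 1.0, phen.std(axis=0))
    # symmetric fixed mixing: every metabolite loads with equal magnitude
    # on both latent traits (signs alternate on protein), so no trait is
    # privileged in the spectra
    w_fat = np.ones(n_traits) / max(np.sqrt(n_traits), 1.0)
    w_pro = ((-1.0) ** np.arange(n_traits)) / max(np.sqrt(n_traits), 1.0)
    latent = np.zeros((n, 2))
    r2 = config.spectra_signal_r2
    for k, w in enumerate((w_fat, w_pro)):
        combo = phen_std @ w
        sdc = combo.std()
        combo = combo / sdc if sdc > 0 else combo
        latent[:, k] = np.sqrt(r2) * combo + np.sqrt(1.0 - r2) * rng.standard_normal(n)

    wl, basis = _channel_basis(config.n_channels)
    baseline = 1.0 + 0.3 * np.sin(wl / 200.0)
    cow_mean = baseline[None, :] + latent @ basis.T  # (n, channels)

    counts = np.maximum(rng.poisson(config.mean_subobs, size=n), 1)
    lo_w, hi_w = config.milk_weight_range
    sub_spectra: list[np.ndarray] = []
    sub_weights: list[np.ndarray] = []
    for i in range(n):
        k = counts[i]
        noise = config.subobs_sd * rng.standard_normal((k, config.n_channels))
        noise += config.noise_sd_channels * rng.standard_normal((k, config.n_channels))
        sub_spectra.append(cow_mean[i][None, :] + noise)
        sub_weights.append(rng.uniform(lo_w, hi_w, size=k))

    cow_ids = [f"cow{i + 1:04d}" for i in range(n)]
    return SpectraSet(
        cow_ids=cow_ids,
        sub_spectra=sub_spectra,
        weights=sub_weights,
        wavelengths=wl,
    )


def simulate_herd(config: SimConfig) -> SyntheticHerd:
    """Generate a complete synthetic herd (genotypes, phenotypes, spectra)."""
    gd = simulate_genotypes(config)
    ph = simulate_phenotypes(gd, config)
    spectra = simulate_spectra(ph, config)
    return SyntheticHerd(
        config=config,
        genotypes=gd,
        qtl_indices=ph["qtl_indices"],
        qtl_effects=ph["qtl_effects"],
        breeding_values=ph["breeding_values"],
        phenotypes=ph["phenotypes"],
        dim_class=ph["dim_class"],
        parity_class=ph["parity_class"],
        batch=ph["batch"],
        spectra=spectra,
    )
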