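"""Synthetic case/control GWAS data with realistic local LD.

The generator emulates haplotype-mosaic resampling: a small reference
panel of binary haplotypes carries local linkage disequilibrium, and
each simulated individual is built from two independent "imperfect
mosaic" haplotypes that copy a panel template, switching template at
each site with a small probability (the recombination analogue).
Genotypes are the allele sum (0/1/2).

Panel haplotypes are drawn from a Gaussian-copula AR(1) process: a
latent first-order autoregressive Gaussian per haplotype, thresholded
site-by-site at the quantile of that site's target allele frequency.
This gives exact Bernoulli(f_j) marginals (frequencies drawn uniformly
from ``maf_range``) together with positive, tunable correlation between
nearby sites, which the mosaic step then propagates into the cohort's
LD structure.

Disease labels are optional: a penetrance table assigns each sample a
case probability from its genotype combination at a chosen causal
tuple, so both null cohorts (flat table) and embedded k-way interaction
effects can be produced.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .genotype_io import MISSING, GenotypeMatrix


@dataclass
class HaplotypePanel:
    """Reference panel of h binary haplotypes over m SNP sites."""

    alleles: np.ndarray  # (h, m) uint8, strictly {0,1}
    recomb_rate: float  # per-site template-switch probability for mosaics

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 2 or self.alleles.shape[0] < 2:
            raise ValueError("panel needs >= 2 haplotypes (h x m array)")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("panel alleles must be strictly binary")
        if not 0.0 <= self.recomb_rate <= 1.0:
            raise ValueError("recomb_rate must be in [0, 1]")

    @property
    def h(self) -> int:
        return self.alleles.shape[0]

    @property
    def m(self) -> int:
        return self.alleles.shape[1]


def generate_panel(
    h: int,
    m: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    recomb_rate: float = 0.01,
    ld_strength: float = 0.9,
) -> HaplotypePanel:
    """Draw a reference haplotype panel with local LD.

    Parameters
    ----------
    h, m
        Number of haplotypes and SNP sites (h >= 2, m >= 1).
    maf_range
        Per-site target minor-allele frequencies are drawn uniformly
        from this sub-interval of (0, 0.5].
    recomb_rate
        Per-site template-switch probability stored on the panel and
        used later by :func:`simulate_genotypes`.
    ld_strength
        AR(1) coefficient of the latent Gaussian in [0, 1); 0 gives
        independent sites, values near 1 give long haplotype blocks.
    """
    if h < 2 or m < 1:
        raise ValueError("need h >= 2 haplotypes and m >= 1 sites")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must lie within (0, 0.5], got {maf_range}")
    if not 0.0 <= ld_strength < 1.0:
        raise ValueError("ld_strength must be in [0, 1)")
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(lo, hi, size=m)
    z = np.empty((h, m))
    z[:, 0] = rng.standard_normal(h)
    innov = rng.standard_normal((h, m)) * np.sqrt(1.0 - ld_strength**2)
    for j in range(1, m):
        z[:, j] = ld_strength * z[:, j - 1] + innov[:, j]
    # Phi(z) is uniform, so thresholding at f_j gives exact Bernoulli(f_j)
    alleles = (norm.cdf(z) < freqs[None, :]).astype(np.uint8)
    return HaplotypePanel(alleles=alleles, recomb_rate=recomb_rate)


def simulate_genotypes(
    panel: HaplotypePanel,
    n: int,
    seed: int = 0,
    missing_rate: float = 0.0,
    snp_prefix: str = "snp",
) -> GenotypeMatrix:
    """Simulate n unlabeled individuals as pairs of mosaic haplotypes.

    Each haplotype copies a uniformly chosen panel template, re-choosing
    the template at every site with probability ``panel.recomb_rate``;
    the genotype is the sum of the two haplotype alleles.  Phenotypes
    are all 0 (controls) until assigned.
    """
    if n < 1:
        raise ValueError("need n >= 1 samples")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    h, m = panel.h, panel.m
    draws = 2 * n

    switch = rng.random((draws, m)) < panel.recomb_rate
    switch[:, 0] = True  # initial template choice
    candidates = rng.integers(0, h, size=(draws, m), dtype=np.int32)
    cols = np.arange(m, dtype=np.int32)
    # forward-fill: index of the most recent switch site per position
    last_switch = np.maximum.accumulate(np.where(switch, cols, -1), axis=1)
    rows = np.arange(draws, dtype=np.int32)[:, None]
    templates = candidates[rows, last_switch]
    haps = panel.alleles[templates, cols[None, :]]
    geno = (haps[0::2].astype(np.int8) + haps[1::2].astype(np.int8)).T  # (m, n)

    if missing_rate > 0.0:
        geno[rng.random(geno.shape) < missing_rate] = MISSING

    return GenotypeMatrix(
        snp_ids=[f"{snp_prefix}{i}" for i in range(m)],
        genotypes=geno,
        phenotypes=np.zeros(n, dtype=np.int8),
        allow_single_class=True,
    )


@dataclass
class PenetranceModel:
    """P(case | genotype combination) for a k-SNP causal tuple.

    ``table[j]`` is the case probability of the combination whose base-3
    digits are ``j`` with the FIRST SNP of the causal tuple as the most
    significant digit (the same enumeration the contingency tables use).
    ``baseline`` applies to samples with a missing genotype at the tuple.
    """

    k: int
    table: np.ndarray  # (3**k,) probabilities
    baseline: float = 0.0

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=np.float64)
        if self.table.shape != (3**self.k,):
            raise ValueError(f"table must have 3^{self.k} entries")
        if ((self.table < 0) | (self.table > 1)).any() or not 0 <= self.baseline <= 1:
            raise ValueError("penetrances must be probabilities in [0, 1]")

    @classmethod
    def null(cls, k: int, prevalence: float = 0.5) -> "PenetranceModel":
        """Flat table: phenotype independent of genotype (null model)."""
        return cls(k=k, table=np.full(3**k, prevalence), baseline=prevalence)

    @classmethod
    def from_effects(
        cls,
        k: int,
        effects: dict[tuple[int, ...], float],
        baseline: float,
    ) -> "PenetranceModel":
        """Sparse construction: ``effects`` maps combinations to case
        probabilities; unspecified combinations get ``baseline``."""
        table = np.full(3**k, baseline)
        for combo, p in effects.items():
            if len(combo) != k or any(g not in (0, 1, 2) for g in combo):
                raise ValueError(f"bad genotype combination {combo}")
            j = 0
            for g in combo:
                j = 3 * j + g
            table[j] = p
        return cls(k=k, table=table, baseline=baseline)

    @classmethod
    def xor_pair(cls, high: float = 0.8, low: float = 0.1) -> "PenetranceModel":
        """Pure-epistasis pairwise model: case probability ``high`` on
        odd-parity genotype combinations (g_a + g_b odd), ``low``
        elsewhere.  Neither SNP has a marginal effect under allele
        frequency 0.5; jointly the pair is strongly associated."""
        table = np.empty(9)
        for ga in range(3):
            for gb in range(3):
                table[3 * ga + gb] = high if (ga + gb) % 2 == 1 else low
        return cls(k=2, table=table, baseline=low)


def assign_phenotypes(
    gm: GenotypeMatrix,
    model: PenetranceModel,
    indices: Sequence[int],
    target_cases: int | None = None,
    seed: int = 0,
    n_out: int | None = None,
) -> GenotypeMatrix:
    """Label samples as cases/controls from a penetrance model.

    Each sample becomes a case with the probability given by its
    genotype combination at ``indices``.  If ``target_cases`` is given,
    a cohort of ``n_out`` samples (default: all) with exactly
    ``target_cases`` cases and ``n_out - target_cases`` controls is
    subsampled from the labeled pool; simulate more genotypes than
    ``n_out`` to make the target reachable.  Deterministic per seed.
    """
    tup = tuple(int(i) for i in indices)
    if len(tup) != model.k:
        raise ValueError(f"tuple {tup} does not match model order k={model.k}")
    if len(set(tup)) != len(tup) or any(not 0 <= i < gm.m for i in tup):
        raise ValueError(f"invalid SNP tuple {tup} for m={gm.m}")
    rng = np.random.default_rng(seed)

    combo = np.zeros(gm.n, dtype=np.int64)
    missing = np.zeros(gm.n, dtype=bool)
    for snp in tup:
        g = gm.genotypes[snp].astype(np.int64)
        missing |= g == MISSING
        combo = 3 * combo + np.clip(g, 0, 2)
    probs = np.where(missing, model.baseline, model.table[combo])
    pheno = (rng.random(gm.n) < probs).astype(np.int8)

    if target_cases is None:
        return GenotypeMatrix(
            snp_ids=list(gm.snp_ids),
            genotypes=gm.genotypes.copy(),
            phenotypes=pheno,
            sample_ids=list(gm.sample_ids),
        )

    n_out = gm.n if n_out is None else int(n_out)
    if not 0 < target_cases < n_out:
        raise ValueError("need 0 < target_cases < n_out")
    cases = np.flatnonzero(pheno == 1)
    controls = np.flatnonzero(pheno == 0)
    if len(cases) < target_cases or len(controls) < n_out - target_cases:
        raise ValueError(
            f"drew {len(cases)} cases / {len(controls)} controls; cannot form a "
            f"cohort of {target_cases} cases + {n_out - target_cases} controls — "
            "simulate a larger pool of genotypes (larger n)"
        )
    keep = np.sort(
        np.concatenate(
            [
                rng.choice(cases, size=target_cases, replace=False),
                rng.choice(controls, size=n_out - target_cases, replace=False),
            ]
        )
    )
    return GenotypeMatrix(
        snp_ids=list(gm.snp_ids),
        genotypes=gm.genotypes[:, keep].copy(),
        phenotypes=pheno[keep],
        sample_ids=[gm.sample_ids[i] for i in keep],
    )


def simulate_dataset(
    m: int,
    n: int,
    h: int = 100,
    maf_range: tuple[float, float] = (0.05, 0.5),
    recomb_rate: float = 0.01,
    ld_strength: float = 0.9,
    seed: int = 0,
    model: PenetranceModel | None = None,
    effect_tuple: Sequence[int] | None = None,
    target_cases: int | None = None,
    n_pool: int | None = None,
    missing_rate: float = 0.0,
) -> GenotypeMatrix:
    """One-call cohort simulation: panel -> mosaic genotypes -> labels.

    With no ``model``, labels come from a flat 0.5-prevalence null
    table at a dummy tuple (phenotype independent of genotype).  With a
    model and ``effect_tuple``, the interaction effect is embedded at
    that tuple.  ``n_pool`` genotypes (default ``2 n`` when a case
    target is set, else ``n``) are simulated before subsampling.
    """
    if n_pool is None:
        n_pool = 2 * n if target_cases is not None else n
    panel = generate_panel(
        h, m, maf_range=maf_range, seed=seed, recomb_rate=recomb_rate,
        ld_strength=ld_strength,
    )
    pool = simulate_genotypes(panel, n_pool, seed=seed + 1, missing_rate=missing_rate)
    if model is None:
        model = PenetranceModel.null(k=1, prevalence=0.5)
        effect_tuple = (0,)
    elif effect_tuple is None:
        raise ValueError("an effect model requires an effect_tuple")
    return assign_phenotypes(
        pool, model, effect_tuple, target_cases=target_cases, seed=seed + 2, n_out=n
    )
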