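"""Synthetic regional genetics: LD-structured genotypes plus phenotypes.

This module fabricates the substrate the rest of the pipeline operates on —
a single genomic region (~600 kb by default) of biallelic SNPs carried by a
cohort of unrelated individuals, with

* block-structured linkage disequilibrium (LD) generated at the haplotype
  level from an AR(1) Gaussian copula, so genotype correlation decays
  monotonically with inter-SNP distance within a block and vanishes across
  block boundaries;
* one continuous expression phenotype, optionally cis-regulated by a single
  causal SNP explaining a configurable fraction ``h2_expr`` of its variance;
* one binary disease phenotype drawn per individual from a logistic model
  with a configurable per-allele log odds ratio at a (possibly distinct,
  possibly shared) causal SNP.

Every draw is reproducible from ``SimulationConfig.seed``; the three
generation stages use disjoint seed substreams so that, e.g., regenerating
expression with a different architecture leaves the genotypes untouched.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "SimulationConfig",
    "RegionDataset",
    "generate_genotypes",
    "generate_expression",
    "generate_disease",
    "generate_dataset",
]

# seed substream tags: genotypes / expression / disease
_STAGE_GENO, _STAGE_EXPR, _STAGE_DIS = 0, 1, 2

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic regional cohort.

    Defaults emulate a blood-donor eQTL panel of 320 genotyped individuals
    over a 600 kb region; see docs/methods.md for the rationale behind each
    default.

    Parameters
    ----------
    n_individuals
        Cohort size (same individuals carry genotypes, expression, disease).
    n_snps
        Number of biallelic SNPs in the region.
    maf_range
        Per-SNP target frequency of allele 1 is drawn uniformly from this
        interval; both ends must lie in (0, 0.5].
    ld_decay
        AR(1) correlation rho of adjacent latent haplotype variables within
        an LD block, in [0, 1); latent corr(i, j) = rho**|i-j| inside a
        block and 0 across blocks.
    block_size
        Number of consecutive SNPs per LD block.
    causal_index_expr, h2_expr
        Index of the SNP driving expression and the fraction of expression
        variance its dosage explains in expectation; ``None`` index means a
        pure-noise trait.
    causal_index_dis, log_or_dis
        Index of the disease risk SNP and its per-allele log odds ratio.
    prevalence
        Dosage-averaged case probability; the logistic intercept is solved
        numerically on the realized dosages so the expected case fraction
        equals this value exactly.
    region_span
        Length in base pairs over which SNP positions are scattered
        (cosmetic: positions are metadata for export/plotting only).
    seed
        Master seed; identical config + seed reproduces byte-identical
        output.
    """

    n_individuals: int = 320
    n_snps: int = 200
    maf_range: Tuple[float, float] = (0.05, 0.5)
    ld_decay: float = 0.8
    block_size: int = 20
    causal_index_expr: Optional[int] = None
    h2_expr: float = 0.0
    causal_index_dis: Optional[int] = None
    log_or_dis: float = 0.0
    prevalence: float = 0.5
    region_span: int = 600_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        if self.n_snps < 2:
            raise ValueError("n_snps must be >= 2")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(
                f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}"
            )
        if not (0.0 <= self.ld_decay < 1.0):
            raise ValueError(f"ld_decay must lie in [0, 1), got {self.ld_decay}")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        if not (0.0 <= self.h2_expr < 1.0):
            raise ValueError(f"h2_expr must lie in [0, 1), got {self.h2_expr}")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError(f"prevalence must lie in (0, 1), got {self.prevalence}")
        for name in ("causal_index_expr", "causal_index_dis"):
            idx = getattr(self, name)
            if idx is not None and not (0 <= idx < self.n_snps):
                raise ValueError(f"{name}={idx} outside [0, {self.n_snps})")
        if self.region_span < self.n_snps:
            raise ValueError("region_span must allow distinct positions")


@dataclass
class RegionDataset:
    """Genotypes, SNP metadata and phenotypes for one region.

    ``dosages`` counts copies of allele 1 (0/1/2) per individual x SNP;
    ``expression`` and ``disease`` are ``None`` until their generation stage
    (or a file reader) fills them. ``truth`` keeps the generating config for
    downstream truth-recovery checks; file-loaded datasets carry ``None``.
    """

    sample_ids: Sequence[str]
    snp_ids: Sequence[str]
    positions: np.ndarray
    allele1: np.ndarray
    allele2: np.ndarray
    dosages: np.ndarray
    expression: Optional[np.ndarray] = None
    disease: Optional[np.ndarray] = None
    truth: Optional[SimulationConfig] = None

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def replace(self, **kwargs) -> "RegionDataset":
        return dataclasses.replace(self, **kwargs)


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage]))


def generate_genotypes(config: SimulationConfig) -> RegionDataset:
    """Draw LD-structured dosages and SNP metadata.

    Two latent haplotypes per individual are drawn from a within-block AR(1)
    Gaussian copula: latent z_j = rho * z_{j-1} + sqrt(1-rho^2) * eps at SNPs
    j in the same block as j-1, fresh standard normal at block starts. A
    haplotype carries allele 1 at SNP s iff z_s < Phi^{-1}(maf_s), so each
    site has its target allele-1 frequency and Hardy-Weinberg genotype
    proportions in expectation, and dosage correlation decays with distance.
    """
    rng = _rng(config.seed, _STAGE_GENO)
    n, m = config.n_individuals, config.n_snps
    rho = config.ld_decay

    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    thresholds = stats.norm.ppf(mafs)

    # (2n, m) latent matrix: one row per haplotype
    eps = rng.standard_normal(size=(2 * n, m))
    z = np.empty_like(eps)
    z[:, 0] = eps[:, 0]
    scale = np.sqrt(1.0 - rho * rho)
    for j in range(1, m):
        if j % config.block_size == 0:  # new LD block: break the chain
            z[:, j] = eps[:, j]
        else:
            z[:, j] = rho * z[:, j - 1] + scale * eps[:, j]

    haplo = (z < thresholds[None, :]).astype(np.int8)
    dosages = haplo[0::2] + haplo[1::2]

    positions = np.sort(rng.choice(config.region_span, size=m, replace=False)) + 1
    allele_idx = np.array([rng.choice(4, size=2, replace=False) for _ in range(m)])
    allele1 = _BASES[allele_idx[:, 0]]
    allele2 = _BASES[allele_idx[:, 1]]
    width = max(4, len(str(m)))
    snp_ids = [f"snp{j + 1:0{width}d}" for j in range(m)]
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    return RegionDataset(
        sample_ids=sample_ids,
        snp_ids=snp_ids,
        positions=positions.astype(np.int64),
        allele1=allele1,
        allele2=allele2,
        dosages=dosages,
        truth=config,
    )


def generate_expression(data: RegionDataset, config: SimulationConfig) -> RegionDataset:
    """Fill the expression phenotype.

    With a causal SNP c, expression = beta * g_c + eps where eps is standard
    normal and beta = sqrt(h2 / ((1 - h2) * var(g_c))), so g_c explains
    exactly ``h2_expr`` of the variance in expectation. Without one the
    trait is pure noise. The trait is mean-centered (simple-regression
    slopes, R^2 and p-values are unaffected).
    """
    rng = _rng(config.seed, _STAGE_EXPR)
    eps = rng.standard_normal(config.n_individuals)
    if config.causal_index_expr is not None and config.h2_expr > 0:
        c = config.causal_index_expr
        g = data.dosages[:, c].astype(float)
        var_g = g.var()
        if var_g == 0:
            raise ValueError(
                f"expression causal SNP {data.snp_ids[c]} (index {c}) is "
                "monomorphic in this sample"
            )
        beta = np.sqrt(config.h2_expr / ((1.0 - config.h2_expr) * var_g))
        expr = beta * g + eps
    else:
        expr = eps
    expr = expr - expr.mean()
    return data.replace(expression=expr, truth=config)


def _solve_intercept(g: np.ndarray, log_or: float, prevalence: float) -> float:
    """Intercept alpha with mean(expit(alpha + log_or * g)) == prevalence.

    Solved numerically on the realized dosage distribution: the mean case
    probability is strictly increasing in alpha, so brentq on a wide bracket
    is exact to float precision.
    """

    def mean_risk(alpha: float) -> float:
        return float(special.expit(alpha + log_or * g).mean()) - prevalence

    return float(optimize.brentq(mean_risk, -40.0, 40.0, xtol=1e-12))


def generate_disease(data: RegionDataset, config: SimulationConfig) -> RegionDataset:
    """Fill the binary disease phenotype.

    Per-individual case probability is logistic(alpha + log_or_dis * g_c)
    with alpha solved so the dosage-averaged case probability equals
    ``prevalence``; case status is then an independent Bernoulli draw. This
    is a population draw, not case/control ascertainment, which keeps the
    downstream logistic scan correctly specified.
    """
    rng = _rng(config.seed, _STAGE_DIS)
    if config.causal_index_dis is not None and config.log_or_dis != 0.0:
        g = data.dosages[:, config.causal_index_dis].astype(float)
        alpha = _solve_intercept(g, config.log_or_dis, config.prevalence)
        prob = special.expit(alpha + config.log_or_dis * g)
    else:
        prob = np.full(config.n_individuals, config.prevalence)
    disease = (rng.random(config.n_individuals) < prob).astype(np.int8)
    return data.replace(disease=disease, truth=config)


def generate_dataset(config: SimulationConfig) -> RegionDataset:
    """Genotypes + expression + disease in one call."""
    data = generate_genotypes(config)
    data = generate_expression(data, config)
    return generate_disease(data, config)
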