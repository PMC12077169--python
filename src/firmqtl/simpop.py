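"""Seeded simulation of a clone-replicated breeding population.

The generator emulates the statistical structure of a strawberry breeding
study built around one major, incompletely dominant firmness locus:

* biallelic SNP genotypes at Hardy--Weinberg proportions,
* a major locus with additive effect ``a`` and dominance deviation ``d``
  (in kg-force) on an additive polygenic background,
* clone-replicated phenotypes observed across locations x years x blocks x
  harvests with genotype-by-year and residual variation,
* ripe-fruit transcript counts where one focal gene (the softening gene)
  is strongly expressed in wildtype homozygotes and silenced, >10-fold,
  in favorable-allele homozygotes,
* full-sib families segregating 1:2:1 at the major locus.

Dosage convention: genotypes are coded 0/1/2 as the count of the
*favorable* (firmness-increasing) allele, so the focal transcript is
*negatively* correlated with both dosage and phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "SimConfig",
    "GenotypeMatrix",
    "CountsMatrix",
    "TruthRecord",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_expression",
    "simulate_fullsib",
]


class ConfigurationError(ValueError):
    """Raised when a :class:`SimConfig` is internally inconsistent."""


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic population.

    Defaults mirror the discovery-study conditions: a major locus with
    a = 0.10 kg-force and d = 0.04 kg-force (|d/a| = 0.4, incomplete
    dominance) that explains half of a total genotypic variance of 0.010,
    clone replication over 2 locations x 2 years x 2 blocks x 3 harvests
    (24 observations/individual), variance components chosen so broad-sense
    clone-mean heritability is 0.50, and a focal transcript with a
    (2000, 1000, 160) CPM profile across favorable-allele dosage classes
    (a 12.5-fold wildtype/mutant homozygote contrast).
    """

    n_individuals: int = 200
    n_markers: int = 500
    maf_range: tuple[float, float] = (0.05, 0.5)
    major_locus_index: int = 250
    major_locus_maf: float = 0.5
    # major-locus effects, kg-force
    a: float = 0.10
    d: float = 0.04
    # variance components (kg-force^2); sigma2_G is the total genotypic
    # variance among clones, major locus included
    sigma2_G: float = 0.010
    sigma2_GY: float = 0.010
    sigma2_e: float = 0.12
    # nuisance design variances; irrelevant to clone-mean heritability
    sigma2_Y: float = 0.002
    sigma2_LY: float = 0.001
    sigma2_LYB: float = 0.002
    location_effects: tuple[float, ...] = (0.0, 0.03)
    n_locations: int = 2
    n_years: int = 2
    n_blocks: int = 2
    n_harvests: int = 3
    # expression
    n_genes: int = 2000
    focal_gene_index: int = 1000
    cpm_by_genotype: tuple[float, float, float] = (2000.0, 1000.0, 160.0)
    nb_dispersion: float = 0.1
    lib_size_range: tuple[float, float] = (5e5, 2e6)
    baseline_cpm_range: tuple[float, float] = (1.0, 1000.0)
    grand_mean: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(
                f"maf_range must lie within (0, 0.5], got {self.maf_range}"
            )
        if self.a < 0:
            raise ConfigurationError("additive effect a must be >= 0")
        for name in ("sigma2_G", "sigma2_GY", "sigma2_e", "sigma2_Y",
                     "sigma2_LY", "sigma2_LYB"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0 <= self.major_locus_index < self.n_markers:
            raise ConfigurationError("major_locus_index out of range")
        if not 0 <= self.focal_gene_index < self.n_genes:
            raise ConfigurationError("focal_gene_index out of range")
        c0, c1, c2 = self.cpm_by_genotype
        if not (c0 > c1 > c2 >= 0):
            raise ConfigurationError(
                "cpm_by_genotype must be strictly decreasing from -/- to +/+"
            )
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be > 0")
        if self.n_individuals < 2 or self.n_markers < 1:
            raise ConfigurationError("need >= 2 individuals and >= 1 marker")
        if len(self.location_effects) < self.n_locations:
            raise ConfigurationError(
                "need one fixed location effect per location"
            )


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic markers, favorable-allele dosage 0/1/2.

    ``dosages`` is float so missing calls can be carried as NaN.
    """

    dosages: np.ndarray
    individuals: list[str]
    marker_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray  # 1-based

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def allele_freqs(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0


@dataclass
class CountsMatrix:
    """Raw transcript counts (genes x samples) plus library sizes."""

    counts: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    lib_sizes: np.ndarray
    gene_chrom: np.ndarray | None = None
    gene_midpoint: np.ndarray | None = None

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


@dataclass
class TruthRecord:
    """Ground truth retained from a simulation for recovery tests."""

    a: float
    d: float
    allele_freqs: np.ndarray
    breeding_values: np.ndarray  # total genotypic value per individual
    polygenic_values: np.ndarray
    sigma2_G_total: float
    H2: float
    h2: float
    major_locus_index: int
    focal_gene_index: int


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # independent substream per operation so call order never matters
    return np.random.default_rng([config.seed, stream])


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Draw a dosage matrix at Hardy--Weinberg proportions.

    Marker allele frequencies are uniform over ``maf_range`` except the
    major locus, which is pinned at ``major_locus_maf``.  All markers sit
    on one synthetic chromosome ("chr6A") at evenly spaced 1-based
    positions.
    """
    rng = _rng(config, 0)
    n, m = config.n_individuals, config.n_markers
    lo, hi = config.maf_range
    freqs = rng.uniform(lo, hi, size=m)
    freqs[config.major_locus_index] = config.major_locus_maf
    dosages = rng.binomial(2, freqs, size=(n, m)).astype(float)
    individuals = [f"ind{i:04d}" for i in range(n)]
    marker_ids = [f"mk{j:05d}" for j in range(m)]
    chrom = np.array(["chr6A"] * m)
    pos = np.arange(1, m + 1, dtype=int) * 4000
    return GenotypeMatrix(dosages, individuals, marker_ids, chrom, pos)


def _major_locus_values(config: SimConfig, x: np.ndarray) -> np.ndarray:
    return config.a * (x - 1.0) + config.d * (x == 1.0)


def simulate_phenotypes(
    config: SimConfig, G: GenotypeMatrix
) -> tuple[pd.DataFrame, TruthRecord]:
    """Generate replicated phenotype observations and the realized truth.

    The genotypic value of individual *i* is the major-locus term
    ``a*(x_i - 1) + d*[x_i == 1]`` plus an additive polygenic background
    realized through the remaining markers with i.i.d. Gaussian effects.
    The background is rescaled post hoc so the realized total genotypic
    variance among clones equals ``sigma2_G`` exactly (when
    ``sigma2_G == 0`` the major locus is the only genetic term).
    Observations follow a location/year/block/harvest design with fixed
    location effects and independent Gaussian year, location-by-year,
    genotype-by-year, block-within-location-year, and residual effects.
    """
    rng = _rng(config, 1)
    n = G.n_individuals
    x = G.dosages[:, config.major_locus_index]
    major = _major_locus_values(config, x)

    if (config.sigma2_G == 0 and config.sigma2_GY == 0
            and config.sigma2_e == 0 and config.a == 0 and config.d == 0):
        raise ConfigurationError("total phenotypic variance is zero")

    # additive polygenic background on the non-causal markers
    bg_idx = np.array(
        [j for j in range(G.n_markers) if j != config.major_locus_index]
    )
    if bg_idx.size > 0:
        Z = G.dosages[:, bg_idx]
        Z = Z - Z.mean(axis=0)
        beta = rng.normal(size=bg_idx.size) / np.sqrt(bg_idx.size)
        poly_raw = Z @ beta
    else:
        poly_raw = np.zeros(n)

    var_major = float(np.var(major, ddof=1))
    if config.sigma2_G > 0:
        # solve var(major + c*poly) == sigma2_G for c >= 0
        vp = float(np.var(poly_raw, ddof=1))
        cov = float(np.cov(major, poly_raw, ddof=1)[0, 1]) if vp > 0 else 0.0
        cc = var_major - config.sigma2_G
        if vp == 0:
            if abs(cc) > 1e-12:
                raise ConfigurationError(
                    "no polygenic markers available to reach sigma2_G"
                )
            c = 0.0
        else:
            disc = cov * cov - vp * cc
            if disc < 0 or (-cov + np.sqrt(disc)) < 0:
                raise ConfigurationError(
                    f"major-locus variance {var_major:.4g} exceeds "
                    f"sigma2_G={config.sigma2_G:.4g}; no valid background scale"
                )
            c = (-cov + np.sqrt(disc)) / vp
        poly = c * poly_raw
    else:
        poly = np.zeros(n)
    g = major + poly
    sigma2_G_total = float(np.var(g, ddof=1)) if n > 1 else 0.0

    n_loc, n_yr = config.n_locations, config.n_years
    n_blk, n_hv = config.n_blocks, config.n_harvests

    year_eff = rng.normal(0, np.sqrt(config.sigma2_Y), size=n_yr)
    ly_eff = rng.normal(0, np.sqrt(config.sigma2_LY), size=(n_loc, n_yr))
    gy_eff = rng.normal(0, np.sqrt(config.sigma2_GY), size=(n, n_yr))
    lyb_eff = rng.normal(
        0, np.sqrt(config.sigma2_LYB), size=(n_loc, n_yr, n_blk)
    )

    rows: dict[str, list] = {
        "individual": [], "location": [], "year": [],
        "block": [], "harvest": [],
    }
    values = []
    inds = G.individuals
    for l in range(n_loc):
        for y in range(n_yr):
            for b in range(n_blk):
                base = (config.grand_mean + config.location_effects[l]
                        + year_eff[y] + ly_eff[l, y] + lyb_eff[l, y, b])
                for h in range(n_hv):
                    e = rng.normal(0, np.sqrt(config.sigma2_e), size=n)
                    vals = base + g + gy_eff[:, y] + e
                    rows["individual"].extend(inds)
                    rows["location"].extend([f"L{l + 1}"] * n)
                    rows["year"].extend([f"Y{y + 1}"] * n)
                    rows["block"].extend([f"B{b + 1}"] * n)
                    rows["harvest"].extend([f"H{h + 1}"] * n)
                    values.append(vals)
    pheno = pd.DataFrame(rows)
    pheno["value"] = np.concatenate(values)

    # truth heritabilities on a clone-mean basis
    r_reps = n_loc * n_blk * n_hv  # replications per genotype per year
    denom = (sigma2_G_total + config.sigma2_GY / n_yr
             + config.sigma2_e / (r_reps * n_yr))
    H2 = sigma2_G_total / denom if denom > 0 else float("nan")
    p_major = float(np.mean(x) / 2.0)
    q_major = 1.0 - p_major
    # dominance variance contributed by the major locus (only non-additive term)
    sigma2_D = (2.0 * p_major * q_major * config.d) ** 2
    sigma2_A = max(sigma2_G_total - sigma2_D, 0.0)
    h2 = sigma2_A / denom if denom > 0 else float("nan")

    truth = TruthRecord(
        a=config.a, d=config.d,
        allele_freqs=G.allele_freqs(),
        breeding_values=g,
        polygenic_values=poly,
        sigma2_G_total=sigma2_G_total,
        H2=H2, h2=h2,
        major_locus_index=config.major_locus_index,
        focal_gene_index=config.focal_gene_index,
    )
    return pheno, truth


def simulate_expression(config: SimConfig, G: GenotypeMatrix) -> CountsMatrix:
    """Draw negative-binomial ripe-fruit transcript counts, one sample per
    individual (the study pools fruit within clone).

    The focal gene's expected CPM follows ``cpm_by_genotype`` indexed by
    the individual's major-locus dosage; every other gene has a
    genotype-independent baseline CPM drawn log-uniformly.  Counts have
    mean ``CPM * libsize / 1e6`` and NB variance ``mu + phi * mu^2``.
    """
    rng = _rng(config, 2)
    n, g_n = G.n_individuals, config.n_genes
    lo, hi = config.lib_size_range
    lib = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    blo, bhi = config.baseline_cpm_range
    base_cpm = np.exp(rng.uniform(np.log(blo), np.log(bhi), size=g_n))

    cpm = np.tile(base_cpm[:, None], (1, n))
    x = G.dosages[:, config.major_locus_index].astype(int)
    cpm[config.focal_gene_index, :] = np.asarray(config.cpm_by_genotype)[x]

    mu = cpm * lib[None, :] / 1e6
    size = 1.0 / config.nb_dispersion
    p = size / (size + mu)
    counts = rng.negative_binomial(size, p)

    gene_ids = [f"gene{j:05d}" for j in range(g_n)]
    sample_ids = list(G.individuals)
    # genes share the synthetic chromosome; the focal gene sits 1 kb from
    # the major locus so a cis window always contains it
    span = int(G.pos.max()) + 4000
    midpoints = np.linspace(2000, span, g_n).astype(int)
    midpoints[config.focal_gene_index] = (
        int(G.pos[config.major_locus_index]) + 1000
    )
    return CountsMatrix(
        counts=counts.astype(np.int64),
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        lib_sizes=lib,
        gene_chrom=np.array(["chr6A"] * g_n),
        gene_midpoint=midpoints,
    )


def simulate_fullsib(
    parent1_genotype: int,
    parent2_genotype: int,
    n_progeny: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Mendelian single-locus transmission from two parents.

    A 1 x 1 (het x het) cross segregates 1:2:1 in expectation.
    """
    for g in (parent1_genotype, parent2_genotype):
        if g not in (0, 1, 2):
            raise ValueError(f"parent dosage must be 0, 1 or 2, got {g}")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))

    def gametes(g: int) -> np.ndarray:
        if g == 0:
            return np.zeros(n_progeny, dtype=int)
        if g == 2:
            return np.ones(n_progeny, dtype=int)
        return rng.integers(0, 2, size=n_progeny)

    return gametes(parent1_genotype) + gametes(parent2_genotype)
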