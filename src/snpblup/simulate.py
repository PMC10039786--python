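"""LD-structured genotype and phenotype simulation.

Genotypes: per chromosome, each individual carries two haplotypes generated
by a first-order Markov chain along SNPs.  Per-SNP allele frequencies follow
a reflected random walk on the logit scale so neighboring SNPs have similar
frequencies (as under real LD), and the chain's transition probabilities are
chosen so each SNP keeps exactly its nominal marginal frequency while
adjacent haplotype alleles have Pearson correlation ``ld_rho`` (clipped at
the Frechet bound, which the slowly varying frequencies make rare).  Setting
ld_rho near 0.97 emulates the strong LD of livestock SNP-chip data; 0 gives
independent SNPs.

Phenotypes: a random subset of SNPs act as QTLs with effects drawn from the
standard normal on standardized genotypes (so rarer QTLs have larger
per-allele effects; a flag switches to per-allele effects).  Residual
variance is scaled from the realized sample variance of the true breeding
values, so the target heritability is hit exactly in expectation for each
dataset.

This generator emulates the study design of large-scale breeding
simulations at desk scale; it has no pedigree structure, selection or
genotyping error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

from .plink import GenotypeMatrix, StandardizedGenotypes, standardize
from .reml import MixedModelData


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic data generator.

    Defaults are the desk-scale analogue of a large livestock simulation:
    2,000 individuals, 5,000 SNPs on 10 chromosomes, strong LD
    (ld_rho = 0.965), 500 QTLs with standard-normal effects and a target
    heritability of 0.3.
    """

    n_individuals: int = 2000
    n_snps: int = 5000
    n_chromosomes: int = 10
    ld_rho: float = 0.965
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_qtl: int = 500
    h2_target: float = 0.3
    effect_scale: str = "standardized"  # or "per_allele"
    freq_walk_sd: float = 0.03  # logit-scale step of the allele-frequency walk
    seed: int = 1

    def __post_init__(self) -> None:
        low, high = self.maf_range
        if not (0.01 <= low < high <= 0.5):
            raise ValueError("maf_range must satisfy 0.01 <= low < high <= 0.5")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must be in [0, 1)")
        if not (0.0 < self.h2_target < 1.0):
            raise ValueError("h2_target must be in (0, 1)")
        if self.n_qtl > self.n_snps:
            raise ValueError("n_qtl cannot exceed n_snps")
        if self.effect_scale not in ("standardized", "per_allele"):
            raise ValueError(f"unknown effect_scale {self.effect_scale!r}")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset."""

    qtl_indices: np.ndarray
    qtl_effects: np.ndarray
    true_breeding_values: np.ndarray
    realized_h2: float


def _chromosome_sizes(m: int, n_chrom: int) -> list[int]:
    base = m // n_chrom
    sizes = [base + (1 if i < m % n_chrom else 0) for i in range(n_chrom)]
    return [s for s in sizes if s > 0]


def _frequency_path(L: int, cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Reflected logit-scale random walk inside maf_range."""
    low, high = logit(cfg.maf_range[0]), logit(cfg.maf_range[1])
    x = np.empty(L)
    x[0] = rng.uniform(low, high)
    steps = rng.normal(0.0, cfg.freq_walk_sd, size=L - 1)
    for j in range(1, L):
        v = x[j - 1] + steps[j - 1]
        # reflect into [low, high]
        while v < low or v > high:
            v = 2 * low - v if v < low else 2 * high - v
        x[j] = v
    return expit(x)


def _haplotypes(freq: np.ndarray, rho: float, n_hap: int, rng: np.random.Generator) -> np.ndarray:
    """Markov haplotype chain with exact marginals and adjacent correlation rho.

    Transitions P(1|1) = f' + rho*sqrt(f'(1-f')(1-f)/f) and
    P(1|0) = f' - rho*sqrt(f'(1-f') f/(1-f)) give Corr(a_j, a_{j+1}) = rho
    exactly whenever both probabilities are inside [0, 1]; clipping (at the
    binary Frechet bound) only occurs for large frequency jumps.
    """
    L = freq.size
    H = np.empty((n_hap, L), dtype=np.int8)
    H[:, 0] = rng.random(n_hap) < freq[0]
    u = rng.random((n_hap, L - 1))
    for j in range(1, L):
        f, fp = freq[j - 1], freq[j]
        odds = np.sqrt(fp * (1.0 - fp))
        p11 = min(1.0, fp + rho * odds * np.sqrt((1.0 - f) / f))
        p10 = max(0.0, fp - rho * odds * np.sqrt(f / (1.0 - f)))
        prev = H[:, j - 1] == 1
        H[:, j] = u[:, j - 1] < np.where(prev, p11, p10)
    return H


def sim_genotypes(cfg: SimulationConfig) -> GenotypeMatrix:
    """Simulate LD-structured biallelic dosages sorted by (chromosome, position)."""
    rng = np.random.default_rng([cfg.seed, 0])
    n = cfg.n_individuals
    blocks = []
    chroms = []
    positions = []
    ids = []
    for c, L in enumerate(_chromosome_sizes(cfg.n_snps, cfg.n_chromosomes), start=1):
        freq = _frequency_path(L, cfg, rng)
        H = _haplotypes(freq, cfg.ld_rho, 2 * n, rng)
        blocks.append(H[0::2] + H[1::2])
        chroms.extend([str(c)] * L)
        positions.extend(range(1000, 1000 * (L + 1), 1000))
        ids.extend(f"chr{c}_snp{j + 1}" for j in range(L))
    dosages = np.concatenate(blocks, axis=1).astype(np.int8)
    m = dosages.shape[1]
    return GenotypeMatrix(
        dosages=dosages,
        snp_ids=np.array(ids, dtype=object),
        chrom=np.array(chroms, dtype=object),
        pos=np.array(positions, dtype=np.int64),
        a1=np.array(["A"] * m, dtype=object),
        a2=np.array(["C"] * m, dtype=object),
        sample_ids=np.array([f"ind{i + 1:06d}" for i in range(n)], dtype=object),
    )


def sim_phenotypes(
    g: GenotypeMatrix, cfg: SimulationConfig, sg: StandardizedGenotypes | None = None
) -> tuple[MixedModelData, SimulationTruth]:
    """Add QTL effects and residuals at the target heritability.

    QTLs are a uniform random subset of SNPs; their effects are standard
    normal on standardized genotypes ("standardized", the default) or on
    centered dosages ("per_allele", making each QTL's variance contribution
    proportional to 2p(1-p)).  Residual variance is
    var(tbv) (1 - h2) / h2 computed from the realized sample variance.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    qtl = np.sort(rng.choice(g.m, size=cfg.n_qtl, replace=False))
    effects = rng.standard_normal(cfg.n_qtl)
    if cfg.effect_scale == "standardized":
        if sg is None:
            sg = standardize(g)
        tbv = sg.Z[:, qtl] @ effects
    else:
        d = g.dosages[:, qtl].astype(np.float64)
        d[d < 0] = np.nan
        means = np.nanmean(d, axis=0)
        d = np.where(np.isnan(d), means, d)
        tbv = (d - means) @ effects
    var_tbv = tbv.var(ddof=1)
    if var_tbv <= 0:
        raise ValueError("true breeding values are constant; cannot scale residual variance")
    sigma2_e = var_tbv * (1.0 - cfg.h2_target) / cfg.h2_target
    e = rng.normal(0.0, np.sqrt(sigma2_e), size=g.n)
    y = tbv + e
    data = MixedModelData(y=y, X=np.ones((g.n, 1)), r=np.ones(g.n), sample_ids=g.sample_ids)
    truth = SimulationTruth(
        qtl_indices=qtl,
        qtl_effects=effects,
        true_breeding_values=tbv,
        realized_h2=float(var_tbv / y.var(ddof=1)),
    )
    return data, truth


def simulate_dataset(cfg: SimulationConfig) -> tuple[GenotypeMatrix, MixedModelData, SimulationTruth]:
    """Convenience wrapper: genotypes plus phenotypes in one call."""
    g = sim_genotypes(cfg)
    data, truth = sim_phenotypes(g, cfg)
    return g, data, truth
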