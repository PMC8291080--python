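"""Semi-synthetic GWAS data generator.

Emulates the generated-data design used to benchmark two-step GWAS methods: a
block of LD-correlated informative SNPs embedded in the middle of a long
LD-structured noise region, with binary phenotypes drawn from a logistic
function of a single causal SNP inside the informative block.

Genotypes come from a latent-Gaussian copula: per subject, two haplotype
latent vectors are drawn from an AR(1) Gaussian process with per-block
correlation ``rho``; coordinate ``j`` carries the minor allele iff its latent
value falls below the ``Phi^{-1}(maf_j)`` cutpoint, and the genotype is the
sum of the two haplotype alleles. Marginally each SNP is in Hardy-Weinberg
proportions at its MAF, while adjacent-SNP LD decays geometrically with
distance inside a block and is zero across blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .data import GenotypeMatrix, PhenotypeVector, SnpMeta


@dataclass
class SimulationConfig:
    """Study-design parameters of one simulated dataset.

    Defaults reproduce the benchmark conditions: 300 subjects, 20 informative
    SNPs centered in 10 000 noise SNPs (total d = 10 020, informative block at
    1-based positions 5001..5020, causal SNP at 5010) and effect size
    ``gamma = 6``.
    """

    n_subjects: int = 300
    n_noise_snps: int = 10_000
    n_informative_snps: int = 20
    causal_offset: int = 10          # 1-based offset of the causal SNP in the block
    gamma: float = 6.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho_informative: float = 0.95
    ld_rho_noise: float = 0.9
    block_length_noise: int = 35     # mean geometric LD-block length in the noise region
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        for rho in (self.ld_rho_informative, self.ld_rho_noise):
            if not 0 <= rho < 1:
                raise ValueError("ld_rho must be in [0, 1)")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.n_informative_snps > 0 and not (
            1 <= self.causal_offset <= self.n_informative_snps
        ):
            raise ValueError("causal_offset must lie inside the informative block")


@dataclass
class SimulatedDataset:
    """A generated dataset together with its ground truth."""

    genotypes: GenotypeMatrix
    phenotypes: PhenotypeVector | None
    informative_indices: np.ndarray  # 0-based column indices of the informative block
    causal_index: int                # 0-based column index of the causal SNP
    config: SimulationConfig = field(repr=False, default=None)

    @property
    def truth_mask(self) -> np.ndarray:
        mask = np.zeros(self.genotypes.n_snps, dtype=bool)
        mask[self.informative_indices] = True
        return mask


def simulate_genotype_block(
    n: int,
    m: int,
    mafs: np.ndarray,
    rho: float,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Draw an ``n x m`` genotype block from the AR(1) latent-Gaussian copula."""
    if m < 1:
        raise ValueError("block must contain at least one SNP")
    mafs = np.asarray(mafs, dtype=float)
    if mafs.shape != (m,):
        raise ValueError("mafs must have length m")
    if ((mafs <= 0) | (mafs > 0.5)).any():
        raise ValueError("each maf must lie in (0, 0.5]")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    cut = norm.ppf(mafs)
    genotype = np.zeros((n, m), dtype=np.int8)
    scale = np.sqrt(1.0 - rho * rho)
    for _hap in range(2):  # two independent haplotypes per subject
        eps = rng.standard_normal((n, m))
        z = np.empty((n, m))
        z[:, 0] = eps[:, 0]
        for j in range(1, m):
            z[:, j] = rho * z[:, j - 1] + scale * eps[:, j]
        genotype += (z < cut[None, :]).astype(np.int8)
    return genotype


def _noise_block_lengths(total: int, mean_length: int, rng: np.random.Generator):
    """Geometric block lengths (mean ``mean_length``) covering ``total`` SNPs."""
    lengths = []
    left = total
    while left > 0:
        ln = min(int(rng.geometric(1.0 / mean_length)), left)
        lengths.append(ln)
        left -= ln
    return lengths


def assemble_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Build the genotype layout (phenotypes unset).

    The informative block (correlation ``ld_rho_informative``) is placed in
    the middle of the noise region, which is a concatenation of mutually
    independent AR(1) blocks with geometric lengths, so that LD is confined
    within blocks and the informative SNPs are uncorrelated with the noise.
    """
    rng = np.random.default_rng(cfg.seed)
    n, m_inf = cfg.n_subjects, cfg.n_informative_snps
    half = cfg.n_noise_snps // 2
    d = cfg.n_noise_snps + m_inf

    def noise_region(width: int) -> np.ndarray:
        parts = []
        for ln in _noise_block_lengths(width, cfg.block_length_noise, rng):
            mafs = rng.uniform(*cfg.maf_range, size=ln)
            parts.append(simulate_genotype_block(n, ln, mafs, cfg.ld_rho_noise, rng))
        return np.concatenate(parts, axis=1) if parts else np.zeros((n, 0), dtype=np.int8)

    left = noise_region(half)
    right = noise_region(cfg.n_noise_snps - half)
    if m_inf > 0:
        mafs = rng.uniform(*cfg.maf_range, size=m_inf)
        inf = simulate_genotype_block(n, m_inf, mafs, cfg.ld_rho_informative, rng)
        counts = np.concatenate([left, inf, right], axis=1)
        informative = np.arange(half, half + m_inf)
        causal = half + cfg.causal_offset - 1
    else:
        counts = np.concatenate([left, right], axis=1)
        informative = np.arange(0)
        causal = -1
    snps = [SnpMeta(f"snp_{j + 1}", "1", j + 1) for j in range(d)]
    return SimulatedDataset(GenotypeMatrix(counts, snps), None, informative, causal, cfg)


def phenotype_probability(
    x_causal: np.ndarray | int, median_count: float, gamma: float
) -> np.ndarray | float:
    """P(case | causal genotype) = 1 / (1 + exp(-gamma * (x - median)))."""
    return 1.0 / (1.0 + np.exp(-gamma * (np.asarray(x_causal, dtype=float) - median_count)))


def draw_phenotypes(
    ds: SimulatedDataset, gamma: float | None = None, seed: int | None = None
) -> PhenotypeVector:
    """Independent Bernoulli labels from the causal-SNP logistic model.

    The median is the sample median of the realized causal column. Degenerate
    single-class draws are redrawn with an incremented seed until both classes
    are present.
    """
    if ds.causal_index < 0:
        raise ValueError("dataset has no causal SNP (pure-null configuration)")
    gamma = ds.config.gamma if gamma is None else gamma
    seed = ds.config.seed if seed is None else seed
    x = ds.genotypes.counts[:, ds.causal_index].astype(float)
    prob = phenotype_probability(x, float(np.median(x)), gamma)
    for attempt in range(1000):
        rng = np.random.default_rng(seed + attempt)
        labels = (rng.random(x.shape[0]) < prob).astype(np.int8)
        if labels.any() and not labels.all():
            return PhenotypeVector(labels)
    raise RuntimeError("could not draw a two-class phenotype vector")


def simulate_dataset(cfg: SimulationConfig | None = None, **kwargs) -> SimulatedDataset:
    """Genotypes plus phenotypes in one call; ``kwargs`` override config fields."""
    if cfg is None:
        cfg = SimulationConfig(**kwargs)
    ds = assemble_dataset(cfg)
    ds.phenotypes = draw_phenotypes(ds)
    return ds
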