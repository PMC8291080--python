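"""Westfall-Young-style permutation calibration of the significance threshold.

The phenotype labels are randomly permuted B times; the complete
selection-then-test pipeline is re-run on each permutation (classifier
retraining included) and the smallest masked p-value is recorded. The
empirical lower alpha-quantile of these B minima is the family-wise
threshold t*: rejecting p < t* bounds the FWER by alpha even under the
arbitrary dependence that linkage disequilibrium induces between tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .data import GenotypeMatrix, PhenotypeVector


@dataclass
class CalibrationConfig:
    """Number of permutations B, FWER level alpha, and the master seed."""

    B: int = 100
    alpha_fwer: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not 0 < self.alpha_fwer < 1:
            raise ValueError("alpha must be in (0, 1)")


def permute_phenotypes(y: PhenotypeVector, seed: int) -> PhenotypeVector:
    """Uniform random permutation of the labels (multiset preserved)."""
    rng = np.random.default_rng(seed)
    return PhenotypeVector(y.labels[rng.permutation(y.n)])


def threshold_from_minima(minima: np.ndarray, alpha: float) -> float:
    """t* = the floor(alpha*B)-th smallest null minimum; 0 if that index is < 1.

    With t* = 0 and the strict rejection rule p < t*, no discovery is
    possible — the degenerate but valid answer when B*alpha < 1.
    """
    minima = np.sort(np.asarray(minima, dtype=float))
    m = int(np.floor(alpha * minima.shape[0]))
    if m < 1:
        warnings.warn(
            f"B*alpha = {alpha * minima.shape[0]:g} < 1: calibrated threshold is 0 "
            "and nothing can be rejected; increase B",
            stacklevel=2,
        )
        return 0.0
    return float(minima[m - 1])


def null_min_pvalues(
    g: GenotypeMatrix,
    y: PhenotypeVector,
    pipeline: Callable[[GenotypeMatrix, PhenotypeVector, int], np.ndarray],
    cfg: CalibrationConfig,
) -> np.ndarray:
    """Smallest masked p-value of the pipeline under each of B permutations.

    ``pipeline(g, y_permuted, seed)`` must return the full masked p-value
    vector; it is re-run from scratch with a permutation-specific seed.
    """
    minima = np.empty(cfg.B)
    for b in range(cfg.B):
        perm_seed = cfg.seed * 100_003 + b  # distinct, reproducible per permutation
        y_perm = permute_phenotypes(y, perm_seed)
        pvalues = pipeline(g, y_perm, perm_seed)
        minima[b] = float(np.min(pvalues))
    return minima


def calibrate_threshold(
    g: GenotypeMatrix,
    y: PhenotypeVector,
    pipeline: Callable[[GenotypeMatrix, PhenotypeVector, int], np.ndarray],
    cfg: CalibrationConfig | None = None,
) -> tuple[float, np.ndarray]:
    """Return (t*, null minima) for the wrapped pipeline."""
    cfg = cfg or CalibrationConfig()
    minima = null_min_pvalues(g, y, pipeline, cfg)
    return threshold_from_minima(minima, cfg.alpha_fwer), minima


def estimate_fwer(
    false_positive_flags: np.ndarray, confidence: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Empirical FWER = P(>= 1 false discovery) with a binomial CI.

    ``false_positive_flags`` holds one boolean per replication: whether any
    significant SNP fell outside the ground-truth informative set. The CI is
    Clopper-Pearson.
    """
    from scipy.stats import beta

    flags = np.asarray(false_positive_flags, dtype=bool)
    n = flags.shape[0]
    k = int(flags.sum())
    rate = k / n
    lo = 0.0 if k == 0 else float(beta.ppf((1 - confidence) / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(beta.isf((1 - confidence) / 2, k + 1, n - k))
    return rate, (lo, hi)
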