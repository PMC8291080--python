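"""Chi-square genotype-phenotype association testing and helpers.

Each SNP is tested for independence of genotype (0/1/2 minor alleles) and
phenotype (control/case) with the Pearson chi-square statistic
``sum (O - E)^2 / E`` referred to a chi-square distribution with two degrees
of freedom. Raw p-value thresholding (RPVT) declares SNPs with ``p <= t*``
significant; two-step methods test only a selected subset and set all other
p-values to one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2 as chi2_dist
from scipy.stats import fisher_exact as _scipy_fisher

from .data import GenotypeMatrix, PhenotypeVector

#: default weak-association threshold used in GWAS reporting
DEFAULT_THRESHOLD = 1e-5


@dataclass
class AssociationResult:
    """Per-SNP p-values with the selection and significance masks."""

    pvalues: np.ndarray
    threshold: float
    selected: np.ndarray
    significant: np.ndarray
    method: str = ""

    def __post_init__(self) -> None:
        self.pvalues = np.asarray(self.pvalues, dtype=float)
        self.selected = np.asarray(self.selected, dtype=bool)
        self.significant = np.asarray(self.significant, dtype=bool)

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())


def genotype_contingency(g_column: np.ndarray, y: PhenotypeVector) -> np.ndarray:
    """3x2 table of genotype level (rows 0,1,2) by phenotype (columns control, case)."""
    g_column = np.asarray(g_column)
    if g_column.shape[0] != y.n:
        raise ValueError("genotype column and phenotype lengths differ")
    table = np.zeros((3, 2), dtype=np.int64)
    for pheno in (0, 1):
        table[:, pheno] = np.bincount(g_column[y.labels == pheno], minlength=3)[:3]
    return table


def chi2_pvalue(table: np.ndarray) -> float:
    """Upper-tail chi-square p-value at 2 df; cells with E = 0 contribute 0."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    if n <= 0:
        raise ValueError("empty contingency table")
    col = table.sum(axis=0)
    if (col == 0).any():
        raise ValueError("both phenotype classes must be present")
    expected = np.outer(table.sum(axis=1), col) / n
    with np.errstate(invalid="ignore", divide="ignore"):
        cells = np.where(expected > 0, (table - expected) ** 2 / expected, 0.0)
    return float(chi2_dist.sf(cells.sum(), df=2))


def chi2_pvalues_all(g: GenotypeMatrix, y: PhenotypeVector) -> np.ndarray:
    """Vectorized per-SNP chi-square p-values (2 df) over all columns."""
    if not y.both_classes_present():
        raise ValueError("both phenotype classes must be present")
    counts = g.counts
    n, d = counts.shape
    # observed genotype-level counts per phenotype, shape (3, 2, d)
    obs = np.empty((3, 2, d), dtype=np.float64)
    for pheno in (0, 1):
        sub = counts[y.labels == pheno]
        for level in (0, 1, 2):
            obs[level, pheno] = (sub == level).sum(axis=0)
    row = obs.sum(axis=1, keepdims=True)          # genotype margins (3, 1, d)
    col = obs.sum(axis=0, keepdims=True)          # phenotype margins (1, 2, d)
    expected = row * col / n
    with np.errstate(invalid="ignore", divide="ignore"):
        cells = np.where(expected > 0, (obs - expected) ** 2 / expected, 0.0)
    return chi2_dist.sf(cells.sum(axis=(0, 1)), df=2)


def bonferroni_threshold(alpha: float, d: int) -> float:
    """Family-wise threshold ``alpha / d``."""
    if d <= 0:
        raise ValueError("d must be a positive number of tests")
    return alpha / d


def mask_pvalues(pvalues: np.ndarray, selected: np.ndarray) -> np.ndarray:
    """Copy p-values on the selected set and set all others to one."""
    pvalues = np.asarray(pvalues, dtype=float)
    selected = np.asarray(selected, dtype=bool)
    if pvalues.shape != selected.shape:
        raise ValueError("pvalues and selection mask must be aligned")
    return np.where(selected, pvalues, 1.0)


def significance_mask(
    pvalues: np.ndarray, threshold: float, calibrated: bool = False
) -> np.ndarray:
    """``p <= t*`` for fixed thresholds, strict ``p < t*`` for calibrated ones.

    The strict form prevents anti-conservativeness when the calibrated
    threshold ties with null minima (t* is itself an order statistic of
    permutation minima).
    """
    pvalues = np.asarray(pvalues, dtype=float)
    return pvalues < threshold if calibrated else pvalues <= threshold


def rpvt(
    g: GenotypeMatrix,
    y: PhenotypeVector,
    t_star: float = DEFAULT_THRESHOLD,
    calibrated: bool = False,
) -> AssociationResult:
    """Raw p-value thresholding: test every SNP, threshold at ``t_star``."""
    pvalues = chi2_pvalues_all(g, y)
    selected = np.ones(g.n_snps, dtype=bool)
    return AssociationResult(
        pvalues, t_star, selected,
        significance_mask(pvalues, t_star, calibrated), method="rpvt",
    )


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value of the table ((a, b), (c, d)).

    Two-sidedness by the hypergeometric-mass convention: sum the
    probabilities of all tables (with the observed margins) whose probability
    does not exceed that of the observed table. A zero margin gives p = 1.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("cell counts must be non-negative integers")
    table = np.array([[a, b], [c, d]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 1.0
    return float(_scipy_fisher(table, alternative="two-sided")[1])
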