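"""COMBI baseline: linear soft-margin SVM scoring plus the shared
filter/select/test path, and raw-score ranking baselines.

The SVM solves ``argmin_w ||w||_2^2 + C * sum_i max(0, 1 - y_i w^T x_i)`` on
one-hot genotype features (labels recoded to -1/+1). The weight vector is
pooled per SNP (Euclidean norm of each weight triplet), smoothed with the
same moving-average filter as the relevance scores, and the top-k SNPs go
into masked chi-square testing — identical code path to DeepCOMBI, so the
scoring method is the only difference between the two.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import LinearSVC

from .association import (
    AssociationResult,
    DEFAULT_THRESHOLD,
    chi2_pvalues_all,
    mask_pvalues,
    significance_mask,
)
from .data import (
    GenotypeMatrix,
    PhenotypeVector,
    encode_one_hot,
    standardize,
    stratified_split,
)
from .lrp import SelectionConfig, moving_average_filter, select_top_k


@dataclass
class SvmConfig:
    """Hinge-loss trade-off ``C`` (as written in the primal above) and the
    shared selection parameters."""

    C: float = 1.0
    max_iter: int = 10_000
    tol: float = 1e-5
    seed: int = 0
    selection: SelectionConfig = None

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.selection is None:
            self.selection = SelectionConfig()


def train_linear_svm(
    x_features: np.ndarray, y, cfg: SvmConfig | None = None
) -> tuple[np.ndarray, float]:
    """Return (weight vector, intercept) minimizing the soft-margin primal.

    The solver is liblinear's dual hinge formulation; its objective
    ``0.5 ||w||^2 + C' sum hinge`` matches the primal above with C' = C/2.
    The intercept enters the decision function but not the norm penalty.
    """
    cfg = cfg or SvmConfig()
    labels = y.labels if isinstance(y, PhenotypeVector) else np.asarray(y)
    if not ((labels == 0).any() and (labels == 1).any()):
        raise ValueError("both classes must be present")
    clf = LinearSVC(
        C=cfg.C / 2.0,
        loss="hinge",
        max_iter=cfg.max_iter,
        tol=cfg.tol,
        random_state=cfg.seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            clf.fit(x_features, labels)
        except ConvergenceWarning:
            warnings.warn(
                f"linear SVM did not converge within {cfg.max_iter} iterations",
                stacklevel=2,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                clf.fit(x_features, labels)
    return clf.coef_.ravel().astype(float), float(clf.intercept_[0])


def svm_primal_objective(
    w: np.ndarray, intercept: float, x: np.ndarray, y_pm: np.ndarray, C: float
) -> float:
    """``||w||^2 + C sum hinge`` at (w, b); used for solver cross-checks."""
    margins = y_pm * (x @ w + intercept)
    return float(w @ w + C * np.maximum(0.0, 1.0 - margins).sum())


def svm_snp_scores(
    w: np.ndarray, d: int, selection: SelectionConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP raw scores (triplet Euclidean norms) and their filtered form."""
    w = np.asarray(w, dtype=float)
    if w.shape[0] != 3 * d:
        raise ValueError(f"weight vector length {w.shape[0]} != 3*d = {3 * d}")
    selection = selection or SelectionConfig()
    raw = np.sqrt((w.reshape(d, 3) ** 2).sum(axis=1))
    return raw, moving_average_filter(raw, selection.l, selection.p)


@dataclass
class CombiResult:
    association: AssociationResult
    scores: np.ndarray            # raw per-SNP scores
    scores_filtered: np.ndarray
    test_accuracy: float
    test_balanced_accuracy: float


def combi(
    g: GenotypeMatrix,
    y: PhenotypeVector,
    cfg: SvmConfig | None = None,
    t_star: float = DEFAULT_THRESHOLD,
    calibrated: bool = False,
    split_fraction: float = 0.8,
) -> CombiResult:
    """The two-step SVM baseline on one dataset (same split protocol as
    DeepCOMBI: train on the stratified 80%, report held-out accuracy, test
    all subjects)."""
    cfg = cfg or SvmConfig()
    onehot = encode_one_hot(g)
    split = stratified_split(y, split_fraction, seed=cfg.seed)
    x_train, stats = standardize(onehot.features[split.train_indices])
    w, intercept = train_linear_svm(x_train, y.labels[split.train_indices], cfg)

    x_test, _ = standardize(onehot.features[split.test_indices], stats)
    pred = (x_test @ w + intercept > 0).astype(int)
    y_test = y.labels[split.test_indices]
    acc = float((pred == y_test).mean())
    tpr = float((pred[y_test == 1] == 1).mean()) if (y_test == 1).any() else np.nan
    tnr = float((pred[y_test == 0] == 0).mean()) if (y_test == 0).any() else np.nan
    bal_acc = float(np.nanmean([tpr, tnr]))

    raw, filtered = svm_snp_scores(w, g.n_snps, cfg.selection)
    selected = select_top_k(filtered, cfg.selection.k)
    pvalues = mask_pvalues(chi2_pvalues_all(g, y), selected)
    assoc = AssociationResult(
        pvalues, t_star, selected,
        significance_mask(pvalues, t_star, calibrated) & selected,
        method="combi",
    )
    return CombiResult(assoc, raw, filtered, acc, bal_acc)


def raw_score_ranking(scores: np.ndarray) -> np.ndarray:
    """Turn descending raw scores into an ascending pseudo-p-value ranking.

    The returned statistic can be fed to the same curve machinery as
    p-values: smaller = more strongly associated. Monotone transform of the
    scores, so ROC/PR curves are invariant to score scaling.
    """
    scores = np.asarray(scores, dtype=float)
    return -scores
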