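"""Layer-wise relevance propagation and the DeepCOMBI pipeline.

After the classifier is trained, the winning output node's pre-softmax score
of each subject is redistributed backwards through the network with the
alpha-beta rule

    R_s = sum_t ( alpha * (a_s w_st)^+ / sum_s (a_s w_st)^+
                - beta  * (a_s w_st)^- / sum_s (a_s w_st)^- ) * R_t,

collapsed from the one-hot input columns to one score per SNP, averaged in
absolute value over subjects into a global relevance profile, smoothed with a
p-th-order moving average filter, and the k top-scoring SNPs are passed to
chi-square testing (all other p-values set to one).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn
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

_SUBJECT_CHUNK = 16  # bounds the n x S x T intermediate in lrp_backward


@dataclass
class LRPConfig:
    """alpha-beta rule parameters; alpha - beta = 1 preserves conservation."""

    alpha: float = 1.0
    beta: float = 0.0
    epsilon: float = 1e-9

    def __post_init__(self) -> None:
        if abs(self.alpha - self.beta - 1.0) > 1e-12:
            warnings.warn(
                f"alpha - beta = {self.alpha - self.beta:g} != 1: relevance "
                "conservation does not hold",
                stacklevel=2,
            )

    @classmethod
    def wtccc_profile(cls) -> "LRPConfig":
        return cls(alpha=2.0, beta=1.0)


@dataclass
class SelectionConfig:
    """Filter window ``l`` (odd), filter order ``p`` and top-``k`` selection."""

    k: int = 30
    l: int = 35
    p: float = 2.0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.l % 2 == 0 or self.l < 1:
            raise ValueError("window size l must be odd and >= 1")
        if self.p <= 0:
            raise ValueError("filter order p must be positive")

    @classmethod
    def wtccc_profile(cls) -> "SelectionConfig":
        return cls(k=200, l=21)


@dataclass
class GlobalRelevance:
    """Per-SNP relevance, raw (``r``) and filtered (``r_filtered``)."""

    r: np.ndarray
    r_filtered: np.ndarray
    selection: SelectionConfig = field(default=None, repr=False)


def _propagate_layer(
    activations: np.ndarray,
    weights: np.ndarray,
    relevance: np.ndarray,
    cfg: LRPConfig,
) -> np.ndarray:
    """One alpha-beta step for a batch of subjects (biases get no relevance)."""
    out = np.empty_like(activations, dtype=np.float64)
    a64 = activations.astype(np.float64, copy=False)
    w64 = weights.astype(np.float64, copy=False)
    for start in range(0, a64.shape[0], _SUBJECT_CHUNK):
        A = a64[start:start + _SUBJECT_CHUNK]
        R = relevance[start:start + _SUBJECT_CHUNK]
        Z = A[:, :, None] * w64[None, :, :]
        Zp = np.maximum(Z, 0.0)
        Zn = Z - Zp
        sp = Zp.sum(axis=1)
        sn = Zn.sum(axis=1)
        fp = np.where(sp != 0, cfg.alpha * R / (sp + cfg.epsilon), 0.0)
        fn = np.where(sn != 0, -cfg.beta * R / (sn - cfg.epsilon), 0.0)
        out[start:start + _SUBJECT_CHUNK] = np.einsum(
            "nst,nt->ns", Zp, fp
        ) + np.einsum("nst,nt->ns", Zn, fn)
    return out


def lrp_backward(
    model: nn.TrainedModel, x_features: np.ndarray, cfg: LRPConfig | None = None
) -> np.ndarray:
    """Input-layer relevances (n x 3d') for standardized features.

    The propagated quantity is each subject's winning pre-softmax score.
    """
    cfg = cfg or LRPConfig()
    acts = nn.forward(model.params, np.asarray(x_features, dtype=np.float32))
    logits = acts[-1]
    if not np.isfinite(logits).all():
        raise ValueError("non-finite activations in the forward pass")
    winner = logits.argmax(axis=1)
    relevance = np.zeros_like(logits, dtype=np.float64)
    relevance[np.arange(logits.shape[0]), winner] = logits[
        np.arange(logits.shape[0]), winner
    ]
    for q in (2, 1, 0):
        relevance = _propagate_layer(acts[q], model.params.weights[q], relevance, cfg)
    return relevance


def collapse_onehot(
    r0: np.ndarray, feature_mask: np.ndarray | None = None
) -> np.ndarray:
    """Average each one-hot triplet into one per-SNP score (divide by 3).

    If ``feature_mask`` is given, prefiltered SNPs are re-inserted with
    relevance exactly zero.
    """
    r0 = np.atleast_2d(np.asarray(r0, dtype=float))
    n, width = r0.shape
    if width % 3:
        raise ValueError("input relevance width must be a multiple of 3")
    rho = r0.reshape(n, width // 3, 3).sum(axis=2) / 3.0
    if feature_mask is not None:
        feature_mask = np.asarray(feature_mask, dtype=bool)
        full = np.zeros((n, feature_mask.shape[0]))
        full[:, feature_mask] = rho
        rho = full
    return rho


def global_relevance(
    rho: np.ndarray, selection: SelectionConfig | None = None
) -> GlobalRelevance:
    """Mean absolute per-subject relevance, then the moving-average filter."""
    rho = np.atleast_2d(np.asarray(rho, dtype=float))
    selection = selection or SelectionConfig()
    r = np.abs(rho).mean(axis=0)
    return GlobalRelevance(r, moving_average_filter(r, selection.l, selection.p), selection)


def moving_average_filter(r: np.ndarray, l: int, p: float) -> np.ndarray:
    """Truncated-window power-mean root: ``(sum_window r_h^p)^(1/p)``.

    Windows are centered with half-width (l-1)/2 and truncated at the
    boundaries (no padding, no renormalization).
    """
    if l % 2 == 0 or l < 1:
        raise ValueError("window size l must be odd and >= 1")
    r = np.asarray(r, dtype=float)
    if (r < 0).any():
        raise ValueError("relevance scores must be non-negative")
    half = (l - 1) // 2
    powed = r ** p
    csum = np.concatenate([[0.0], np.cumsum(powed)])
    d = r.shape[0]
    j = np.arange(d)
    lo = np.maximum(0, j - half)
    hi = np.minimum(d - 1, j + half)
    return (csum[hi + 1] - csum[lo]) ** (1.0 / p)


def select_top_k(r_filtered: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask of the k largest scores; ties broken by lowest index."""
    if k < 1:
        raise ValueError("k must be >= 1")
    r_filtered = np.asarray(r_filtered, dtype=float)
    k = min(k, r_filtered.shape[0])
    order = np.argsort(-r_filtered, kind="stable")
    mask = np.zeros(r_filtered.shape[0], dtype=bool)
    mask[order[:k]] = True
    return mask


@dataclass
class DeepCombiResult:
    """End-to-end output: association result, relevances and the model."""

    association: AssociationResult
    relevance: GlobalRelevance
    model: nn.TrainedModel
    test_accuracy: float
    test_balanced_accuracy: float


def deepcombi(
    g: GenotypeMatrix,
    y: PhenotypeVector,
    train_cfg: nn.TrainingConfig | None = None,
    lrp_cfg: LRPConfig | None = None,
    selection: SelectionConfig | None = None,
    t_star: float = DEFAULT_THRESHOLD,
    calibrated: bool = False,
    split_fraction: float = 0.8,
) -> DeepCombiResult:
    """The full three-step method on one dataset.

    The network is trained on a stratified ``split_fraction`` share of the
    subjects (accuracy reported on the held-out rest); relevance scores are
    computed for every subject through the trained network, and chi-square
    p-values use all subjects so they are directly comparable to RPVT.
    """
    train_cfg = train_cfg or nn.TrainingConfig()
    lrp_cfg = lrp_cfg or LRPConfig()
    selection = selection or SelectionConfig()

    feature_mask, g_red = nn.pvalue_prefilter(g, y, train_cfg.kappa)
    onehot = encode_one_hot(g_red)
    split = stratified_split(y, split_fraction, seed=train_cfg.seed)
    x_train, stats = standardize(onehot.features[split.train_indices])
    model = nn.train(
        x_train, y.labels[split.train_indices], train_cfg,
        stats=stats, feature_mask=feature_mask,
    )
    x_all, _ = standardize(onehot.features, stats)
    test_acc = nn.accuracy(model, x_all[split.test_indices], y.labels[split.test_indices])
    pred_test, _, _ = nn.predict(model, x_all[split.test_indices])
    y_test = y.labels[split.test_indices]
    tpr = float((pred_test[y_test == 1] == 1).mean()) if (y_test == 1).any() else np.nan
    tnr = float((pred_test[y_test == 0] == 0).mean()) if (y_test == 0).any() else np.nan
    bal_acc = float(np.nanmean([tpr, tnr]))

    r0 = lrp_backward(model, x_all, lrp_cfg)
    rho = collapse_onehot(r0, feature_mask)
    relevance = global_relevance(rho, selection)
    selected = select_top_k(relevance.r_filtered, selection.k)
    # prefiltered SNPs are never candidates even when few positive scores exist
    selected &= feature_mask if feature_mask is not None else True

    pvalues = mask_pvalues(chi2_pvalues_all(g, y), selected)
    assoc = AssociationResult(
        pvalues, t_star, selected,
        significance_mask(pvalues, t_star, calibrated) & selected,
        method="deepcombi",
    )
    return DeepCombiResult(assoc, relevance, model, test_acc, bal_acc)
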