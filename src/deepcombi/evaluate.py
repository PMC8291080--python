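"""Metrics, ROC/PR curves and the paired replication harness.

Discovery performance is measured against the known informative set of a
simulated dataset: TP are significant SNPs inside that set, FP significant
SNPs outside it. Curves sweep the per-SNP statistic (ascending p-values, or
negated raw scores) through all thresholds; curves from many replications
are averaged vertically on a fixed x-grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(significant: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Cross-tabulate a significance mask against the ground-truth mask."""
    significant = np.asarray(significant, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if significant.shape != truth.shape:
        raise ValueError("masks must be aligned")
    return ConfusionCounts(
        tp=int((significant & truth).sum()),
        fp=int((significant & ~truth).sum()),
        tn=int((~significant & ~truth).sum()),
        fn=int((~significant & truth).sum()),
    )


def metric_suite(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, balanced accuracy, precision, TPR, FPR.

    Metrics with a zero denominator are reported as nan, never silently 0.
    """

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    tpr = ratio(c.tp, c.tp + c.fn)
    tnr = ratio(c.tn, c.tn + c.fp)
    return {
        "accuracy": ratio(c.tp + c.tn, c.total),
        "balanced_accuracy": (tpr + tnr) / 2,
        "precision": ratio(c.tp, c.tp + c.fp),
        "tpr": tpr,
        "fpr": ratio(c.fp, c.fp + c.tn),
    }


@dataclass
class CurvePoints:
    """Monotone (x, y) curve points plus the trapezoid AUC."""

    x: np.ndarray
    y: np.ndarray
    auc: float


def curve_from_ranking(
    statistic: np.ndarray,
    truth: np.ndarray,
    kind: str = "roc",
    absolute_counts: bool = False,
) -> CurvePoints:
    """ROC or PR curve from an ascending per-SNP statistic.

    ``statistic`` is interpreted like a p-value vector: smaller means more
    strongly associated (negate raw scores first). Every threshold is swept;
    tied statistics enter together. With ``absolute_counts`` the ROC axes are
    TP versus FP instead of TPR versus FPR.
    """
    statistic = np.asarray(statistic, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if not truth.any():
        raise ValueError("ground-truth set is empty")
    order = np.argsort(statistic, kind="stable")
    sorted_truth = truth[order]
    tp = np.concatenate([[0], np.cumsum(sorted_truth)])
    fp = np.concatenate([[0], np.cumsum(~sorted_truth)])
    # collapse ties: keep only the last point of each tied group
    svals = statistic[order]
    keep = np.concatenate([svals[1:] != svals[:-1], [True]])
    keep = np.concatenate([[True], keep])
    tp, fp = tp[keep], fp[keep]
    n_pos, n_neg = int(truth.sum()), int((~truth).sum())
    if kind == "roc":
        x = fp if absolute_counts else fp / max(n_neg, 1)
        y = tp if absolute_counts else tp / n_pos
        auc = float(np.trapezoid(y, x))
    elif kind == "pr":
        with np.errstate(invalid="ignore"):
            precision = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 1.0)
        recall = tp / n_pos
        x, y = recall, precision
        auc = float(np.trapezoid(y, x))
    else:
        raise ValueError("kind must be 'roc' or 'pr'")
    return CurvePoints(x, y, auc)


def average_curves(
    curves: list[CurvePoints], grid_points: int = 200
) -> CurvePoints:
    """Vertical averaging on a common x-grid (documented convention)."""
    grid = np.linspace(0.0, max(float(c.x[-1]) for c in curves), grid_points)
    ys = np.vstack([np.interp(grid, c.x, c.y) for c in curves])
    mean_y = ys.mean(axis=0)
    return CurvePoints(grid, mean_y, float(np.trapezoid(mean_y, grid)))


@dataclass
class ReplicationSummary:
    """Per-method accuracy table and per-replication discovery records."""

    accuracy_table: pd.DataFrame
    records: pd.DataFrame
    curves: dict[str, CurvePoints] = field(default_factory=dict)


def summarize_accuracy(per_rep: dict[str, list[tuple[float, float]]]) -> pd.DataFrame:
    """Mean/sd/min/max of (accuracy, balanced accuracy) per method."""
    rows = []
    for method, pairs in per_rep.items():
        acc = np.array([p[0] for p in pairs])
        bal = np.array([p[1] for p in pairs])
        rows.append(
            {
                "method": method,
                "mean_accuracy": acc.mean(),
                "mean_balanced_accuracy": bal.mean(),
                "sd_accuracy": acc.std(ddof=1) if len(acc) > 1 else 0.0,
                "sd_balanced_accuracy": bal.std(ddof=1) if len(bal) > 1 else 0.0,
                "min_accuracy": acc.min(),
                "min_balanced_accuracy": bal.min(),
                "max_accuracy": acc.max(),
                "max_balanced_accuracy": bal.max(),
            }
        )
    return pd.DataFrame(rows)


def replication_experiment(
    n_reps: int,
    methods: dict,
    simulate_fn,
    seed: int = 0,
    curve_grid: int = 200,
) -> ReplicationSummary:
    """Run each method on identical simulated datasets (paired design).

    ``simulate_fn(seed)`` must return a dataset with ``genotypes``,
    ``phenotypes`` and ``truth_mask``; each entry of ``methods`` maps a name
    to ``fn(dataset, seed) -> (statistic, significant_mask, accuracy_pair)``
    where ``accuracy_pair`` may be None for methods without a classifier.
    """
    acc: dict[str, list] = {m: [] for m in methods}
    curve_bank: dict[str, list[CurvePoints]] = {m: [] for m in methods}
    rows = []
    for rep in range(n_reps):
        ds = simulate_fn(seed + rep)
        truth = ds.truth_mask
        for name, fn in methods.items():
            statistic, significant, acc_pair = fn(ds, seed + rep)
            if acc_pair is not None:
                acc[name].append(acc_pair)
            counts = confusion_counts(significant, truth)
            rows.append(
                {"rep": rep, "method": name, "tp": counts.tp, "fp": counts.fp,
                 "tn": counts.tn, "fn": counts.fn,
                 "min_p_informative": float(np.min(statistic[truth]))}
            )
            curve_bank[name].append(
                curve_from_ranking(statistic, truth, "roc", absolute_counts=True)
            )
    curves = {m: average_curves(cs, curve_grid) for m, cs in curve_bank.items() if cs}
    table = summarize_accuracy({m: v for m, v in acc.items() if v})
    return ReplicationSummary(table, pd.DataFrame(rows), curves)
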