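"""ROC/AUC and fixed-threshold operating-point metrics.

AUC follows the Mann-Whitney formulation: the probability that a randomly
chosen positive outscores a randomly chosen negative, with ties credited
0.5 — identical to trapezoidal integration of the ROC curve. The operating
point reports sensitivity (true-positive rate among depressed cases) and
specificity (true-negative rate among non-depressed cases) at a fixed
probability threshold with the inclusive flag rule prob >= threshold.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import rankdata

from .errors import DegenerateLabelsError


@dataclass(frozen=True)
class RocCurve:
    """ROC points in threshold-descending order, endpoints (0,0) and (1,1)."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float

    def to_csv(self, path: str | Path) -> None:
        with Path(path).open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["fpr", "tpr", "threshold"])
            for f, t, th in zip(self.fpr, self.tpr, self.thresholds):
                writer.writerow([f"{f:.10g}", f"{t:.10g}", f"{th:.10g}"])


@dataclass(frozen=True)
class OperatingPoint:
    """Confusion counts and rates at a fixed decision threshold."""

    threshold: float
    sensitivity: float
    specificity: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def confusion(self) -> tuple[int, int, int, int]:
        return (self.tp, self.fp, self.tn, self.fn)

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "sensitivity": round(self.sensitivity, 3),
            "specificity": round(self.specificity, 3),
            "confusion": {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn},
            "n_pos": self.tp + self.fn,
            "n_neg": self.tn + self.fp,
        }


def _check_binary(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=int).ravel()
    if len(set(np.unique(y).tolist())) < 2:
        raise DegenerateLabelsError("both classes required")
    return y


def roc_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 * P(tie).

    Computed via midranks, equivalent to averaging the pairwise indicator
    over all (positive, negative) pairs with half credit for ties.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    y = _check_binary(y)
    n_pos = int(np.sum(y == 1))
    n_neg = y.size - n_pos
    ranks = rankdata(scores)  # midranks handle ties as 0.5 credit
    r_pos = float(np.sum(ranks[y == 1]))
    return (r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def roc_curve(scores: np.ndarray, y: np.ndarray) -> RocCurve:
    """ROC points over distinct score thresholds (ties merged into one step)."""
    scores = np.asarray(scores, dtype=float).ravel()
    y = _check_binary(y)
    n_pos = int(np.sum(y == 1))
    n_neg = y.size - n_pos
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = y[order]
    tps = np.cumsum(y_sorted == 1)
    fps = np.cumsum(y_sorted == 0)
    # keep only the last index of each tied block of scores
    last_of_block = np.r_[np.diff(s_sorted) != 0, True]
    tpr = tps[last_of_block] / n_pos
    fpr = fps[last_of_block] / n_neg
    thresholds = s_sorted[last_of_block]
    tpr = np.r_[0.0, tpr]
    fpr = np.r_[0.0, fpr]
    thresholds = np.r_[np.inf, thresholds]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)


def operating_point(probs: np.ndarray, y: np.ndarray, threshold: float) -> OperatingPoint:
    """Confusion counts and sensitivity/specificity at prob >= threshold."""
    probs = np.asarray(probs, dtype=float).ravel()
    y = _check_binary(y)
    flags = probs >= threshold
    tp = int(np.sum(flags & (y == 1)))
    fp = int(np.sum(flags & (y == 0)))
    tn = int(np.sum(~flags & (y == 0)))
    fn = int(np.sum(~flags & (y == 1)))
    return OperatingPoint(
        threshold=float(threshold),
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
    )


def metrics_report(
    scores: np.ndarray, probs: np.ndarray, y: np.ndarray, threshold: float
) -> dict:
    """JSON-ready evaluation summary: AUC plus the fixed operating point."""
    op = operating_point(probs, y, threshold)
    out = {"auc": round(roc_auc(scores, y), 3)}
    out.update(op.to_dict())
    return out


def write_metrics(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=1, sort_keys=True), encoding="utf-8")
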