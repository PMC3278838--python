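"""Confusion-based metrics, ROC/AUC and ROC-space quadrant analysis.

Sensitivity Sn = TP/(TP+FN), specificity Sp = TN/(TN+FP), balanced
accuracy BACC = (Sn+Sp)/2, and the Matthews correlation coefficient
summarize a binary predictor.  The ROC-space unit square is split at
(FPR, TPR) = (0.5, 0.5) into quadrants I-IV; quadrant II (TPR > 0.5,
FPR < 0.5) marks predictors that balance sensitivity and specificity.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(true_labels, predicted_labels) -> ConfusionCounts:
    """Standard binary confusion counts with 1 = positive."""
    y = np.asarray(true_labels).astype(int)
    p = np.asarray(predicted_labels).astype(int)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {p.shape}")
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (p == 1))),
        fp=int(np.sum((y == 0) & (p == 1))),
        tn=int(np.sum((y == 0) & (p == 0))),
        fn=int(np.sum((y == 1) & (p == 0))),
    )


def metrics(c: ConfusionCounts) -> tuple[float, float, float, float]:
    """(Sn, Sp, BACC, MCC); an empty class yields NaN for the affected rate.

    MCC's zero-denominator case (any marginal empty) is defined as 0.
    """
    if c.total == 0:
        raise ValueError("empty confusion matrix")
    sn = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else math.nan
    sp = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else math.nan
    bacc = (sn + sp) / 2
    den = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if den == 0:
        mcc = 0.0
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(den)
    return sn, sp, bacc, mcc


def roc_points(scores, true_labels) -> np.ndarray:
    """(FPR, TPR, threshold) rows from (0,0) to (1,1), ties collapsed.

    Thresholds sweep the distinct score values plus an initial sentinel,
    so the point count is at most the number of distinct scores plus one.
    """
    y = np.asarray(true_labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = _sk_roc_curve(y, np.asarray(scores, dtype=float),
                                  drop_intermediate=False)
    return np.column_stack([fpr, tpr, thr])


def auc(points: np.ndarray) -> float:
    """Trapezoidal area under a ROC curve.

    Equals the Mann-Whitney concordance probability P(score+ > score-)
    with ties counted one half.
    """
    pts = np.asarray(points)
    fpr, tpr = pts[:, 0], pts[:, 1]
    order = np.argsort(fpr, kind="stable")
    return float(np.trapezoid(tpr[order], fpr[order]))


def auc_score(scores, true_labels) -> float:
    """AUC straight from scores and labels."""
    return auc(roc_points(scores, true_labels))


def quadrant(point: tuple[float, float]) -> str:
    """Quadrant of a (FPR, TPR) operating point.

    II: TPR > 0.5 and FPR < 0.5 (high Sn, high Sp — the desirable corner);
    I: TPR > 0.5, FPR >= 0.5; III: TPR <= 0.5, FPR < 0.5; IV otherwise.
    Boundary points (rate exactly 0.5) fall into the "lower" quadrant.
    """
    fpr, tpr = point
    if not (0 <= fpr <= 1 and 0 <= tpr <= 1):
        raise ValueError(f"(FPR, TPR) must lie in the unit square, got {point}")
    if tpr > 0.5:
        return "II" if fpr < 0.5 else "I"
    return "III" if fpr < 0.5 else "IV"


@dataclass
class EvaluationReport:
    """Everything needed to judge one classifier on one labeled set."""

    counts: ConfusionCounts
    sensitivity: float
    specificity: float
    bacc: float
    mcc: float
    roc: np.ndarray
    auc: float
    quadrant: str

    def to_json(self) -> str:
        return json.dumps(
            {
                "counts": asdict(self.counts),
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "bacc": self.bacc,
                "mcc": self.mcc,
                "auc": self.auc,
                "quadrant": self.quadrant,
                "roc": [
                    {"fpr": float(f), "tpr": float(t), "threshold": float(th)}
                    for f, t, th in self.roc
                ],
            },
            indent=2,
        )


def evaluate(true_labels, scores, threshold: float = 0.5) -> EvaluationReport:
    """Full report: metrics at the threshold plus the threshold-free curve."""
    y = np.asarray(true_labels).astype(int)
    s = np.asarray(scores, dtype=float)
    pred = (s >= threshold).astype(int)
    c = confusion(y, pred)
    sn, sp, bacc, mcc = metrics(c)
    pts = roc_points(s, y)
    area = auc(pts)
    fpr_at = 1 - sp
    return EvaluationReport(
        counts=c,
        sensitivity=sn,
        specificity=sp,
        bacc=bacc,
        mcc=mcc,
        roc=pts,
        auc=area,
        quadrant=quadrant((fpr_at, sn)),
    )


def plot_roc(report: EvaluationReport, path: str, label: str = "model") -> None:
    """ROC curve figure (PNG/PDF by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(report.roc[:, 0], report.roc[:, 1],
            label=f"{label} (AUC = {report.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate (1 - Sp)")
    ax.set_ylabel("True positive rate (Sn)")
    ax.legend(loc="lower right")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def plot_quadrants(points: dict[str, tuple[float, float]], path: str) -> None:
    """Scatter of (FPR, TPR) operating points on the quadrant grid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, (fpr, tpr) in points.items():
        ax.scatter([fpr], [tpr], label=f"{name} ({quadrant((fpr, tpr))})")
    ax.axhline(0.5, color="grey", lw=0.8)
    ax.axvline(0.5, color="grey", lw=0.8)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_xlabel("False positive rate (1 - Sp)")
    ax.set_ylabel("True positive rate (Sn)")
    ax.legend(loc="lower right", fontsize=8)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
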