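"""ROC discrimination of SCD from HC using node-strength scores.

The empirical AUC is the Mann-Whitney U statistic normalized by
n0*n1 (midrank tie handling), identical to the trapezoidal area under
the ROC curve.  The operating point maximizes Youden's
J = sensitivity + specificity - 1, with ties broken toward higher
specificity.  SCD is the positive class: higher strength scores count
as more SCD-like.

For cohorts specified only by group means and SDs, the binormal closed
form AUC = Phi((mu1 - mu0) / sqrt(sd0^2 + sd1^2)) serves as the
analytic check, and ``monte_carlo_summary_auc`` estimates the mean
finite-sample empirical AUC over replicate Gaussian cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_curve


@dataclass(frozen=True)
class RocResult:
    auc: float
    sensitivity: float
    specificity: float
    threshold: float
    fpr: np.ndarray = field(repr=False)
    tpr: np.ndarray = field(repr=False)
    criterion: str = "youden"

    def to_dict(self) -> dict:
        return {"auc": self.auc, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "threshold": self.threshold,
                "criterion": self.criterion}


def empirical_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as Mann-Whitney U / (n0*n1) with midrank ties; positive
    class is label 1."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(np.concatenate([neg, pos]))
    u = ranks[neg.size:].sum() - pos.size * (pos.size + 1) / 2
    return float(u / (pos.size * neg.size))


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocResult:
    """Full ROC analysis: AUC, curve, and the Youden operating point.

    ``labels`` may be 0/1 or the strings "HC"/"SCD" (SCD positive).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if labels.dtype.kind in "UO":
        labels = (labels == "SCD").astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thresholds = roc_curve(labels, scores)
    auc = empirical_auc(scores, labels)
    j = tpr - fpr
    # roc_curve orders thresholds decreasing, so fpr is nondecreasing and
    # the first argmax is the highest-specificity maximizer of J.
    best = int(np.argmax(j))
    return RocResult(auc=auc, sensitivity=float(tpr[best]),
                     specificity=float(1.0 - fpr[best]),
                     threshold=float(thresholds[best]), fpr=fpr, tpr=tpr)


@dataclass(frozen=True)
class BinormalParams:
    """Gaussian score distributions for the two groups (0 = HC, 1 = SCD)."""

    mu0: float
    sd0: float
    mu1: float
    sd1: float

    def __post_init__(self) -> None:
        if self.sd0 <= 0 or self.sd1 <= 0:
            raise ValueError("standard deviations must be positive")


def binormal_auc(p: BinormalParams) -> float:
    """Closed-form AUC for two Gaussian score distributions."""
    return float(sps.norm.cdf((p.mu1 - p.mu0) / np.hypot(p.sd0, p.sd1)))


def monte_carlo_summary_auc(params: BinormalParams, n0: int, n1: int,
                            n_replicates: int, rng: np.random.Generator,
                            bilateral: tuple[BinormalParams, BinormalParams] | None = None,
                            ) -> float:
    """Mean empirical AUC over replicate Gaussian cohorts.

    Each replicate draws n0 HC and n1 SCD scores from the summary
    distributions and computes the empirical AUC.  With ``bilateral``
    given as (left, right) parameter pairs, per-subject scores are the
    sum of independent left and right draws and ``params`` is ignored.
    """
    aucs = np.empty(n_replicates)
    labels = np.concatenate([np.zeros(n0, dtype=int), np.ones(n1, dtype=int)])
    for k in range(n_replicates):
        if bilateral is not None:
            left, right = bilateral
            hc = rng.normal(left.mu0, left.sd0, n0) + rng.normal(right.mu0, right.sd0, n0)
            scd = rng.normal(left.mu1, left.sd1, n1) + rng.normal(right.mu1, right.sd1, n1)
        else:
            hc = rng.normal(params.mu0, params.sd0, n0)
            scd = rng.normal(params.mu1, params.sd1, n1)
        aucs[k] = empirical_auc(np.concatenate([hc, scd]), labels)
    return float(aucs.mean())
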