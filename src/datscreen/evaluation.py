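"""ROC evaluation and pre/post-intervention response assessment.

The screening score is evaluated against the specialist CP/CN labels with
a full ROC sweep; the operating threshold is the Youden optimum
(maximizing sensitivity + specificity - 1, ties resolved toward the
higher threshold, i.e. fewer referrals).

A successful optimization of therapy is expected to drop the score by
about (pre-score - 20).  ``classify_response`` places a pre/post score
pair into one of four regions: predicted response, failed optimization,
unmasked need (the post score rose into the high band), or low-risk
stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve as _sk_roc_curve

__all__ = [
    "ROCReport",
    "ResponseAssessment",
    "RESPONSE_REGIONS",
    "DEFAULT_RESPONSE_TOLERANCE",
    "roc_report",
    "operating_point",
    "optimum_threshold",
    "predicted_response_delta",
    "classify_response",
    "assess_response",
]

#: Half-width of the predicted-response band, in score points.
DEFAULT_RESPONSE_TOLERANCE = 15.0
#: Score at/above which the high-risk band starts.
HIGH_RISK = 60.0
#: Expected residual score after successful optimization.
RESPONSE_OFFSET = 20.0

RESPONSE_REGIONS = (
    "predicted_response",
    "failed_optimization",
    "unmasked_need",
    "low_risk_stable",
)


@dataclass
class ROCReport:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    optimum_threshold: float
    sensitivity_at_optimum: float  # percent
    specificity_at_optimum: float  # percent

    def as_dict(self) -> dict:
        return {
            "auc": float(self.auc),
            "optimum_threshold": float(self.optimum_threshold),
            "sensitivity_at_optimum": float(self.sensitivity_at_optimum),
            "specificity_at_optimum": float(self.specificity_at_optimum),
            "curve": [
                {"fpr": float(f), "tpr": float(t), "threshold": float(th)}
                for f, t, th in zip(self.fpr, self.tpr, self.thresholds)
            ],
        }


def _binary(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "OUS":
        y = (labels.astype(str) == "CP").astype(int)
    else:
        y = labels.astype(int)
    if np.unique(y).size < 2:
        raise ValueError("degenerate labels")
    return y


def roc_report(scores, labels) -> ROCReport:
    """Full ROC sweep with AUC and the Youden-optimal operating point.

    The AUC equals the Mann-Whitney pair statistic (ties count one half).
    Classification convention: score >= threshold predicts CP.
    """
    scores = np.asarray(scores, dtype=float)
    y = _binary(labels)
    fpr, tpr, thr = _sk_roc_curve(y, scores)
    auc = float(roc_auc_score(y, scores))
    t, sens, spec = optimum_threshold(fpr, tpr, thr)
    return ROCReport(fpr, tpr, thr, auc, t, sens, spec)


def optimum_threshold(fpr: np.ndarray, tpr: np.ndarray, thresholds: np.ndarray):
    """Youden-optimal threshold and its operating point (percents).

    Ties in J = tpr - fpr are broken toward the higher threshold.  The
    sentinel top threshold of the sweep (above every score) is reported as
    just above the maximal finite score when selected.
    """
    j = tpr - fpr
    i = int(np.argmax(j))  # thresholds descend, so argmax takes the highest
    t = float(thresholds[i])
    if np.isinf(t):
        finite = thresholds[np.isfinite(thresholds)]
        t = float(finite.max()) + 1.0 if finite.size else 1.0
    return t, float(100.0 * tpr[i]), float(100.0 * (1.0 - fpr[i]))


def operating_point(scores, labels, threshold: float):
    """Sensitivity and specificity (percents) of 'score >= threshold -> CP'."""
    scores = np.asarray(scores, dtype=float)
    y = _binary(labels)
    pred = scores >= threshold
    sens = 100.0 * (pred & (y == 1)).sum() / (y == 1).sum()
    spec = 100.0 * (~pred & (y == 0)).sum() / (y == 0).sum()
    return float(sens), float(spec)


def _check_score(value: float, name: str) -> float:
    value = float(value)
    if not 0.0 <= value <= 100.0:
        raise ValueError(f"{name} must be in [0, 100]")
    return value


def predicted_response_delta(pre_score: float) -> float:
    """Expected score drop when therapy optimization succeeds: pre - 20."""
    return _check_score(pre_score, "pre_score") - RESPONSE_OFFSET


def classify_response(pre: float, post: float, tolerance: float = DEFAULT_RESPONSE_TOLERANCE) -> str:
    """Region of a pre/post score pair after a therapeutic intervention.

    - low_risk_stable: both scores below the high band and essentially
      unchanged;
    - predicted_response: the observed drop matches the expected
      pre - 20 within ``tolerance``;
    - unmasked_need: the score rose beyond tolerance into the high band
      (increasing therapy revealed fluctuations/dyskinesia);
    - failed_optimization: everything else (the score stayed high or did
      not drop as predicted).
    """
    pre = _check_score(pre, "pre")
    post = _check_score(post, "post")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    delta = pre - post
    if pre < HIGH_RISK and post < HIGH_RISK and abs(delta) <= tolerance:
        return "low_risk_stable"
    if abs(delta - (pre - RESPONSE_OFFSET)) <= tolerance:
        return "predicted_response"
    if delta < -tolerance and post >= HIGH_RISK:
        return "unmasked_need"
    return "failed_optimization"


@dataclass
class ResponseAssessment:
    pre_score: float
    post_score: float
    delta: float
    predicted_delta: float
    region: str


def assess_response(pre: float, post: float, tolerance: float = DEFAULT_RESPONSE_TOLERANCE) -> ResponseAssessment:
    """Bundle the observed and predicted score change with its region."""
    pre = _check_score(pre, "pre")
    post = _check_score(post, "post")
    return ResponseAssessment(
        pre_score=pre,
        post_score=post,
        delta=pre - post,
        predicted_delta=predicted_response_delta(pre),
        region=classify_response(pre, post, tolerance),
    )
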