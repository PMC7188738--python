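"""ROC, operating-point, and decision-curve evaluation of diagnostic scores.

The positive class is tumor recurrence throughout and the classification
rule is "score >= threshold => positive".  AUC is the Mann-Whitney
statistic (ties counted one half); confidence intervals come from a
stratified nonparametric bootstrap with percentile limits; operating
points default to the Youden-J maximum with ties resolved toward the
lowest threshold.  Net benefit follows the standard decision-curve
definition NB(p_t) = TP/n - (FP/n) * p_t / (1 - p_t), compared against
the treat-all and treat-none strategies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

DEFAULT_N_BOOT = 2000
DCA_GRID = np.round(np.arange(0.01, 1.0, 0.01), 2)


@dataclass
class EvaluationReport:
    """ROC metrics of one model on one cohort."""

    model: str
    cohort: str
    auc: float
    ci_low: float
    ci_high: float
    threshold: float
    sensitivity: float
    specificity: float
    accuracy: float

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "cohort": self.cohort,
            "AUC": self.auc,
            "CI95_low": self.ci_low,
            "CI95_high": self.ci_high,
            "Threshold": self.threshold,
            "Sensitivity": self.sensitivity,
            "Specificity": self.specificity,
            "Accuracy": self.accuracy,
        }


@dataclass
class DecisionCurve:
    """Net-benefit curves of a model vs treat-all / treat-none."""

    thresholds: np.ndarray
    net_benefit_model: np.ndarray
    net_benefit_all: np.ndarray
    net_benefit_none: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "net_benefit_model": self.net_benefit_model,
                "net_benefit_all": self.net_benefit_all,
                "net_benefit_none": self.net_benefit_none,
            }
        )


def _check_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney statistic, ties count 1/2)."""
    y = np.asarray(labels, dtype=int).ravel()
    s = np.asarray(scores, dtype=float).ravel()
    _check_classes(y)
    return float(roc_auc_score(y, s))


def auc_ci(
    scores,
    labels,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> tuple[float, float]:
    """Stratified-bootstrap percentile 95% CI for the AUC.

    Resampling is within-class, so every resample retains both classes;
    deterministic for a fixed seed.
    """
    y = np.asarray(labels, dtype=int).ravel()
    s = np.asarray(scores, dtype=float).ravel()
    _check_classes(y)
    pos, neg = s[y == 1], s[y == 0]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("each class needs >= 2 members for a bootstrap CI")
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    yb = np.concatenate([np.ones(len(pos), int), np.zeros(len(neg), int)])
    for b in range(n_boot):
        sb = np.concatenate(
            [rng.choice(pos, len(pos)), rng.choice(neg, len(neg))]
        )
        aucs[b] = roc_auc_score(yb, sb)
    low, high = np.percentile(aucs, [2.5, 97.5])
    return float(low), float(high)


def operating_point(scores, labels, rule: str = "youden") -> dict:
    """Threshold and metrics at the chosen operating rule.

    ``youden`` maximizes sensitivity + specificity - 1 over all observed
    score values (ties broken toward the lowest threshold); positives are
    predicted where score >= threshold.
    """
    y = np.asarray(labels, dtype=int).ravel()
    s = np.asarray(scores, dtype=float).ravel()
    _check_classes(y)
    if rule != "youden":
        raise ValueError(f"unknown operating rule {rule!r}")
    candidates = np.unique(s)
    best = None
    for thr in candidates:  # ascending -> lowest threshold wins ties
        pred = s >= thr
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        sens = tp / np.sum(y == 1)
        spec = 1 - fp / np.sum(y == 0)
        j = sens + spec - 1
        if best is None or j > best["youden_j"] + 1e-12:
            best = {
                "threshold": float(thr),
                "sensitivity": float(sens),
                "specificity": float(spec),
                "accuracy": float(np.mean(pred == (y == 1))),
                "youden_j": float(j),
            }
    return best


def evaluate_scores(
    scores,
    labels,
    model: str = "model",
    cohort: str = "primary",
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> EvaluationReport:
    """Full ROC report: AUC with bootstrap CI plus Youden operating point."""
    auc = roc_auc(scores, labels)
    low, high = auc_ci(scores, labels, n_boot=n_boot, seed=seed)
    op = operating_point(scores, labels)
    return EvaluationReport(
        model=model,
        cohort=cohort,
        auc=auc,
        ci_low=low,
        ci_high=high,
        threshold=op["threshold"],
        sensitivity=op["sensitivity"],
        specificity=op["specificity"],
        accuracy=op["accuracy"],
    )


def decision_curve(
    probabilities, labels, threshold_grid: np.ndarray | None = None
) -> DecisionCurve:
    """Net benefit of the model, treat-all, and treat-none strategies."""
    y = np.asarray(labels, dtype=int).ravel()
    p = np.asarray(probabilities, dtype=float).ravel()
    _check_classes(y)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    grid = DCA_GRID if threshold_grid is None else np.asarray(threshold_grid, float)
    if np.any(grid >= 1.0) or np.any(grid <= 0.0):
        raise ValueError("threshold grid must lie strictly inside (0, 1)")
    n = len(y)
    prevalence = y.mean()
    odds = grid / (1.0 - grid)
    nb_model = np.empty(len(grid))
    for i, pt in enumerate(grid):
        pred = p >= pt
        tp = np.sum(pred & (y == 1)) / n
        fp = np.sum(pred & (y == 0)) / n
        nb_model[i] = tp - fp * odds[i]
    nb_all = prevalence - (1.0 - prevalence) * odds
    return DecisionCurve(
        thresholds=grid,
        net_benefit_model=nb_model,
        net_benefit_all=nb_all,
        net_benefit_none=np.zeros(len(grid)),
    )


def compare_models(reports: list[EvaluationReport]) -> pd.DataFrame:
    """Rank >= 2 same-cohort reports by AUC (descending; ties by model name)."""
    if len(reports) < 2:
        raise ValueError("need at least 2 reports to compare")
    cohorts = {r.cohort for r in reports}
    if len(cohorts) != 1:
        raise ValueError(f"reports span different cohorts: {sorted(cohorts)}")
    frame = pd.DataFrame([r.to_dict() for r in reports])
    return frame.sort_values(
        ["AUC", "model"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
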