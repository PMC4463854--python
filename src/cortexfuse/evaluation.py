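"""Classifier validation: leave-one-out cross-validation, confusion
metrics, ROC construction from held-out discriminant scores, and the
per-region simple logistic regression screen.

LOOCV fits the full pipeline — including PRESS component selection and, if
enabled, data-driven region selection — on N-1 subjects and predicts the
held-out one, so each subject is scored exactly once by a model that never
saw it.  The positive class of a pairwise comparison is the more impaired
diagnosis (AD in AD/NC and AD/MCI; MCI in MCI/NC).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .features import SEVERITY, FeatureTable, assemble, select_data_driven
from .plslda import fit_plslda, predict

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierConfig",
    "CvResult",
    "RocCurve",
    "LogisticScreenRow",
    "positive_class_of",
    "loocv",
    "confusion_metrics",
    "roc_from_scores",
    "logistic_regression_1d",
    "logistic_screen",
]


def positive_class_of(group_a: str, group_b: str) -> str:
    """The more impaired diagnosis of a pair (severity NC < MCI < AD)."""
    for g in (group_a, group_b):
        if g not in SEVERITY:
            raise ValueError(f"unknown diagnosis {g!r}")
    return group_a if SEVERITY[group_a] >= SEVERITY[group_b] else group_b


@dataclass
class ClassifierConfig:
    """Knobs of the PLS-LDA pipeline used inside each LOOCV fold."""

    a_max: int = 10
    autoscale: bool = False
    priors: str = "equal"
    #: refit data-driven top-k region selection inside every training fold
    #: (leakage-safe); None disables selection.
    data_driven_k: int | None = None
    #: reproduce the single-shot reading: select regions once on the full
    #: table before LOOCV (leaks the held-out subject into selection).
    select_once: bool = False


@dataclass
class CvResult:
    """Per-subject LOOCV predictions plus derived confusion metrics."""

    subjects: list
    true_labels: np.ndarray  # 0/1
    predicted: np.ndarray  # 0/1
    scores: np.ndarray  # signed discriminant scores, positive favors 1
    positive_class: str
    negative_class: str

    @property
    def counts(self) -> dict[str, int]:
        t, p = self.true_labels, self.predicted
        return {
            "TP": int(((t == 1) & (p == 1)).sum()),
            "FN": int(((t == 1) & (p == 0)).sum()),
            "TN": int(((t == 0) & (p == 0)).sum()),
            "FP": int(((t == 0) & (p == 1)).sum()),
        }

    @property
    def accuracy(self) -> float:
        c = self.counts
        return (c["TP"] + c["TN"]) / len(self.true_labels)

    @property
    def sensitivity(self) -> float | None:
        c = self.counts
        pos = c["TP"] + c["FN"]
        return c["TP"] / pos if pos else None

    @property
    def specificity(self) -> float | None:
        c = self.counts
        neg = c["TN"] + c["FP"]
        return c["TN"] / neg if neg else None

    def roc(self) -> "RocCurve":
        return roc_from_scores(self.scores, self.true_labels, positive_class=1)


def confusion_metrics(
    predictions: np.ndarray, truths: np.ndarray, positive_class
) -> tuple[float, float | None, float | None]:
    """(accuracy, sensitivity, specificity) for binary predictions.

    Sensitivity is the true-positive fraction and specificity the
    true-negative fraction.  When the truth vector contains no positives
    (or no negatives) the undefined metric is returned as None, not 0.
    """
    predictions = np.asarray(predictions)
    truths = np.asarray(truths)
    if predictions.shape != truths.shape:
        raise ValueError("predictions and truths must have equal length")
    p = predictions == positive_class
    t = truths == positive_class
    tp = int((p & t).sum())
    tn = int((~p & ~t).sum())
    acc = (tp + tn) / len(truths)
    sens = tp / t.sum() if t.sum() else None
    spec = tn / (~t).sum() if (~t).sum() else None
    return acc, sens, spec


def loocv(table: FeatureTable, group_a: str, group_b: str,
          config: ClassifierConfig | None = None) -> CvResult:
    """Leave-one-out cross-validation of the PLS-LDA pipeline on a pair.

    Every subject is held out exactly once; the remaining N-1 form the
    training set on which PRESS selection (and optional data-driven region
    selection) is re-run from scratch.  The held-out subject's signed LDA
    discriminant score is retained for ROC construction.
    """
    config = config or ClassifierConfig()
    pos = positive_class_of(group_a, group_b)
    neg = group_b if pos == group_a else group_a
    sub = table.pair_subset(group_a, group_b)
    N = sub.n_subjects
    if N < 4:
        raise ValueError("LOOCV needs at least 4 subjects")
    y_all = (sub.labels == pos).astype(int).to_numpy()
    if y_all.sum() < 2 or (1 - y_all).sum() < 2:
        raise ValueError("both classes need at least 2 subjects")

    fixed_regions = None
    if config.data_driven_k is not None and config.select_once:
        fixed_regions = select_data_driven(sub, group_a, group_b,
                                           k=config.data_driven_k)

    X_all = sub.data.to_numpy(dtype=float)
    preds = np.empty(N, dtype=int)
    scores = np.empty(N)
    for i in range(N):
        keep = np.ones(N, dtype=bool)
        keep[i] = False
        y_tr = y_all[keep]
        if len(np.unique(y_tr)) < 2:
            raise ValueError(
                f"training fold without subject {sub.data.index[i]!r} "
                "lost a class; aborting"
            )
        if config.data_driven_k is not None:
            if fixed_regions is not None:
                regions = fixed_regions
            else:
                fold_table = FeatureTable(
                    sub.data[keep].copy(), sub.labels[keep].copy(),
                    dict(sub.modality), sub.source,
                )
                regions = select_data_driven(fold_table, group_a, group_b,
                                             k=config.data_driven_k)
            cols = [c for c in sub.feature_names
                    if c.rsplit(" [", 1)[0] in regions]
            col_idx = [sub.feature_names.index(c) for c in cols]
            X_tr = X_all[keep][:, col_idx]
            x_te = X_all[i, col_idx]
        else:
            X_tr = X_all[keep]
            x_te = X_all[i]
        model = fit_plslda(X_tr, y_tr, A_max=config.a_max,
                           autoscale=config.autoscale, priors=config.priors)
        preds[i], scores[i] = predict(model, x_te)
    return CvResult(
        subjects=list(sub.data.index),
        true_labels=y_all,
        predicted=preds,
        scores=scores,
        positive_class=pos,
        negative_class=neg,
    )


@dataclass
class RocCurve:
    """ROC points over all score thresholds plus the trapezoidal AUC."""

    fpr: np.ndarray  # 1 - specificity, nondecreasing
    tpr: np.ndarray  # sensitivity, nondecreasing
    thresholds: np.ndarray
    auc: float


def roc_from_scores(scores, truths, positive_class=1) -> RocCurve:
    """ROC curve from continuous scores (higher score favors positive).

    Sweeps thresholds over the unique score values; the trapezoidal AUC
    equals the Mann-Whitney concordance probability (ties counted half).
    Constant scores yield AUC 0.5 with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    truths = np.asarray(truths)
    if scores.shape != truths.shape:
        raise ValueError("scores and truths must have equal length")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    pos = truths == positive_class
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for a ROC curve")
    if np.ptp(scores) == 0:
        warnings.warn("constant scores; ROC is the chance diagonal",
                      stacklevel=2)
        return RocCurve(np.array([0.0, 1.0]), np.array([0.0, 1.0]),
                        np.array([np.inf, scores[0]]), 0.5)
    order = np.argsort(-scores, kind="stable")
    s, p = scores[order], pos[order]
    # collapse tied scores into single threshold steps
    distinct = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    tp = np.cumsum(p)[distinct]
    fp = np.cumsum(~p)[distinct]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    thresholds = np.r_[np.inf, s[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr, tpr, thresholds, auc)


@dataclass
class LogisticScreenRow:
    """One simple-logistic-regression fit: outcome ~ intercept + feature."""

    region: str
    modality: str
    beta: float
    se: float
    p_value: float
    auc: float
    separated: bool = False


def logistic_regression_1d(
    x: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-10
) -> tuple[float, float, float, float, bool]:
    """Maximum-likelihood simple logistic regression by IRLS.

    Fits ``logit P(y=1) = b0 + b1 x`` by iteratively reweighted least
    squares; the Wald standard error of the slope comes from the observed
    information and the p-value from the normal approximation.  Perfect (or
    quasi-perfect) separation is flagged instead of silently reporting huge
    coefficients.

    Returns ``(beta, se, p, intercept, separated)``.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    X = np.column_stack([np.ones_like(x), x])
    b = np.zeros(2)
    separated = False
    for _ in range(max_iter):
        eta = X @ b
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        w = mu * (1 - mu)
        if w.max() < 1e-10 or abs(b[1]) > 50:
            separated = True
            break
        XtW = X.T * w
        info = XtW @ X
        grad = X.T @ (y - mu)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            separated = True
            break
        b_new = b + step
        if np.abs(step).max() < tol:
            b = b_new
            break
        b = b_new
    else:
        if abs(b[1]) > 15:
            separated = True
    eta = X @ b
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
    w = np.maximum(mu * (1 - mu), 1e-300)
    info = (X.T * w) @ X
    cov = np.linalg.inv(info)
    se = float(np.sqrt(max(cov[1, 1], 0.0)))
    if separated or not np.isfinite(se) or se == 0:
        return float(np.sign(b[1]) * np.inf), float("inf"), 0.0, float(b[0]), True
    z = b[1] / se
    p = float(2 * sps.norm.sf(abs(z)))
    return float(b[1]), se, max(p, np.finfo(float).tiny), float(b[0]), False


def logistic_screen(
    table: FeatureTable, group_a: str, group_b: str
) -> list[LogisticScreenRow]:
    """Per-feature simple logistic regression screen (no covariates).

    For each feature, fits outcome ~ intercept + feature on the pairwise
    subset (positive = the more impaired diagnosis), reporting the slope,
    its Wald standard error and p-value, and the AU-ROC of the fitted
    probabilities.  Perfectly separating features are flagged rather than
    reported with runaway coefficients.
    """
    pos = positive_class_of(group_a, group_b)
    sub = table.pair_subset(group_a, group_b)
    y = (sub.labels == pos).astype(int).to_numpy()
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("both groups need at least 2 subjects")
    rows: list[LogisticScreenRow] = []
    for col in sub.feature_names:
        x = sub.data[col].to_numpy(dtype=float)
        beta, se, p, b0, separated = logistic_regression_1d(x, y)
        if separated:
            auc = roc_from_scores(x, y).auc
            auc = max(auc, 1 - auc)
            rows.append(LogisticScreenRow(
                region=col.rsplit(" [", 1)[0],
                modality=sub.modality[col],
                beta=beta, se=se, p_value=np.nan, auc=auc, separated=True,
            ))
            continue
        probs = 1.0 / (1.0 + np.exp(-(b0 + beta * x)))
        auc = roc_from_scores(probs, y).auc
        rows.append(LogisticScreenRow(
            region=col.rsplit(" [", 1)[0],
            modality=sub.modality[col],
            beta=beta, se=se, p_value=p, auc=auc,
        ))
    return rows
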