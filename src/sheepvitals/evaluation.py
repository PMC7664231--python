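"""Agreement statistics between predicted and reference vitals.

Two report types mirror how non-contact biometric methods are usually
validated: a through-origin linear regression of predictions against
reference values (slope, Pearson R, R^2, RMSE, and the share of points
outside the 95% prediction band), and a staged classifier report
(accuracy/error/MSE per training/testing/overall stage, confusion
matrix, one-vs-rest ROC curves).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import confusion_matrix as _confusion, roc_curve as _roc

__all__ = ["RegressionReport", "regress_through_origin",
           "classification_report"]


@dataclass
class RegressionReport:
    """Through-origin fit y = slope * x and its agreement statistics."""

    slope: float
    r: float        # ordinary Pearson correlation
    r2: float
    rmse: float
    n: int
    outlier_count: int
    outlier_pct: float
    outlier_mask: np.ndarray = field(repr=False, default=None)
    r_uncentered: float = None  # sqrt of the uncentered R^2 of the fit


def regress_through_origin(x, y, ci: float = 0.95) -> RegressionReport:
    """Least-squares fit of ``y = b x`` with no intercept.

    ``slope = sum(xy) / sum(x^2)``; R is the ordinary (centred) Pearson
    correlation, reported alongside the uncentered variant.  Outliers
    are points outside the t-based ``ci`` prediction interval of the
    through-origin fit, ``b x0 +- t s sqrt(1 + x0^2 / sum(x^2))`` with
    ``s^2 = SSE / (n - 1)`` (one fitted parameter).
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points")
    sxx = float(x @ x)
    if sxx == 0.0:
        raise ValueError("x is identically zero; slope undefined")
    slope = float(x @ y) / sxx
    resid = y - slope * x
    sse = float(resid @ resid)
    rmse = np.sqrt(sse / n)
    r = float(stats.pearsonr(x, y).statistic) if np.std(x) > 0 and np.std(y) > 0 else 0.0
    syy = float(y @ y)
    r_unc = float(np.sqrt(max(1.0 - sse / syy, 0.0))) if syy > 0 else 0.0

    dof = n - 1
    s = np.sqrt(sse / dof)
    tq = stats.t.ppf(0.5 + ci / 2.0, dof)
    half_width = tq * s * np.sqrt(1.0 + x ** 2 / sxx)
    outliers = np.abs(resid) > half_width
    count = int(outliers.sum())
    return RegressionReport(
        slope=slope, r=r, r2=r * r, rmse=float(rmse), n=n,
        outlier_count=count, outlier_pct=100.0 * count / n,
        outlier_mask=outliers, r_uncentered=r_unc,
    )


def _stage_metrics(truth, labels, scores, classes) -> dict:
    n = len(truth)
    acc = float(np.mean(labels == truth)) * 100.0
    onehot = (truth[:, None] == classes[None, :]).astype(float)
    mse = float(np.mean((onehot - scores) ** 2))
    return {"n": n, "accuracy": acc, "error": 100.0 - acc, "mse": mse}


def classification_report(truth, labels, scores, classes=None,
                          stage_masks: dict = None) -> dict:
    """Staged classification metrics.

    Parameters
    ----------
    truth, labels : array-like of shape (n,)
        Reference and predicted class labels.
    scores : (n, k) array
        Softmax scores in class order; MSE is computed against one-hot
        encodings of the truth.
    classes : sequence, optional
        Class order of the score columns (defaults to sorted unique
        truth labels).
    stage_masks : dict of name -> boolean mask, optional
        e.g. ``{"training": ..., "testing": ...}``; an "overall" stage
        over all samples is always included.

    Returns a dict with per-stage accuracy/error/MSE, the overall
    confusion matrix (rows = truth), and per-class one-vs-rest ROC
    curves swept over the score threshold.
    """
    truth = np.asarray(truth)
    labels = np.asarray(labels)
    scores = np.atleast_2d(np.asarray(scores, float))
    if classes is None:
        classes = np.unique(truth)
    classes = np.asarray(classes)
    unknown = set(np.unique(labels)) | set(np.unique(truth))
    if not unknown.issubset(set(classes.tolist())):
        raise ValueError(f"unknown label(s) {sorted(unknown - set(classes.tolist()))}")
    if scores.shape != (truth.size, classes.size):
        raise ValueError("scores must be (n_samples, n_classes)")

    stages = {"overall": np.ones(truth.size, bool)}
    if stage_masks:
        stages = {**stage_masks, **stages}
    report = {"stages": {}, "classes": classes.tolist()}
    for name, mask in stages.items():
        mask = np.asarray(mask, bool)
        report["stages"][name] = _stage_metrics(
            truth[mask], labels[mask], scores[mask], classes)
    report["confusion"] = _confusion(truth, labels, labels=classes)
    roc = {}
    for j, c in enumerate(classes):
        fpr, tpr, _ = _roc((truth == c).astype(int), scores[:, j])
        roc[str(c)] = {"fpr": fpr.tolist(), "tpr": tpr.tolist()}
    report["roc"] = roc
    return report
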