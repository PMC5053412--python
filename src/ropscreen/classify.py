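"""Equal-prior linear discriminant classification with two-region fusion.

A two-class pooled-covariance linear discriminant is fit on the (T, S)
feature vector of each diagnostic region, evaluated by leave-one-out
cross-validation, and the per-region decisions are fused by the
precautionary rule: an eye is healthy only if *both* DR1 and EDR1 come
out healthy.  The fusion can only add positives, trading false positives
for sensitivity — the design goal of a screening tool where a missed case
costs sight.

`EqualPriorLDA` follows the scikit-learn estimator protocol (fit /
predict / decision_function, ``get_params``/``set_params``, fitted
attributes with a trailing underscore) and composes with sklearn model
selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.model_selection import LeaveOneOut
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

logger = logging.getLogger(__name__)

__all__ = [
    "EqualPriorLDA",
    "ClassificationResult",
    "fit_lda",
    "loocv",
    "fuse_regions",
    "classify_cohort",
]

POSITIVE = "aprop"
NEGATIVE = "healthy"


class EqualPriorLDA(BaseEstimator, ClassifierMixin):
    """Two-class linear discriminant with equal priors and symmetric cost.

    The decision boundary is the locus of equal Mahalanobis-to-mean
    scores under the pooled within-class covariance.  Features are
    z-scored from the training data before fitting (T and S live on very
    different scales); since LDA is affine-equivariant this changes no
    exact decision, only the conditioning.

    Parameters
    ----------
    ridge : float
        If the pooled covariance is singular (e.g. one sample per class),
        ``ridge * trace(cov)`` is added to its diagonal.
    standardize : bool
        Z-score features from the training set before fitting.

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
    means_ : ndarray of shape (2, n_features)
        Class means in standardized space.
    covariance_ : ndarray of shape (n_features, n_features)
        Pooled within-class covariance (after any ridge).
    coef_, intercept_ : linear decision function; positive scores go to
        ``classes_[1]``.
    regularized_ : bool
        Whether the ridge was applied.
    """

    def __init__(self, ridge: float = 1e-6, standardize: bool = True):
        self.ridge = ridge
        self.standardize = standardize

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=np.float64)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) != 2:
            raise ValueError("EqualPriorLDA is strictly two-class; got "
                             f"{len(self.classes_)} class(es)")
        if self.standardize:
            self.center_ = X.mean(axis=0)
            scale = X.std(axis=0)
            self.scale_ = np.where(scale > 0, scale, 1.0)
        else:
            self.center_ = np.zeros(X.shape[1])
            self.scale_ = np.ones(X.shape[1])
        Z = (X - self.center_) / self.scale_

        self.priors_ = np.array([0.5, 0.5])
        self.means_ = np.vstack([Z[y_idx == k].mean(axis=0) for k in (0, 1)])
        n0, n1 = np.bincount(y_idx, minlength=2)
        d = X.shape[1]
        cov = np.zeros((d, d))
        for k, nk in ((0, n0), (1, n1)):
            if nk > 1:
                cov += (nk - 1) * np.cov(Z[y_idx == k].T, ddof=1).reshape(d, d)
        dof = max(n0 + n1 - 2, 1)
        cov /= dof

        self.regularized_ = False
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            eps = self.ridge * max(np.trace(cov), 1.0)
            cov = cov + eps * np.eye(d)
            self.regularized_ = True
            logger.info("pooled covariance singular; ridge %.3g applied", eps)
            try:
                np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                cov = cov + np.eye(d)  # last resort: spherical fallback
        self.covariance_ = cov

        diff = self.means_[1] - self.means_[0]
        w = np.linalg.solve(cov, diff)
        self.coef_ = w.reshape(1, -1)
        self.intercept_ = np.array([-0.5 * (self.means_[0] + self.means_[1]) @ w])
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=np.float64)
        Z = (X - self.center_) / self.scale_
        return Z @ self.coef_.ravel() + self.intercept_[0]

    def predict(self, X):
        return self.classes_[(self.decision_function(X) > 0).astype(int)]


def fit_lda(X, y, ridge: float = 1e-6, standardize: bool = True) -> EqualPriorLDA:
    """Convenience wrapper: fit an :class:`EqualPriorLDA` and return it."""
    return EqualPriorLDA(ridge=ridge, standardize=standardize).fit(X, y)


@dataclass
class ClassificationResult:
    """LOOCV outcome with the diseased class as positive."""

    y_true: list
    y_pred: list
    tp: int = field(init=False)
    fp: int = field(init=False)
    tn: int = field(init=False)
    fn: int = field(init=False)

    def __post_init__(self) -> None:
        yt = np.asarray(self.y_true)
        yp = np.asarray(self.y_pred)
        self.tp = int(np.sum((yt == POSITIVE) & (yp == POSITIVE)))
        self.fp = int(np.sum((yt != POSITIVE) & (yp == POSITIVE)))
        self.tn = int(np.sum((yt != POSITIVE) & (yp != POSITIVE)))
        self.fn = int(np.sum((yt == POSITIVE) & (yp != POSITIVE)))

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def recall(self) -> float:
        """Sensitivity to the diseased class, percent."""
        denom = self.tp + self.fn
        return 100.0 * self.tp / denom if denom else float("nan")

    @property
    def precision(self) -> float:
        denom = self.tp + self.fp
        return 100.0 * self.tp / denom if denom else float("nan")

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.n if self.n else float("nan")

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
                "n": self.n, "recall": self.recall,
                "precision": self.precision, "accuracy": self.accuracy}


def loocv(X, y, estimator: EqualPriorLDA | None = None) -> ClassificationResult:
    """Leave-one-out cross-validation of the equal-prior discriminant.

    A fold whose training data collapses to a single class cannot fit a
    discriminant; the held-out sample is then scored as misclassified
    (logged), the conservative bookkeeping for a screening estimate.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if len(y) < 3:
        raise ValueError("leave-one-out needs at least 3 samples")
    base = estimator if estimator is not None else EqualPriorLDA()
    preds = []
    for train_idx, test_idx in LeaveOneOut().split(X):
        if len(np.unique(y[train_idx])) < 2:
            truth = y[test_idx][0]
            wrong = POSITIVE if truth != POSITIVE else NEGATIVE
            logger.warning("LOOCV fold with single-class training set; "
                           "held-out sample counted as error")
            preds.append(wrong)
            continue
        model = clone(base).fit(X[train_idx], y[train_idx])
        preds.append(model.predict(X[test_idx])[0])
    return ClassificationResult(y_true=list(y), y_pred=preds)


def fuse_regions(label_dr1: str | None, label_edr1: str | None) -> str:
    """Healthy only if both regions are healthy; missing labels are suspect."""
    if label_dr1 is None or label_edr1 is None:
        logger.warning("missing region label; classifying as %s by precaution",
                       POSITIVE)
        return POSITIVE
    if label_dr1 == NEGATIVE and label_edr1 == NEGATIVE:
        return NEGATIVE
    return POSITIVE


def classify_cohort(features: pd.DataFrame,
                    regions: tuple[str, str] = ("DR1", "EDR1"),
                    estimator: EqualPriorLDA | None = None) -> dict:
    """Per-region LOOCV plus fused decision for a cohort feature table.

    ``features`` is the canonical table (image_id, label, region, T, S,
    ...).  Images with an undefined T in a region are excluded from that
    region's fitting and fall back to the suspect label at fusion; their
    count is reported as ``n_missing``.

    Returns a report dict with per-region confusion/recall/precision, the
    fused result, and the boundary coefficients of the full-cohort fits.
    """
    per_region: dict[str, dict] = {}
    region_pred: dict[str, dict[str, str]] = {}
    image_ids = list(dict.fromkeys(features["image_id"]))
    labels = {r.image_id: r.label for r in features.itertuples()}

    for region in regions:
        sub = features[features["region"] == region]
        fit_rows = sub[np.isfinite(sub["T"])]
        missing = [r.image_id for r in sub.itertuples() if not np.isfinite(r.T)]
        X = fit_rows[["T", "S"]].to_numpy(dtype=float)
        y = fit_rows["label"].to_numpy()
        res = loocv(X, y, estimator=estimator)
        model = (estimator or EqualPriorLDA())
        model = clone(model).fit(X, y)
        region_pred[region] = dict(zip(fit_rows["image_id"], res.y_pred))
        per_region[region] = {
            **res.as_dict(),
            "n_missing": len(missing),
            "boundary": {"coef": model.coef_.ravel().tolist(),
                         "intercept": float(model.intercept_[0])},
        }

    fused_pred, fused_true = [], []
    for img in image_ids:
        fused_pred.append(fuse_regions(region_pred[regions[0]].get(img),
                                       region_pred[regions[1]].get(img)))
        fused_true.append(labels[img])
    fused = ClassificationResult(y_true=fused_true, y_pred=fused_pred)

    return {
        "regions": per_region,
        "fused": fused.as_dict(),
        "predictions": dict(zip(image_ids, fused_pred)),
        "n_images": len(image_ids),
    }
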