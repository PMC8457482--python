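"""Predictive-power assessment for fitted conflict models.

AUC is computed by the rank (Mann–Whitney) formulation: the probability that a
random used point outscores a random available point, with ties counting one
half. The classification threshold is the equal-sensitivity/specificity cut:
among candidate thresholds (every distinct score plus the midpoints between
consecutive distinct scores) the one minimising |sensitivity - specificity|,
ties resolved to the lowest threshold. The decision convention is fixed
throughout: a location is called "conflict" when its score is >= the
threshold, so conflict omission is the fraction of used points scoring
strictly below it and non-conflict omission the fraction of available points
scoring at or above it. "Overall" omission is reported two ways — the pooled
misclassified fraction and the unweighted mean of the two class rates —
because the two definitions genuinely differ on imbalanced samples.

Two split designs are provided: a spatial holdout (train outside a focal
region, test inside — the design used to justify fitting statewide and
predicting regionally) and stratified k-fold cross-validation. Thresholds are
always derived on training data and applied to test data; deriving them on
the test side would leak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .raster import GridRaster
from .rspf import DesignMatrix, eval_w, fit_rspf

logger = logging.getLogger(__name__)

__all__ = ["SplitSpec", "ValidationReport", "roc_auc", "equal_ss_threshold",
           "omission_errors", "spatial_holdout", "kfold_cv", "robustness_check"]


@dataclass(frozen=True)
class SplitSpec:
    """Validation design: spatial holdout on a focal region, or k-fold."""

    mode: str = "kfold"  # "spatial_holdout" | "kfold"
    k: int = 5
    focal_mask: GridRaster | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("spatial_holdout", "kfold"):
            raise ValueError(f"unknown split mode {self.mode!r}")
        if self.mode == "kfold" and self.k < 2:
            raise ValueError("k-fold needs k >= 2")
        if self.mode == "spatial_holdout" and self.focal_mask is None:
            raise ValueError("spatial holdout needs a focal mask")


@dataclass
class ValidationReport:
    """AUC, threshold and omission errors for one validation design."""

    auc: float
    threshold: float
    omission_conflict: float
    omission_nonconflict: float
    overall_omission_mean: float
    overall_omission_pooled: float
    n_train: dict[str, int] = field(default_factory=dict)
    n_test: dict[str, int] = field(default_factory=dict)
    per_fold: pd.DataFrame | None = None
    passed: bool | None = None

    def to_dict(self) -> dict:
        out = {
            "auc": self.auc, "threshold": self.threshold,
            "omission_conflict": self.omission_conflict,
            "omission_nonconflict": self.omission_nonconflict,
            "overall_omission_mean": self.overall_omission_mean,
            "overall_omission_pooled": self.overall_omission_pooled,
            "n_train": self.n_train, "n_test": self.n_test,
            "passed": self.passed,
        }
        if self.per_fold is not None:
            out["per_fold"] = self.per_fold.to_dict(orient="records")
        return out


def _check_two_classes(labels: np.ndarray) -> None:
    if not ((labels == 1).any() and (labels == 0).any()):
        raise ValueError("both classes must be present")


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve via mid-ranks (ties contribute 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    ranks = rankdata(scores)  # average ranks handle ties exactly
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    s = np.unique(scores)
    if s.size == 1:
        return s
    mids = (s[:-1] + s[1:]) / 2.0
    return np.unique(np.concatenate([s, mids]))


def equal_ss_threshold(scores, labels) -> float:
    """Score cut where sensitivity and specificity are as close as possible.

    Candidates are every distinct score and the midpoints between consecutive
    distinct scores; the lowest minimiser of |sens - spec| wins.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    pos = np.sort(scores[labels == 1])
    neg = np.sort(scores[labels == 0])
    cands = _candidate_thresholds(scores)
    # sens = P(pos >= t), spec = P(neg < t); vectorised via searchsorted
    sens = 1.0 - np.searchsorted(pos, cands, side="left") / pos.size
    spec = np.searchsorted(neg, cands, side="left") / neg.size
    gap = np.abs(sens - spec)
    return float(cands[int(np.argmin(gap))])  # argmin takes the first (lowest)


def omission_errors(scores, labels, threshold: float) -> tuple[float, float, dict]:
    """Class-wise and overall omission at a threshold.

    Returns (conflict_omission, nonconflict_omission, overall) where overall
    carries both definitions: ``{"mean": ..., "pooled": ...}``.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    used = scores[labels == 1]
    avail = scores[labels == 0]
    conflict_om = float((used < threshold).mean()) if used.size else 0.0
    nonconflict_om = float((avail >= threshold).mean()) if avail.size else 0.0
    n_wrong = (used < threshold).sum() + (avail >= threshold).sum()
    overall = {
        "mean": (conflict_om + nonconflict_om) / 2.0,
        "pooled": float(n_wrong / max(scores.size, 1)),
    }
    return conflict_om, nonconflict_om, overall


def _score(fit, X: np.ndarray) -> np.ndarray:
    return eval_w(fit.beta, X)


def focal_membership(points: pd.DataFrame, focal_mask: GridRaster) -> np.ndarray:
    """Boolean array: True where a point's containing cell is in the focal region."""
    grid = focal_mask.grid
    x = points["x"].to_numpy(dtype=float)
    y = points["y"].to_numpy(dtype=float)
    row, col = grid.xy_to_rowcol(x, y)
    ok = (row >= 0) & (row < grid.n_rows) & (col >= 0) & (col < grid.n_cols)
    inside = np.zeros(len(points), dtype=bool)
    inside[ok] = focal_mask.values.astype(bool)[row[ok], col[ok]]
    return inside


def subset_rows(data: DesignMatrix, keep: np.ndarray) -> DesignMatrix:
    """Row subset of a design (same columns and encoding)."""
    return DesignMatrix(data.X[keep], data.labels[keep], data.column_names,
                        data.reference_class)


def spatial_holdout(points: pd.DataFrame, focal_mask: GridRaster
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split points into train (outside the focal region) and test (inside)."""
    if not focal_mask.values.astype(bool).any():
        raise ValueError("focal mask is empty")
    inside = focal_membership(points, focal_mask)
    train = points.loc[~inside].reset_index(drop=True)
    test = points.loc[inside].reset_index(drop=True)
    if len(train) == 0 or len(test) == 0:
        raise ValueError("spatial holdout produced an empty side")
    for name, side in (("train", train), ("test", test)):
        counts = side["label"].value_counts()
        logger.info("spatial_holdout %s: used=%d available=%d", name,
                    counts.get(1, 0), counts.get(0, 0))
        if counts.get(1, 0) == 0 or counts.get(0, 0) == 0:
            logger.warning("spatial_holdout: %s side is single-class", name)
    return train, test


def evaluate_split(train: DesignMatrix, test: DesignMatrix,
                   seed: int | None = None) -> ValidationReport:
    """Fit on train (bootstrap off), threshold on train, score test."""
    fit = fit_rspf(train, B=0, seed=seed, on_separation="flag")
    thr = equal_ss_threshold(_score(fit, train.X), train.labels)
    scores = _score(fit, test.X)
    auc = roc_auc(scores, test.labels)
    c_om, n_om, overall = omission_errors(scores, test.labels, thr)
    return ValidationReport(
        auc=auc, threshold=thr, omission_conflict=c_om,
        omission_nonconflict=n_om, overall_omission_mean=overall["mean"],
        overall_omission_pooled=overall["pooled"],
        n_train={"used": train.n_used, "available": train.n_avail},
        n_test={"used": test.n_used, "available": test.n_avail},
    )


def kfold_cv(data: DesignMatrix, k: int = 5, seed: int | None = None) -> ValidationReport:
    """Stratified k-fold cross-validation of the (already selected) model.

    Each fold serves as the test set once; the model is refit on the other
    k - 1 folds with the bootstrap off. Per-fold rows report the training
    AIC, the test AUC and the test omission errors at the train-derived
    equal-sensitivity/specificity threshold.
    """
    labels = data.labels
    _check_two_classes(labels)
    if k > min(int(labels.sum()), int((labels == 0).sum())):
        raise ValueError("k exceeds the size of a class")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rows = []
    all_scores = np.empty(labels.size)
    all_thr = []
    for fold, (itr, ite) in enumerate(skf.split(data.X, labels), start=1):
        train = DesignMatrix(data.X[itr], labels[itr], data.column_names,
                             data.reference_class)
        fit = fit_rspf(train, B=0, seed=seed, on_separation="flag")
        thr = equal_ss_threshold(_score(fit, train.X), train.labels)
        scores = _score(fit, data.X[ite])
        all_scores[ite] = scores
        all_thr.append(thr)
        auc = roc_auc(scores, labels[ite])
        c_om, n_om, overall = omission_errors(scores, labels[ite], thr)
        rows.append({"fold": fold, "aic": fit.aic, "auc": auc,
                     "omission_conflict": c_om, "omission_nonconflict": n_om,
                     "overall_omission_mean": overall["mean"],
                     "overall_omission_pooled": overall["pooled"]})
    per_fold = pd.DataFrame(rows)
    pooled_auc = roc_auc(all_scores, labels)
    thr = float(np.mean(all_thr))
    c_om, n_om, overall = omission_errors(all_scores, labels, thr)
    return ValidationReport(
        auc=pooled_auc, threshold=thr, omission_conflict=c_om,
        omission_nonconflict=n_om, overall_omission_mean=overall["mean"],
        overall_omission_pooled=overall["pooled"],
        n_train={"used": int(labels.sum()), "available": int((labels == 0).sum())},
        n_test={"used": int(labels.sum()), "available": int((labels == 0).sum())},
        per_fold=per_fold,
    )


def robustness_check(report: ValidationReport, min_auc: float = 0.7,
                     max_overall_omission: float = 0.3,
                     overall: str = "mean") -> ValidationReport:
    """Apply the configurable robustness gate (AUC and overall omission)."""
    om = (report.overall_omission_mean if overall == "mean"
          else report.overall_omission_pooled)
    report.passed = bool(report.auc > min_auc and om < max_overall_omission)
    return report
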