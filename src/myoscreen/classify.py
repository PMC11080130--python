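"""Sensitivity-weighted soft-voting ensemble under subject-level 5-fold CV.

Three members — a linear-kernel SVM (Platt-calibrated probabilities), a
200-tree random forest, and a gradient boosting machine — are combined by
weighted soft voting:

    y_hat = argmax_j  sum_i w_i P_ij      (j = 0 healthy, 1 sarcopenic)

The weights are grid-searched over {0, 0.1, ..., 1}^3 \\ {0,0,0} to maximize
inner-cross-validated sensitivity on the training folds (ties broken by
higher specificity, then by the lexicographically smallest weight vector).
Evaluation uses class-balanced subject-level five-fold cross-validation with
accuracy, sensitivity, specificity, F1, pooled ROC/AUC, and the optimal
operating point (maximal sensitivity subject to specificity > 0.65, the
screening-oriented rule). Ties in the vote resolve to the sarcopenic class.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_predict
from sklearn.svm import SVC

POSITIVE = 1   # sarcopenic
DEFAULT_WEIGHT_GRID = tuple(np.round(np.arange(0.0, 1.01, 0.1), 1))
SPECIFICITY_FLOOR = 0.65


@dataclass(frozen=True)
class EnsembleSpec:
    """Member hyperparameter grids and ensemble search settings."""

    svm_c_grid: tuple[float, ...] = (0.1, 1.0, 10.0)
    rf_n_estimators: int = 200
    rf_depth_grid: tuple = (3, 5, None)
    gbm_learning_rate_grid: tuple[float, ...] = (0.05, 0.1)
    gbm_n_estimators: int = 200
    gbm_depth: int = 3
    weight_grid: tuple[float, ...] = DEFAULT_WEIGHT_GRID
    inner_folds: int = 3
    svm_calibration_folds: int = 3
    seed: int = 0


@dataclass
class CVReport:
    """Per-fold and aggregate metrics of one cross-validation run."""

    fold_metrics: pd.DataFrame          # fold, accuracy, sensitivity, ...
    mean: dict[str, float]
    sd: dict[str, float]
    roc: pd.DataFrame                   # threshold, fpr, tpr
    auc: float
    oop: dict[str, float] | None        # threshold, sensitivity, specificity
    weights: list[np.ndarray]           # chosen voting weights per fold
    pooled_scores: np.ndarray = field(default_factory=lambda: np.empty(0))
    pooled_labels: np.ndarray = field(default_factory=lambda: np.empty(0))


def make_folds(labels: np.ndarray, k: int = 5, seed: int = 0) -> np.ndarray:
    """Class-balanced subject-level partition into ``k`` folds.

    Within every fold the two class counts differ by at most one. Each class
    is shuffled and chunked near-equally; the larger chunks of one class are
    paired with the smaller chunks of the other to even out fold sizes.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    for c in classes:
        if np.sum(labels == c) < k:
            raise ValueError(f"class {c!r} has fewer than {k} subjects")
    fold_of = np.empty(labels.size, dtype=int)
    chunk_orders = []
    for c in classes:
        idx = rng.permutation(np.flatnonzero(labels == c))
        chunks = np.array_split(idx, k)
        chunk_orders.append(chunks)
    # array_split puts the larger chunks first; reverse the second class so
    # large pairs with small and fold sizes stay near-equal
    a_chunks, b_chunks = chunk_orders[0], list(reversed(chunk_orders[1]))
    for f, (ca, cb) in enumerate(zip(a_chunks, b_chunks)):
        if abs(len(ca) - len(cb)) > 1:
            raise ValueError("cannot balance classes within folds")
        fold_of[ca] = f
        fold_of[cb] = f
    return fold_of


def _members(spec: EnsembleSpec):
    inner = StratifiedKFold(spec.inner_folds, shuffle=True, random_state=spec.seed)
    # linear SVM with Platt-scaled probabilities calibrated on inner folds
    svm = GridSearchCV(
        CalibratedClassifierCV(SVC(kernel="linear", random_state=spec.seed),
                               method="sigmoid", cv=spec.svm_calibration_folds,
                               ensemble=False),
        {"estimator__C": list(spec.svm_c_grid)}, cv=inner)
    rf = GridSearchCV(
        RandomForestClassifier(n_estimators=spec.rf_n_estimators,
                               random_state=spec.seed),
        {"max_depth": list(spec.rf_depth_grid)}, cv=inner)
    gbm = GridSearchCV(
        GradientBoostingClassifier(n_estimators=spec.gbm_n_estimators,
                                   max_depth=spec.gbm_depth,
                                   random_state=spec.seed),
        {"learning_rate": list(spec.gbm_learning_rate_grid)}, cv=inner)
    return [svm, rf, gbm]


def fit_members(x_train: np.ndarray, y_train: np.ndarray, spec: EnsembleSpec):
    """Grid-search and fit the three members on the training subjects only."""
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set contains a single class")
    members = _members(spec)
    for m in members:
        m.fit(x_train, y_train)
    return members


def _prob_positive(member, x: np.ndarray) -> np.ndarray:
    proba = member.predict_proba(x)
    cls = list(member.classes_)
    return proba[:, cls.index(POSITIVE)]


def search_weights(members, x_train: np.ndarray, y_train: np.ndarray,
                   spec: EnsembleSpec) -> np.ndarray:
    """Exhaustive weight search maximizing inner-CV sensitivity.

    Member probabilities are re-estimated out-of-fold on the training set so
    the objective never sees a member's in-sample fit; ties break toward
    higher specificity, then the lexicographically smallest weight vector.
    Returns weights normalized to sum 1.
    """
    inner = StratifiedKFold(spec.inner_folds, shuffle=True, random_state=spec.seed)
    pos_col = int(np.searchsorted(np.unique(y_train), POSITIVE))
    p_oof = np.column_stack([
        cross_val_predict(clone(m.best_estimator_ if isinstance(m, GridSearchCV) else m),
                          x_train, y_train, cv=inner,
                          method="predict_proba")[:, pos_col]
        for m in members
    ])
    pos = y_train == POSITIVE
    best = None
    for w in itertools.product(spec.weight_grid, repeat=len(members)):
        if not any(w):
            continue
        wv = np.asarray(w)
        score = p_oof @ wv / wv.sum()
        pred = score >= 0.5                       # tie votes sarcopenic
        sens = np.mean(pred[pos]) if pos.any() else np.nan
        specif = np.mean(~pred[~pos]) if (~pos).any() else np.nan
        key = (sens, specif, tuple(-v for v in w))
        if best is None or key > best[0]:
            best = (key, wv)
    wv = best[1]
    return wv / wv.sum()


def soft_vote(members, weights: np.ndarray, x: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray]:
    """Weighted soft vote: normalized positive-class score and hard label.

    With members emitting complementary two-class probabilities the argmax of
    the weighted class sums reduces to thresholding the normalized positive
    score at 0.5; exact ties resolve to the sarcopenic class.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.sum() <= 0 or np.any(weights < 0):
        raise ValueError("weights must be non-negative and not all zero")
    p1 = np.column_stack([_prob_positive(m, x) for m in members])
    score = p1 @ weights / weights.sum()
    label = (score >= 0.5).astype(int)
    return score, label


def metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, F1 with sarcopenic as positive."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    out = {"accuracy": (tp + tn) / max(len(y_true), 1)}
    out["sensitivity"] = tp / (tp + fn) if tp + fn else float("nan")
    out["specificity"] = tn / (tn + fp) if tn + fp else float("nan")
    out["f1"] = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else float("nan")
    return out


def roc_auc(scores: np.ndarray, labels: np.ndarray
            ) -> tuple[pd.DataFrame, float]:
    """ROC over the distinct score thresholds and trapezoidal AUC.

    The AUC so computed equals the tie-averaged pairwise ranking probability
    (the normalized Mann-Whitney U statistic)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    if np.ptp(scores) == 0:
        warnings.warn("constant scores: AUC defaults to 0.5", stacklevel=2)
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    rows = []
    for thr in thresholds:
        pred = scores >= thr
        tpr = np.sum(pred & (labels == 1)) / n_pos
        fpr = np.sum(pred & (labels == 0)) / n_neg
        rows.append((thr, fpr, tpr))
    roc = pd.DataFrame(rows, columns=["threshold", "fpr", "tpr"])
    auc = float(np.trapezoid(roc["tpr"], roc["fpr"]))
    return roc, auc


def select_oop(roc: pd.DataFrame, spec_floor: float = SPECIFICITY_FLOOR
               ) -> dict[str, float]:
    """Optimal operating point: maximal sensitivity with specificity above the
    floor; ties prefer the higher specificity."""
    if roc.empty:
        raise ValueError("empty ROC")
    spec = 1.0 - roc["fpr"].to_numpy()
    ok = spec > spec_floor
    if not ok.any():
        raise ValueError(
            f"no operating point with specificity > {spec_floor}; "
            f"best achievable is {spec.max():.3f}")
    cand = roc.loc[ok].assign(specificity=spec[ok])
    cand = cand.sort_values(["tpr", "specificity"], ascending=False)
    row = cand.iloc[0]
    return {"threshold": float(row["threshold"]),
            "sensitivity": float(row["tpr"]),
            "specificity": float(row["specificity"])}


def cross_validate(x: np.ndarray, y: np.ndarray, spec: EnsembleSpec | None = None,
                   k: int = 5, seed: int = 0) -> CVReport:
    """Subject-level k-fold CV of the weighted voting ensemble.

    Member fitting, hyperparameter search, and weight search all see only the
    k-1 training folds; the held-out fold is scored once. Pooled held-out
    scores feed the ROC/AUC and the operating-point rule.
    """
    spec = spec or EnsembleSpec(seed=seed)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    fold_of = make_folds(y, k=k, seed=seed)
    rows, weights_per_fold = [], []
    pooled_scores = np.empty(y.size)
    for f in range(k):
        test = fold_of == f
        if len(np.unique(y[test])) < 2:
            raise ValueError(f"fold {f} contains a single class")
        members = fit_members(x[~test], y[~test], spec)
        w = search_weights(members, x[~test], y[~test], spec)
        score, pred = soft_vote(members, w, x[test])
        pooled_scores[test] = score
        m = metrics(y[test], pred)
        m["fold"] = f
        rows.append(m)
        weights_per_fold.append(w)
    fold_df = pd.DataFrame(rows).set_index("fold")
    roc, auc = roc_auc(pooled_scores, y)
    try:
        oop = select_oop(roc)
    except ValueError:
        oop = None
    return CVReport(
        fold_metrics=fold_df,
        mean={c: float(fold_df[c].mean()) for c in fold_df.columns},
        sd={c: float(fold_df[c].std(ddof=1)) for c in fold_df.columns},
        roc=roc, auc=auc, oop=oop, weights=weights_per_fold,
        pooled_scores=pooled_scores, pooled_labels=y.copy(),
    )
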