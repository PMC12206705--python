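"""Classification and explainability stage.

Pipeline: stratified hold-out split → (training side only) median
imputation, Bayesian hyperparameter tuning of an XGBoost classifier scored
by 3-fold stratified cross-validation with SMOTE applied *inside* each
training fold, mean-|SHAP| feature importance computed on the original
(non-oversampled) training data, threshold/scan feature selection →
final model trained on SMOTE-balanced selected features → evaluation on the
untouched hold-out (per-class precision/recall/specificity/F1/Fβ, accuracy
with stratified-bootstrap CI, macro one-vs-rest ROC–AUC) plus per-sample
signed SHAP attributions.

SMOTE synthesizes minority samples as convex combinations of a minority
point and one of its k nearest minority neighbors; it is always fitted on
training partitions only, so no synthetic sample can leak into any
evaluation partition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.metrics import roc_auc_score
from sklearn.neighbors import NearestNeighbors

from .optimize import ParamRange, bayes_optimize

logger = logging.getLogger(__name__)

_seen_warnings: set = set()


def _warn_once(key, message: str) -> None:
    """Log a warning the first time ``key`` occurs (repeats go to DEBUG)."""
    if key in _seen_warnings:
        logger.debug(message)
    else:
        _seen_warnings.add(key)
        logger.warning(message)

__all__ = [
    "ModelConfig",
    "DEFAULT_HYPERPARAMETER_SPACE",
    "smote_upsample",
    "FoldResult",
    "cv_with_infold_smote",
    "tune_hyperparameters",
    "mean_abs_shap",
    "select_features",
    "ReportMetrics",
    "classification_report_from_confusion",
    "ClassifierReport",
    "evaluate_holdout",
    "shap_contribution_table",
    "direction_summary",
    "SpeechMarkerClassifier",
    "DEFAULT_CLASS_ORDER",
]

DEFAULT_CLASS_ORDER = ("NAR", "AR", "FEP")

#: search ranges for the gradient-boosted trees (declared here; not taken
#: from any published protocol, which leaves the space unreported)
DEFAULT_HYPERPARAMETER_SPACE: dict[str, ParamRange] = {
    "max_depth": ParamRange(2, 6, "int"),
    "learning_rate": ParamRange(0.03, 0.3, "logfloat"),
    "n_estimators": ParamRange(50, 300, "int"),
    "subsample": ParamRange(0.6, 1.0, "float"),
    "colsample_bytree": ParamRange(0.5, 1.0, "float"),
    "min_child_weight": ParamRange(1.0, 5.0, "float"),
}

DEFAULT_XGB_PARAMS = {
    "max_depth": 3,
    "learning_rate": 0.1,
    "n_estimators": 150,
    "subsample": 0.9,
    "colsample_bytree": 0.9,
    "min_child_weight": 1.0,
}


@dataclass(frozen=True)
class ModelConfig:
    k_folds: int = 3
    test_fraction: float = 0.3
    smote_k_neighbors: int = 5
    bayes_opt_iterations: int = 15
    hyperparameter_space: Mapping[str, ParamRange] = field(
        default_factory=lambda: dict(DEFAULT_HYPERPARAMETER_SPACE)
    )
    shap_threshold: float = 0.3
    selection: str = "threshold"  # or "scan"
    scan_top_n: int = 10
    fbeta_beta: float = 2.0
    bootstrap_reps: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.selection not in ("threshold", "scan"):
            raise ValueError("selection must be 'threshold' or 'scan'")
        if not self.hyperparameter_space:
            raise ValueError("hyperparameter_space must be non-empty")


def _make_xgb(params: Mapping, seed: int) -> xgb.XGBClassifier:
    return xgb.XGBClassifier(
        **{k: params[k] for k in DEFAULT_XGB_PARAMS if k in params},
        objective="multi:softprob",
        eval_metric="mlogloss",
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
    )


def smote_upsample(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Balance all classes to the majority count by SMOTE interpolation.

    Each synthetic sample is ``x_i + u (x_nn − x_i)`` with ``u ~ U[0, 1]``
    between a minority sample and one of its ``k_neighbors`` nearest
    neighbors within the same class.  ``k_neighbors`` is clipped (with a
    warning) to ``minority size − 1``; a single-sample class is an error.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.isnan(X).any():
        raise ValueError("X contains NaN; impute before oversampling")
    classes, counts = np.unique(y, return_counts=True)
    n_max = counts.max()
    rng = np.random.default_rng(seed)
    X_out, y_out = [X], [y]
    for cls, count in zip(classes, counts):
        n_new = n_max - count
        if n_new == 0:
            continue
        if count < 2:
            raise ValueError(
                f"class {cls!r} has a single sample; SMOTE needs >= 2 — "
                "use a smaller k_folds or a larger cohort"
            )
        k = min(k_neighbors, count - 1)
        if k < k_neighbors:
            _warn_once(
                ("smote_clip", int(k_neighbors), int(k)),
                f"k_neighbors clipped from {k_neighbors} to {k} for class {cls!r}",
            )
        Xc = X[y == cls]
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
        _, idx = nn.kneighbors(Xc)  # column 0 is the point itself
        base = rng.integers(0, count, size=n_new)
        pick = rng.integers(1, k + 1, size=n_new)
        u = rng.random(n_new)
        neigh = idx[base, pick]
        synth = Xc[base] + u[:, None] * (Xc[neigh] - Xc[base])
        X_out.append(synth)
        y_out.append(np.full(n_new, cls, dtype=y.dtype))
    return np.concatenate(X_out), np.concatenate(y_out)


def _median_impute(train: np.ndarray, *others: np.ndarray):
    """Column medians from the training block, applied to every block."""
    med = np.nanmedian(train, axis=0)
    med = np.where(np.isnan(med), 0.0, med)

    def apply(a: np.ndarray) -> np.ndarray:
        a = np.array(a, dtype=float)
        mask = np.isnan(a)
        if mask.any():
            a[mask] = np.broadcast_to(med, a.shape)[mask]
        return a

    return (apply(train), *map(apply, others), med)


@dataclass(frozen=True)
class FoldResult:
    accuracy: float
    train_indices: np.ndarray
    val_indices: np.ndarray
    n_train_after_smote: int


def cv_with_infold_smote(
    X: np.ndarray,
    y: np.ndarray,
    params: Mapping,
    config: ModelConfig,
    encoder: Mapping | None = None,
) -> list[FoldResult]:
    """Stratified k-fold CV with imputation and SMOTE fitted per training fold.

    The validation partition of each fold is left untouched (no synthetic
    samples, imputation statistics from the training side only).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < config.k_folds:
        raise ValueError(
            f"stratification infeasible: smallest class has {counts.min()} "
            f"members for k_folds={config.k_folds}"
        )
    if encoder is None:
        encoder = {c: i for i, c in enumerate(classes)}
    y_enc = np.array([encoder[v] for v in y])
    skf = StratifiedKFold(
        n_splits=config.k_folds, shuffle=True, random_state=config.seed
    )
    results = []
    for fold, (tr, va) in enumerate(skf.split(X, y_enc)):
        X_tr, X_va, _ = _median_impute(X[tr], X[va])
        X_res, y_res = smote_upsample(
            X_tr, y_enc[tr], config.smote_k_neighbors, seed=config.seed + fold
        )
        clf = _make_xgb(params, seed=config.seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(X_res, y_res)
        acc = float(np.mean(clf.predict(X_va) == y_enc[va]))
        results.append(FoldResult(acc, tr, va, len(y_res)))
    return results


def tune_hyperparameters(
    X: np.ndarray, y: np.ndarray, config: ModelConfig
) -> tuple[dict, float]:
    """Bayesian optimization of mean CV accuracy; returns (params, score)."""

    def objective(params: dict) -> float:
        folds = cv_with_infold_smote(X, y, params, config)
        return float(np.mean([f.accuracy for f in folds]))

    best, score, _ = bayes_optimize(
        objective,
        config.hyperparameter_space,
        n_iter=config.bayes_opt_iterations,
        seed=config.seed,
    )
    return best, score


def mean_abs_shap(
    model: xgb.XGBClassifier, X, feature_names: Sequence[str] | None = None
) -> pd.Series:
    """Mean absolute SHAP value per feature (TreeSHAP attributions).

    Attributions are averaged over samples and, for multiclass models, over
    classes.  The per-sample attributions plus the base value reproduce the
    model's margin output (local accuracy).
    """
    if feature_names is None and isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
    X_arr = np.asarray(X, dtype=float)
    booster = model.get_booster()
    if feature_names is not None and X_arr.shape[1] != len(feature_names):
        raise ValueError("feature_names length does not match X")
    contribs = booster.predict(xgb.DMatrix(X_arr), pred_contribs=True)
    # multiclass: (n, classes, features + bias); binary: (n, features + bias)
    abs_c = np.abs(contribs[..., :-1])
    imp = abs_c.mean(axis=tuple(range(abs_c.ndim - 1)))
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(len(imp))]
    return pd.Series(imp, index=list(feature_names), name="mean_abs_shap")


def select_features(
    importances: pd.Series,
    config: ModelConfig,
    cv_data: tuple[np.ndarray, np.ndarray] | None = None,
) -> list[str]:
    """Choose features from a mean-|SHAP| importance table.

    ``threshold`` mode keeps features with importance > ``shap_threshold``
    (falling back to the top-1 with a warning if none qualify).  ``scan``
    mode evaluates CV accuracy with the top-m features for
    m = 1..``scan_top_n`` and keeps the best m (ties go to the smaller m);
    it requires ``cv_data = (X, y)`` aligned with ``importances.index``.
    """
    if importances.empty:
        raise ValueError("empty importance table")
    ranked = importances.sort_values(ascending=False, kind="stable")
    if config.selection == "threshold" or cv_data is None:
        chosen = list(ranked.index[ranked.to_numpy() > config.shap_threshold])
        if not chosen:
            warnings.warn(
                "no feature exceeds the SHAP threshold; falling back to top-1"
            )
            chosen = [ranked.index[0]]
        if config.selection == "scan" and cv_data is None:
            raise ValueError("scan mode needs cv_data=(X, y)")
        return chosen
    X, y = cv_data
    X = np.asarray(X, dtype=float)
    names = list(importances.index)
    best_m, best_acc = 1, -np.inf
    top_n = min(config.scan_top_n, len(ranked))
    for m in range(1, top_n + 1):
        cols = [names.index(f) for f in ranked.index[:m]]
        folds = cv_with_infold_smote(X[:, cols], y, DEFAULT_XGB_PARAMS, config)
        acc = float(np.mean([f.accuracy for f in folds]))
        if acc > best_acc:  # strict: ties keep the smaller m
            best_m, best_acc = m, acc
    return list(ranked.index[:best_m])


# ---------------------------------------------------------------------------
# metrics


@dataclass(frozen=True)
class ReportMetrics:
    class_names: tuple[str, ...]
    confusion_matrix: np.ndarray
    precision: dict
    recall: dict
    specificity: dict
    f1: dict
    fbeta: dict
    support: dict
    accuracy: float
    macro: dict
    weighted: dict

    def to_frame(self) -> pd.DataFrame:
        rows = {
            c: {
                "precision": self.precision[c],
                "recall": self.recall[c],
                "specificity": self.specificity[c],
                "f1": self.f1[c],
                "fbeta": self.fbeta[c],
                "support": self.support[c],
            }
            for c in self.class_names
        }
        df = pd.DataFrame(rows).T
        df.loc["macro"] = {**self.macro, "support": sum(self.support.values())}
        df.loc["weighted"] = {**self.weighted, "support": sum(self.support.values())}
        return df


def _fscore(p: float, r: float, beta: float) -> float:
    if np.isnan(p) or np.isnan(r) or (p == 0 and r == 0):
        return 0.0 if not (np.isnan(p) or np.isnan(r)) else np.nan
    b2 = beta * beta
    return (1 + b2) * p * r / (b2 * p + r)


def classification_report_from_confusion(
    cm: np.ndarray,
    class_names: Sequence[str] = DEFAULT_CLASS_ORDER,
    beta: float = 2.0,
) -> ReportMetrics:
    """Per-class and aggregate metrics from a confusion matrix.

    Rows are true classes, columns predicted.  Precision is NaN for a class
    never predicted; macro averages skip NaN entries, weighted averages are
    support-weighted.
    """
    cm = np.asarray(cm, dtype=float)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (cm < 0).any():
        raise ValueError("confusion matrix counts must be non-negative")
    if cm.shape[0] != len(class_names):
        raise ValueError("class_names length mismatch")
    total = cm.sum()
    if total == 0 or (cm.sum(axis=1) == 0).any():
        raise ValueError("every true class needs at least one observation")
    precision, recall, specificity, f1, fbeta, support = {}, {}, {}, {}, {}, {}
    for i, c in enumerate(class_names):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp
        precision[c] = tp / (tp + fp) if (tp + fp) > 0 else np.nan
        recall[c] = tp / (tp + fn)
        specificity[c] = tn / (tn + fp) if (tn + fp) > 0 else np.nan
        f1[c] = _fscore(precision[c], recall[c], 1.0)
        fbeta[c] = _fscore(precision[c], recall[c], beta)
        support[c] = int(cm[i].sum())
    weights = np.array([support[c] for c in class_names], dtype=float)
    weights /= weights.sum()

    def agg(d: dict) -> tuple[float, float]:
        vals = np.array([d[c] for c in class_names], dtype=float)
        macro = float(np.nanmean(vals))
        wvals = np.where(np.isnan(vals), 0.0, vals)
        return macro, float(np.sum(weights * wvals))

    macro, weighted = {}, {}
    for name, d in (
        ("precision", precision),
        ("recall", recall),
        ("specificity", specificity),
        ("f1", f1),
        ("fbeta", fbeta),
    ):
        macro[name], weighted[name] = agg(d)
    return ReportMetrics(
        class_names=tuple(class_names),
        confusion_matrix=cm.astype(int),
        precision=precision,
        recall=recall,
        specificity=specificity,
        f1=f1,
        fbeta=fbeta,
        support=support,
        accuracy=float(np.trace(cm) / total),
        macro=macro,
        weighted=weighted,
    )


# ---------------------------------------------------------------------------
# estimator


class SpeechMarkerClassifier(ClassifierMixin, BaseEstimator):
    """XGBoost pipeline with in-fold SMOTE, tuning and SHAP feature selection.

    ``fit`` runs, on the training data only: median imputation → Bayesian
    hyperparameter tuning scored by stratified CV with in-fold SMOTE →
    mean-|SHAP| importances from a model trained on the original (non-SMOTE)
    data → threshold/scan feature selection → final model on SMOTE-balanced
    selected features.

    Fitted attributes: ``classes_``, ``feature_names_``, ``medians_``,
    ``best_params_``, ``cv_score_``, ``importances_``,
    ``selected_features_``, ``model_``.
    """

    def __init__(self, config: ModelConfig | None = None, class_order=None):
        self.config = config
        self.class_order = class_order

    def _resolved_config(self) -> ModelConfig:
        return self.config if self.config is not None else ModelConfig()

    def fit(self, X, y):
        cfg = self._resolved_config()
        if isinstance(X, pd.DataFrame):
            self.feature_names_ = list(X.columns)
            X_arr = X.to_numpy(dtype=float)
        else:
            X_arr = np.asarray(X, dtype=float)
            self.feature_names_ = [f"f{i}" for i in range(X_arr.shape[1])]
        y_arr = np.asarray(y)
        present = list(dict.fromkeys(y_arr))
        order = self.class_order
        if order is None:
            order = [c for c in DEFAULT_CLASS_ORDER if c in present]
            if len(order) != len(present):
                order = sorted(present)
        self.classes_ = np.array(order)
        enc = {c: i for i, c in enumerate(order)}
        y_enc = np.array([enc[v] for v in y_arr])

        X_imp, med = _median_impute(X_arr)
        self.medians_ = med

        if cfg.bayes_opt_iterations > 0:
            self.best_params_, self.cv_score_ = tune_hyperparameters(
                X_arr, y_enc, cfg
            )
        else:
            self.best_params_ = dict(DEFAULT_XGB_PARAMS)
            folds = cv_with_infold_smote(X_arr, y_enc, self.best_params_, cfg)
            self.cv_score_ = float(np.mean([f.accuracy for f in folds]))

        # importances from the original (non-oversampled, imputed) data
        shap_model = _make_xgb(self.best_params_, seed=cfg.seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            shap_model.fit(X_imp, y_enc)
        self.importances_ = mean_abs_shap(shap_model, X_imp, self.feature_names_)

        self.selected_features_ = select_features(
            self.importances_, cfg, cv_data=(X_arr, y_enc)
        )
        cols = [self.feature_names_.index(f) for f in self.selected_features_]
        self._selected_cols_ = cols
        X_sel, y_res = smote_upsample(
            X_imp[:, cols], y_enc, cfg.smote_k_neighbors, seed=cfg.seed
        )
        self.model_ = _make_xgb(self.best_params_, seed=cfg.seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.model_.fit(X_sel, y_res)
        return self

    def _prepare(self, X) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("SpeechMarkerClassifier is not fitted")
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names_].to_numpy(dtype=float)
        X = np.array(X, dtype=float)
        mask = np.isnan(X)
        if mask.any():
            X[mask] = np.broadcast_to(self.medians_, X.shape)[mask]
        return X[:, self._selected_cols_]

    def predict_proba(self, X) -> np.ndarray:
        X_sel = self._prepare(X)
        return self.model_.predict_proba(X_sel)

    def predict(self, X) -> np.ndarray:
        idx = np.argmax(self.predict_proba(X), axis=1)
        return self.classes_[idx]


# ---------------------------------------------------------------------------
# explainability tables


def shap_contribution_table(
    model: xgb.XGBClassifier,
    X,
    class_names: Sequence[str],
    feature_names: Sequence[str] | None = None,
    sample_ids: Sequence | None = None,
) -> pd.DataFrame:
    """Long table of per-sample signed SHAP attributions per class."""
    if feature_names is None:
        feature_names = list(X.columns) if isinstance(X, pd.DataFrame) else [
            f"f{i}" for i in range(np.asarray(X).shape[1])
        ]
    X_arr = np.asarray(X, dtype=float)
    if sample_ids is None:
        sample_ids = list(X.index) if isinstance(X, pd.DataFrame) else list(range(len(X_arr)))
    booster = model.get_booster()
    contribs = booster.predict(xgb.DMatrix(X_arr), pred_contribs=True)
    if contribs.ndim == 2:  # binary: single margin column
        contribs = contribs[:, None, :]
    rows = []
    for si, sid in enumerate(sample_ids):
        for ci, cname in enumerate(class_names):
            for fi, fname in enumerate(feature_names):
                rows.append(
                    (sid, cname, fname, float(contribs[si, ci, fi]), float(X_arr[si, fi]))
                )
    return pd.DataFrame(
        rows, columns=["sample", "class", "feature", "shap_value", "feature_value"]
    )


def direction_summary(contrib: pd.DataFrame) -> pd.DataFrame:
    """Per (class, feature) direction of impact among high-value samples.

    "High-value" samples are those with feature value above the feature's
    median; the sign of their mean attribution gives the direction
    (positive/negative impact of *higher* feature values on that class).
    """
    out = []
    for (cls, feat), grp in contrib.groupby(["class", "feature"], sort=False):
        med = grp["feature_value"].median()
        high = grp[grp["feature_value"] > med]
        if high.empty:  # constant feature: fall back to >= median
            high = grp[grp["feature_value"] >= med]
        mean_shap = float(high["shap_value"].mean())
        out.append(
            {
                "class": cls,
                "feature": feat,
                "mean_shap_high": mean_shap,
                "direction": "positive" if mean_shap > 0 else "negative",
            }
        )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# end-to-end evaluation


@dataclass(frozen=True)
class ClassifierReport:
    metrics: ReportMetrics
    roc_auc: float
    accuracy_ci: tuple[float, float]
    selected_features: list[str]
    importances: pd.Series
    best_params: dict
    cv_accuracy: float
    contributions: pd.DataFrame
    directions: pd.DataFrame
    train_ids: list
    test_ids: list


def _bootstrap_accuracy_ci(
    y_true: np.ndarray, y_pred: np.ndarray, reps: int, seed: int
) -> tuple[float, float]:
    """Percentile bootstrap CI for accuracy, resampling within each class."""
    rng = np.random.default_rng(seed)
    classes = np.unique(y_true)
    idx_by_class = [np.flatnonzero(y_true == c) for c in classes]
    accs = np.empty(reps)
    for r in range(reps):
        correct = n = 0
        for idx in idx_by_class:
            take = rng.integers(0, idx.size, size=idx.size)
            sel = idx[take]
            correct += int(np.sum(y_true[sel] == y_pred[sel]))
            n += idx.size
        accs[r] = correct / n
    lo, hi = np.percentile(accs, [2.5, 97.5])
    return float(lo), float(hi)


def evaluate_holdout(table: pd.DataFrame, config: ModelConfig | None = None,
                     group_col: str = "group") -> ClassifierReport:
    """Full pipeline with a stratified hold-out split and complete report.

    All fitting (imputation, tuning, SHAP selection, SMOTE, final model)
    happens on the training side; the hold-out is only ever scored.
    """
    cfg = config if config is not None else ModelConfig()
    y = table[group_col].to_numpy()
    X = table.drop(columns=[group_col])
    order = [c for c in DEFAULT_CLASS_ORDER if c in set(y)]
    if len(order) != len(set(y)):
        order = sorted(set(y))
    idx = np.arange(len(table))
    try:
        tr_idx, te_idx = train_test_split(
            idx,
            test_size=cfg.test_fraction,
            stratify=y,
            random_state=cfg.seed,
            shuffle=True,
        )
    except ValueError as exc:
        raise ValueError(
            "stratified hold-out split failed — try a different seed or "
            f"test_fraction ({exc})"
        ) from exc
    if set(y[te_idx]) != set(order):
        raise ValueError(
            "a class is absent from the hold-out; use a different seed or "
            "test_fraction"
        )
    clf = SpeechMarkerClassifier(config=cfg, class_order=order).fit(
        X.iloc[tr_idx], y[tr_idx]
    )
    X_te = X.iloc[te_idx]
    y_te = y[te_idx]
    y_pred = clf.predict(X_te)
    proba = clf.predict_proba(X_te)

    cm = np.zeros((len(order), len(order)), dtype=int)
    pos = {c: i for i, c in enumerate(order)}
    for t, p in zip(y_te, y_pred):
        cm[pos[t], pos[p]] += 1
    metrics = classification_report_from_confusion(cm, order, beta=cfg.fbeta_beta)
    y_te_enc = np.array([pos[v] for v in y_te])
    roc = float(
        roc_auc_score(y_te_enc, proba, multi_class="ovr", average="macro",
                      labels=list(range(len(order))))
    )
    ci = _bootstrap_accuracy_ci(y_te, y_pred, cfg.bootstrap_reps, cfg.seed)
    contrib = shap_contribution_table(
        clf.model_,
        pd.DataFrame(clf._prepare(X_te), columns=clf.selected_features_,
                     index=X_te.index),
        class_names=order,
    )
    return ClassifierReport(
        metrics=metrics,
        roc_auc=roc,
        accuracy_ci=ci,
        selected_features=list(clf.selected_features_),
        importances=clf.importances_,
        best_params=dict(clf.best_params_),
        cv_accuracy=float(clf.cv_score_),
        contributions=contrib,
        directions=direction_summary(contrib),
        train_ids=list(table.index[tr_idx]),
        test_ids=list(table.index[te_idx]),
    )
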