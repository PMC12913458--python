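"""Cross-validated classification harness with attribution-based ranking.

Evaluates a roster of classifiers (logistic regression, random forest,
RBF SVM, a shallow feed-forward network, XGBoost, LightGBM, and a stacked
ensemble of the two boosters with a logistic meta-learner) under stratified
k-fold cross-validation with hyperparameter search nested inside the
training split.  Supports the cumulative-domain ablation, exact tree-path
Shapley attribution ranking for the boosters, and top-k retraining.

The evaluation unit matters: ``unit="subject"`` keeps all rows of a subject
in the same fold (leakage-safe default when rows are epochs);
``unit="epoch"`` is a plain stratified split.  Results always carry the
unit they were computed at.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import loguniform
from sklearn.ensemble import RandomForestClassifier, StackingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc, roc_curve
from sklearn.model_selection import (GridSearchCV, RandomizedSearchCV,
                                     StratifiedGroupKFold, StratifiedKFold)
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import schema
from ._types import ConfigError

__all__ = [
    "evaluate_metrics",
    "cross_validated_eval",
    "cumulative_ablation",
    "attribution_rank",
    "topk_retrain",
    "fit_full",
    "EvalResult",
    "AttributionRanking",
    "CLASSIFIER_IDS",
    "UnsupportedModelError",
]


class UnsupportedModelError(TypeError):
    """Attribution requested for a model without exact tree-path Shapley."""


def evaluate_metrics(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    """Accuracy, sensitivity, specificity and F1 (all %) from counts.

    Sensitivity is the recall of the positive (case) class.  Ratios with a
    zero denominator are NaN, with a warning.
    """
    counts = dict(tp=tp, fp=fp, tn=tn, fn=fn)
    if any(v < 0 for v in counts.values()):
        raise ConfigError(f"negative confusion counts: {counts}")
    total = tp + fp + tn + fn
    if total == 0:
        raise ConfigError("empty confusion matrix")

    def ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator)", RuntimeWarning,
                          stacklevel=3)
            return float("nan")
        return 100.0 * num / den

    accuracy = 100.0 * (tp + tn) / total
    sensitivity = ratio(tp, tp + fn, "sensitivity")
    specificity = ratio(tn, tn + fp, "specificity")
    precision = ratio(tp, tp + fp, "precision")
    if np.isnan(precision) or np.isnan(sensitivity) or precision + sensitivity == 0:
        f1 = float("nan")
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    return {"accuracy": accuracy, "sensitivity": sensitivity,
            "specificity": specificity, "f1": f1}


def _xgb(seed: int):
    from xgboost import XGBClassifier
    return XGBClassifier(random_state=seed, n_jobs=1, eval_metric="logloss",
                         tree_method="hist")


def _lgbm(seed: int):
    from lightgbm import LGBMClassifier
    return LGBMClassifier(random_state=seed, n_jobs=1, verbose=-1)


def _scaled(est) -> Pipeline:
    return Pipeline([("scale", StandardScaler()), ("clf", est)])


def _roster(seed: int) -> dict[str, tuple[object, dict]]:
    boost_space = {
        "n_estimators": [50, 100, 200, 300],
        "max_depth": [2, 3, 4, 5],
        "learning_rate": loguniform(0.01, 0.3),
        "subsample": [0.7, 0.85, 1.0],
    }
    return {
        "logreg": (_scaled(LogisticRegression(max_iter=2000, solver="liblinear",
                                              random_state=seed)),
                   {"clf__C": loguniform(1e-2, 1e2),
                    "clf__penalty": ["l1", "l2"]}),
        "rf": (RandomForestClassifier(random_state=seed, n_jobs=1),
               {"n_estimators": [100, 200, 400],
                "max_depth": [None, 3, 5, 10],
                "max_features": ["sqrt", "log2"]}),
        "svm": (_scaled(SVC(kernel="rbf", probability=True, random_state=seed)),
                {"clf__C": loguniform(1e-1, 1e2),
                 "clf__gamma": loguniform(1e-3, 1.0)}),
        "mlp": (_scaled(MLPClassifier(max_iter=500, random_state=seed)),
                {"clf__hidden_layer_sizes": [(32,), (64,), (32, 16)],
                 "clf__alpha": loguniform(1e-5, 1e-2),
                 "clf__learning_rate_init": [1e-3, 1e-2]}),
        "xgb": (_xgb(seed), dict(boost_space)),
        "lgbm": (_lgbm(seed),
                 {**{k: v for k, v in boost_space.items() if k != "max_depth"},
                  "num_leaves": [7, 15, 31]}),
        "stack": (_scaled(StackingClassifier(
                     estimators=[("xgb", _xgb(seed)), ("lgbm", _lgbm(seed))],
                     final_estimator=LogisticRegression(max_iter=2000,
                                                        random_state=seed),
                     cv=3, n_jobs=1)),
                  {"clf__final_estimator__C": loguniform(1e-2, 1e2)}),
    }


CLASSIFIER_IDS = tuple(_roster(0).keys())


@dataclass
class EvalResult:
    """Per-classifier cross-validation outcome (metrics in %, mean +- SD)."""

    classifier: str
    unit: str
    fold_metrics: pd.DataFrame
    # curve points are pooled over folds; the area is the mean of per-fold
    # AUCs (pooling scores from separately calibrated fold models can
    # fabricate inversions that no single model makes)
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    roc_auc: float

    def mean(self, metric: str) -> float:
        return float(self.fold_metrics[metric].mean())

    def sd(self, metric: str) -> float:
        return float(self.fold_metrics[metric].std(ddof=0))

    def summary(self) -> dict[str, float]:
        out: dict[str, float] = {"classifier": self.classifier, "unit": self.unit}
        for m in ("accuracy", "sensitivity", "specificity", "f1"):
            out[f"{m}_mean"] = self.mean(m)
            out[f"{m}_sd"] = self.sd(m)
        out["roc_auc"] = self.roc_auc
        return out


def _binary_targets(groups, positive_group: str | None) -> tuple[np.ndarray, str]:
    groups = np.asarray(groups)
    levels = sorted(set(groups.tolist()))
    if len(levels) != 2:
        raise ConfigError(f"need exactly 2 groups, got {levels}")
    pos = levels[-1] if positive_group is None else positive_group
    if pos not in levels:
        raise ConfigError(f"positive group {pos!r} not in {levels}")
    return (groups == pos).astype(int), pos


def _make_cv(unit: str, folds: int, seed: int):
    if unit == "subject":
        return StratifiedGroupKFold(n_splits=folds, shuffle=True, random_state=seed)
    if unit == "epoch":
        return StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    raise ConfigError(f"unknown unit {unit!r} (use 'subject' or 'epoch')")


def _scores(model, X) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


def cross_validated_eval(table: pd.DataFrame, groups, classifiers=("xgb",),
                         folds: int = 10, search_iters: int = 50,
                         seed: int = 42, unit: str = "subject",
                         subjects=None, positive_group: str | None = None,
                         search: str = "random",
                         param_grid: dict | None = None) -> list[EvalResult]:
    """Stratified k-fold evaluation with nested hyperparameter search.

    ``subjects`` (one id per row) is required for ``unit="subject"`` when
    rows are epochs; when omitted, every row is its own subject.  Scaling
    and the search are fit on training folds only.  ``search_iters=0``
    skips tuning and uses the estimator defaults.
    """
    X = table.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ConfigError("non-finite feature values; impute or drop first")
    y, _ = _binary_targets(groups, positive_group)
    n_rows = X.shape[0]
    subj = np.arange(n_rows) if subjects is None else np.asarray(subjects)
    roster = _roster(seed)
    unknown = [c for c in classifiers if c not in roster]
    if unknown:
        raise ConfigError(f"unknown classifier ids {unknown}; "
                          f"available: {list(roster)}")
    cv = _make_cv(unit, folds, seed)
    results = []
    for cid in classifiers:
        est, space = roster[cid]
        fold_rows = []
        fold_aucs = []
        all_scores = np.empty(n_rows)
        all_true = np.empty(n_rows, dtype=int)
        filled = 0
        for fold, (tr, te) in enumerate(cv.split(X, y, groups=subj)):
            if search_iters > 0 and space:
                if search == "grid":
                    fitted = GridSearchCV(
                        est, param_grid if param_grid is not None else space,
                        cv=3, n_jobs=1).fit(X[tr], y[tr])
                else:
                    fitted = RandomizedSearchCV(
                        est, space, n_iter=search_iters, cv=3,
                        random_state=seed, n_jobs=1).fit(X[tr], y[tr])
                model = fitted.best_estimator_
            else:
                from sklearn.base import clone
                model = clone(est).fit(X[tr], y[tr])
            pred = model.predict(X[te])
            tp = int(((pred == 1) & (y[te] == 1)).sum())
            fp = int(((pred == 1) & (y[te] == 0)).sum())
            tn = int(((pred == 0) & (y[te] == 0)).sum())
            fn = int(((pred == 0) & (y[te] == 1)).sum())
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                metrics = evaluate_metrics(tp, fp, tn, fn)
            metrics["fold"] = fold
            fold_rows.append(metrics)
            s = _scores(model, X[te])
            all_scores[filled:filled + len(te)] = s
            all_true[filled:filled + len(te)] = y[te]
            filled += len(te)
            if len(np.unique(y[te])) == 2:
                f_fpr, f_tpr, _ = roc_curve(y[te], s)
                fold_aucs.append(auc(f_fpr, f_tpr))
        fpr, tpr, _ = roc_curve(all_true[:filled], all_scores[:filled])
        results.append(EvalResult(
            classifier=cid, unit=unit,
            fold_metrics=pd.DataFrame(fold_rows).set_index("fold"),
            roc_fpr=fpr, roc_tpr=tpr,
            roc_auc=float(np.mean(fold_aucs)) if fold_aucs else float("nan"),
        ))
    return results


def cumulative_ablation(table: pd.DataFrame, groups, domain_order=None,
                        classifier: str = "xgb", folds: int = 10,
                        search_iters: int = 20, seed: int = 42,
                        unit: str = "subject", subjects=None,
                        positive_group: str | None = None) -> pd.DataFrame:
    """Accuracy per cumulative feature-domain stage.

    Stages follow ``domain_order`` (default temporal -> +spectral ->
    +complexity -> +higher_order, i.e. 35, 55, 70, 80 columns); each stage
    re-runs the cross-validated booster on exactly its cumulative columns.
    """
    order = schema.DOMAIN_ORDER if domain_order is None else list(domain_order)
    stages = schema.cumulative_columns(order)
    rows = []
    prev_acc = None
    for stage_idx, cols in enumerate(stages):
        missing = [c for c in cols if c not in table.columns]
        if missing:
            raise ConfigError(f"missing domain columns: {missing[:5]} ...")
        res = cross_validated_eval(table[cols], groups, classifiers=(classifier,),
                                   folds=folds, search_iters=search_iters,
                                   seed=seed, unit=unit, subjects=subjects,
                                   positive_group=positive_group)[0]
        acc = res.mean("accuracy")
        rows.append({
            "stage": " + ".join(order[:stage_idx + 1]),
            "n_features": len(cols),
            "accuracy_mean": acc,
            "accuracy_sd": res.sd("accuracy"),
            "increment": float("nan") if prev_acc is None else acc - prev_acc,
        })
        prev_acc = acc
    return pd.DataFrame(rows)


@dataclass
class AttributionRanking:
    """Global feature ranking by mean absolute Shapley attribution."""

    importances: pd.Series  # mean |attribution| per feature, descending
    values: np.ndarray      # per-instance attributions (n, n_features)
    base_value: float
    method: str = "tree_shapley"

    def top(self, k: int = 20) -> list[str]:
        if k > self.importances.size:
            raise ConfigError(f"k={k} exceeds {self.importances.size} features")
        return self.importances.index[:k].tolist()


def fit_full(table: pd.DataFrame, groups, classifier: str = "xgb",
             seed: int = 42, positive_group: str | None = None):
    """Fit one roster model on the full table (for attribution analysis)."""
    y, _ = _binary_targets(groups, positive_group)
    est, _space = _roster(seed)[classifier]
    return est.fit(table.to_numpy(dtype=float), y)


def attribution_rank(model, X, feature_names=None,
                     allow_permutation_fallback: bool = False,
                     seed: int = 42, y=None) -> AttributionRanking:
    """Exact tree-path Shapley attributions, ranked by mean |value|.

    Supports the XGBoost and LightGBM boosters (their native TreeSHAP
    implementation).  Other models raise :class:`UnsupportedModelError`
    unless ``allow_permutation_fallback`` is set, in which case permutation
    importance is returned and flagged as such in ``method``.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns) if feature_names is None else feature_names
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    cls = type(model).__name__
    if cls == "XGBClassifier":
        import xgboost
        contribs = model.get_booster().predict(xgboost.DMatrix(X),
                                               pred_contribs=True)
    elif cls == "LGBMClassifier":
        contribs = np.asarray(model.predict(X, pred_contrib=True))
    elif allow_permutation_fallback:
        from sklearn.inspection import permutation_importance
        if y is None:
            raise ConfigError("permutation fallback needs the true labels y")
        warnings.warn("model has no exact tree-path attribution; using "
                      "permutation importance", RuntimeWarning, stacklevel=2)
        imp = permutation_importance(model, X, np.asarray(y),
                                     n_repeats=10, random_state=seed)
        series = pd.Series(np.abs(imp.importances_mean), index=feature_names)
        series = series.sort_values(ascending=False, kind="stable")
        return AttributionRanking(importances=series,
                                  values=np.abs(imp.importances.T),
                                  base_value=0.0, method="permutation")
    else:
        raise UnsupportedModelError(
            f"{cls} has no exact tree-path Shapley attribution; pass "
            "allow_permutation_fallback=True for a flagged fallback"
        )
    contribs = np.asarray(contribs, dtype=float)
    values, base = contribs[:, :-1], contribs[:, -1]
    series = pd.Series(np.abs(values).mean(axis=0), index=feature_names)
    series = series.sort_values(ascending=False, kind="stable")
    return AttributionRanking(importances=series, values=values,
                              base_value=float(base.mean()))


TOPK_GRID = {"n_estimators": [100, 300], "max_depth": [2, 3, 4],
             "learning_rate": [0.05, 0.1, 0.3]}


def topk_retrain(table: pd.DataFrame, groups, ranking: AttributionRanking,
                 k: int = 20, classifier: str = "xgb", folds: int = 10,
                 seed: int = 42, unit: str = "subject", subjects=None,
                 positive_group: str | None = None,
                 param_grid: dict | None = None) -> EvalResult:
    """Re-evaluate on the top-k ranked features (grid-searched booster)."""
    keep = set(ranking.top(k))
    cols = [c for c in table.columns if c in keep]  # preserve table order
    return cross_validated_eval(
        table[cols], groups, classifiers=(classifier,), folds=folds,
        search_iters=1, seed=seed, unit=unit, subjects=subjects,
        positive_group=positive_group, search="grid",
        param_grid=TOPK_GRID if param_grid is None else param_grid,
    )[0]
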