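"""Disease-probability estimation, label imputation and analysis weights.

A prediction model is fit on subjects with observed case/control status,
using disease-related endophenotypes (e.g. regional MRI measures, cognitive
scores) as predictors; genotypes are never allowed as predictors, because
re-using the tested variant to construct the phenotype would manufacture
false positives.  The fitted model assigns each unlabeled subject an
affection probability p, which is converted into an imputed label and an
analysis weight:

    y = 1  if p >= 0.5 else 0,         w = p  if p >= 0.5 else 1 - p.

The tie p = 0.5 is deliberately coded as a case (y = 1): the imputation rule
uses ">=", which matters on balanced data.

Model selection follows a nested cross-validation protocol: outer folds
estimate the out-of-sample AUC of each candidate algorithm, inner folds tune
its hyperparameters, and the algorithm with the highest mean outer AUC is
refit on all labeled subjects.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "impute_and_weight",
    "PredictionModel",
    "fit_prediction_model",
    "predict_probability",
    "validate_predictors",
    "ALGORITHM_REGISTRY",
]

# Column names that look like genotype data are rejected outright.
_GENOTYPE_PATTERN = re.compile(r"^(rs\d+|snp[\w.]*|chr\d+[:_].*|\d+:\d+[:_].*)$", re.IGNORECASE)


def impute_and_weight(p):
    """Convert affection probabilities into imputed labels and weights.

    Returns ``(y, w)`` with ``y = 1`` iff ``p >= 0.5`` and
    ``w = max(p, 1 - p)``; scalars map to scalars, arrays to arrays.
    Probabilities outside [0, 1] raise ``ValueError``.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1) or not np.all(np.isfinite(arr)):
        raise ValueError("affection probabilities must lie in [0, 1]")
    y = (arr >= 0.5).astype(int)
    w = np.where(arr >= 0.5, arr, 1.0 - arr)
    if np.isscalar(p) or arr.ndim == 0:
        return int(y), float(w)
    return y, w


# ---------------------------------------------------------------------------
# algorithm registry
# ---------------------------------------------------------------------------

def _logistic():
    # C = inf disables the ridge term: plain maximum-likelihood logistic
    return LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000), {}


def _penalized():
    est = LogisticRegression(solver="lbfgs", max_iter=2000)
    return est, {"C": [0.01, 0.1, 1.0, 10.0]}


def _random_forest():
    est = RandomForestClassifier(n_estimators=200)
    return est, {"max_depth": [3, 6, None]}


def _gradient_boosting():
    est = GradientBoostingClassifier()
    return est, {"n_estimators": [100, 300], "learning_rate": [0.05, 0.1]}


def _svm():
    est = SVC(kernel="rbf", probability=True)
    return est, {"C": [0.1, 1.0, 10.0]}


#: name -> factory returning ``(estimator, hyperparameter grid)``.  The
#: insertion order is the deterministic tie-break for model selection.
ALGORITHM_REGISTRY: dict[str, Callable[[], tuple]] = {
    "logistic": _logistic,
    "penalized": _penalized,
    "random_forest": _random_forest,
    "gradient_boosting": _gradient_boosting,
    "svm": _svm,
}


@dataclass
class PredictionModel:
    """A selected, refit disease-status classifier."""

    algorithm: str
    estimator: object
    columns: list[str]
    outer_aucs: np.ndarray
    best_params: dict = field(default_factory=dict)
    candidate_aucs: dict[str, float] = field(default_factory=dict)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.outer_aucs))


def validate_predictors(X: pd.DataFrame) -> pd.DataFrame:
    """Enforce the predictor-table contract.

    Genotype-looking columns are refused; non-numeric columns are refused;
    rows with missing values are dropped with a warning (predictor
    imputation is out of scope).
    """
    bad = [c for c in X.columns if _GENOTYPE_PATTERN.match(str(c))]
    if bad:
        raise ValueError(
            f"genotype columns are not allowed as predictors: {bad}; "
            "SNPs must never feed the prediction model"
        )
    X = X.apply(pd.to_numeric, errors="raise")
    n_bad = int(X.isna().any(axis=1).sum())
    if n_bad:
        warnings.warn(f"dropping {n_bad} subjects with missing predictor values", stacklevel=2)
        X = X.dropna()
    for c in X.columns:
        if not np.isfinite(X[c].to_numpy()).all():
            raise ValueError(f"non-finite values in predictor column {c!r}")
    return X


def _fold_auc(estimator, X_tr, y_tr, X_te, y_te) -> float:
    est = clone(estimator)
    est.fit(X_tr, y_tr)
    return float(roc_auc_score(y_te, est.predict_proba(X_te)[:, 1]))


def fit_prediction_model(
    X: pd.DataFrame,
    y: np.ndarray,
    algorithms: tuple[str, ...] = ("logistic", "penalized"),
    outer_folds: int = 5,
    inner_folds: int = 5,
    seed: int = 0,
) -> PredictionModel:
    """Nested-CV selection and refit of a disease prediction model.

    Outer folds estimate the test AUC of each candidate; inner folds (via
    grid search) choose hyperparameters inside each outer training split.
    The candidate with the highest mean outer AUC wins, ties broken by the
    order of ``algorithms``; it is then refit on all labeled subjects with
    inner-CV-selected hyperparameters.

    Only labeled subjects may be passed; ``y`` must contain both classes.
    """
    y = np.asarray(y)
    if len(y) != len(X):
        raise ValueError("X and y have different lengths")
    keep = ~X.isna().any(axis=1).to_numpy()
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} subjects with missing predictor values",
                      stacklevel=2)
        X, y = X.loc[keep], y[keep]
    X = validate_predictors(X)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("labels contain a single class; cannot fit a classifier")
    unknown = [a for a in algorithms if a not in ALGORITHM_REGISTRY]
    if unknown:
        raise KeyError(f"unknown algorithms {unknown}; registry has {list(ALGORITHM_REGISTRY)}")

    Xv = X.to_numpy(dtype=float)
    ss = np.random.SeedSequence(seed)
    outer_seed, inner_seed, est_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3))
    outer = StratifiedKFold(n_splits=outer_folds, shuffle=True, random_state=outer_seed)

    results: dict[str, tuple[np.ndarray, dict]] = {}
    for name in algorithms:
        est, grid = ALGORITHM_REGISTRY[name]()
        if hasattr(est, "random_state"):
            est.set_params(random_state=est_seed)
        aucs = []
        for tr, te in outer.split(Xv, y):
            if grid:
                inner = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=inner_seed)
                gs = GridSearchCV(clone(est), grid, cv=inner, scoring="roc_auc", n_jobs=1)
                gs.fit(Xv[tr], y[tr])
                fitted = gs.best_estimator_
            else:
                fitted = clone(est).fit(Xv[tr], y[tr])
            aucs.append(float(roc_auc_score(y[te], fitted.predict_proba(Xv[te])[:, 1])))
        results[name] = (np.array(aucs), grid)

    means = {name: float(np.mean(a)) for name, (a, _) in results.items()}
    best = max(algorithms, key=lambda name: means[name])  # max is stable: first winner kept

    est, grid = ALGORITHM_REGISTRY[best]()
    if hasattr(est, "random_state"):
        est.set_params(random_state=est_seed)
    if grid:
        inner = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=inner_seed)
        gs = GridSearchCV(est, grid, cv=inner, scoring="roc_auc", n_jobs=1)
        gs.fit(Xv, y)
        final, best_params = gs.best_estimator_, gs.best_params_
    else:
        final, best_params = est.fit(Xv, y), {}
    return PredictionModel(
        algorithm=best,
        estimator=final,
        columns=list(X.columns),
        outer_aucs=results[best][0],
        best_params=best_params,
        candidate_aucs=means,
    )


def predict_probability(model: PredictionModel, X_new: pd.DataFrame) -> np.ndarray:
    """Affection probabilities for new subjects from a fitted model.

    Columns must match the training columns exactly (order is restored
    automatically); mismatches raise with the offending column names.
    """
    missing = [c for c in model.columns if c not in X_new.columns]
    extra = [c for c in X_new.columns if c not in model.columns]
    if missing or extra:
        raise ValueError(f"predictor columns differ from training: missing={missing}, extra={extra}")
    X_new = validate_predictors(X_new[model.columns])
    p = model.estimator.predict_proba(X_new.to_numpy(dtype=float))[:, 1]
    return np.clip(p, 0.0, 1.0)
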