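"""Cross-validated stacked ensemble (SuperLearner-style meta-learning).

Base learners are fitted per fold; the meta-weights minimize cross-validated
risk over the probability simplex — non-negative least squares for a
continuous response, simplex-constrained negative log-likelihood for a
binary one.  If the optimized combination is (numerically) worse than the
best single learner on the same fold-out predictions, the discrete selector
is returned instead, so the ensemble's CV risk never exceeds the best
learner's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize, nnls
from sklearn.dummy import DummyClassifier, DummyRegressor
from sklearn.linear_model import (
    ElasticNet,
    LinearRegression,
    LogisticRegression,
    Ridge,
)
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import PolynomialFeatures, SplineTransformer, StandardScaler
from sklearn.compose import ColumnTransformer
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

PROB_CLIP = (1e-6, 1.0 - 1e-6)

# library mirroring the reference ensemble where feasible; the trimmed
# default keeps per-fit cost low for replicated simulation runs
DEFAULT_LIBRARY = ["mean", "glm", "glm_interactions", "elastic_net", "tree"]
FULL_LIBRARY = DEFAULT_LIBRARY + ["ridge", "spline_gam", "tree_pruned", "random_forest"]
FAST_LIBRARY = ["mean", "glm"]


class FitFailureError(RuntimeError):
    """All base learners failed to fit."""


@dataclass(frozen=True)
class LearnerSpec:
    name: str
    family: str = "gaussian"
    hyperparameters: dict = field(default_factory=dict, hash=False)


def make_learner(spec: LearnerSpec, seed: int = 0):
    """Instantiate a scikit-learn estimator for a learner spec."""
    name, fam, hp = spec.name, spec.family, dict(spec.hyperparameters)
    binom = fam == "binomial"
    if name == "mean":
        return DummyClassifier(strategy="prior") if binom else DummyRegressor()
    if name == "glm":
        return (LogisticRegression(C=np.inf, max_iter=2000)
                if binom else LinearRegression())
    if name == "glm_interactions":
        base = (LogisticRegression(C=np.inf, max_iter=4000)
                if binom else LinearRegression())
        return make_pipeline(
            PolynomialFeatures(degree=2, interaction_only=True, include_bias=False),
            base)
    if name == "ridge":
        return (LogisticRegression(C=hp.get("C", 1.0), max_iter=2000)
                if binom else Ridge(alpha=hp.get("alpha", 1.0)))
    if name == "elastic_net":
        if binom:
            return LogisticRegression(
                solver="saga", max_iter=5000,
                l1_ratio=hp.get("l1_ratio", 0.5), C=hp.get("C", 1.0))
        return make_pipeline(
            StandardScaler(),
            ElasticNet(alpha=hp.get("alpha", 0.01),
                       l1_ratio=hp.get("l1_ratio", 0.5), max_iter=5000))
    if name == "spline_gam":
        # additive spline model: deferred construction because the column
        # split depends on the design; handled by _SplineWrapper
        return _SplineWrapper(binom)
    if name == "tree":
        cls = DecisionTreeClassifier if binom else DecisionTreeRegressor
        return cls(min_samples_leaf=hp.get("min_samples_leaf", 20),
                   ccp_alpha=hp.get("ccp_alpha", 1e-3), random_state=seed)
    if name == "tree_pruned":
        cls = DecisionTreeClassifier if binom else DecisionTreeRegressor
        return cls(min_samples_leaf=hp.get("min_samples_leaf", 20),
                   ccp_alpha=hp.get("ccp_alpha", 1e-2), random_state=seed)
    if name == "random_forest":
        cls = RandomForestClassifier if binom else RandomForestRegressor
        return cls(n_estimators=hp.get("n_estimators", 100),
                   min_samples_leaf=hp.get("min_samples_leaf", 5),
                   random_state=seed, n_jobs=1)
    raise ValueError(f"unknown learner {name!r}")


class _SplineWrapper:
    """Additive spline GLM built lazily once the design is known."""

    def __init__(self, binomial: bool):
        self.binomial = binomial
        self.pipeline_ = None

    def fit(self, X, y):
        X = np.asarray(X)
        n_unique = [len(np.unique(X[:, j])) for j in range(X.shape[1])]
        cont = [j for j, k in enumerate(n_unique) if k > 10]
        disc = [j for j in range(X.shape[1]) if j not in cont]
        ct = ColumnTransformer(
            [("spline", SplineTransformer(n_knots=5, degree=3), cont),
             ("pass", "passthrough", disc)])
        base = (LogisticRegression(C=np.inf, max_iter=4000)
                if self.binomial else LinearRegression())
        self.pipeline_ = make_pipeline(ct, base)
        self.pipeline_.fit(X, y)
        return self

    def predict(self, X):
        return self.pipeline_.predict(np.asarray(X))

    def predict_proba(self, X):
        return self.pipeline_.predict_proba(np.asarray(X))

    def get_params(self, deep=True):  # clone support
        return {"binomial": self.binomial}

    def set_params(self, **kw):
        self.binomial = kw.get("binomial", self.binomial)
        return self


def _predict(model, X: np.ndarray, binomial: bool) -> np.ndarray:
    if binomial:
        if hasattr(model, "predict_proba"):
            proba = model.predict_proba(X)
            if proba.shape[1] == 1:  # single class seen in training
                cls = float(model.classes_[0])
                return np.full(len(X), cls)
            return proba[:, list(model.classes_).index(1)]
        return np.clip(model.predict(X), 0.0, 1.0)
    return model.predict(X)


def _risk(pred: np.ndarray, y: np.ndarray, binomial: bool) -> float:
    if binomial:
        p = np.clip(pred, *PROB_CLIP)
        return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
    return float(np.mean((y - pred) ** 2))


@dataclass
class EnsembleFit:
    library: list[LearnerSpec]
    weights: np.ndarray
    models: list
    family: str
    cv_risks: dict[str, float]
    cv_risk_ensemble: float
    feature_names: list[str] | None = None

    def predict(self, newdesign) -> np.ndarray:
        return ensemble_predict(self, newdesign)


def _as_array(design, feature_names: list[str] | None = None):
    if isinstance(design, pd.DataFrame):
        if feature_names is not None:
            missing = set(feature_names) - set(design.columns)
            if missing:
                raise ValueError(f"design is missing columns {sorted(missing)}")
            design = design[feature_names]
        return design.to_numpy(dtype=float), list(design.columns)
    arr = np.asarray(design, dtype=float)
    if feature_names is not None and arr.shape[1] != len(feature_names):
        raise ValueError("design has wrong number of columns")
    return arr, feature_names


def cv_stack_fit(
    design,
    response,
    family: str,
    library: Sequence[str | LearnerSpec] = DEFAULT_LIBRARY,
    v_folds: int = 5,
    seed: int = 0,
) -> EnsembleFit:
    """Fit the cross-validated stack.

    ``design`` may be a DataFrame (column names are remembered and enforced
    at prediction time) or an array.  For the binomial family the folds are
    stratified by the response.
    """
    if family not in ("gaussian", "binomial"):
        raise ValueError(f"unknown family {family!r}")
    if v_folds < 2:
        raise ValueError("v_folds must be at least 2")
    X, feature_names = _as_array(design)
    y = np.asarray(response, dtype=float)
    if len(y) != len(X):
        raise ValueError("response length must match design rows")
    binom = family == "binomial"
    if binom and not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("binomial response must be 0/1")

    specs = [s if isinstance(s, LearnerSpec) else LearnerSpec(s, family)
             for s in library]
    specs = [LearnerSpec(s.name, family, s.hyperparameters) for s in specs]
    if len({s.name for s in specs}) != len(specs):
        raise ValueError("learner names must be unique within a library")

    if binom and 0 < y.sum() < len(y):
        splitter = StratifiedKFold(v_folds, shuffle=True, random_state=seed)
        folds = list(splitter.split(X, y))
    else:
        splitter = KFold(v_folds, shuffle=True, random_state=seed)
        folds = list(splitter.split(X))

    n, L = len(y), len(specs)
    P = np.full((n, L), np.nan)
    ok = np.ones(L, dtype=bool)
    for j, spec in enumerate(specs):
        try:
            for k, (tr, te) in enumerate(folds):
                model = make_learner(spec, seed=seed + 31 * j + k)
                model.fit(X[tr], y[tr])
                P[te, j] = _predict(model, X[te], binom)
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"learner {spec.name!r} failed and was dropped: {exc}")
            ok[j] = False
    if not ok.any():
        raise FitFailureError("all base learners failed to fit")
    specs = [s for s, good in zip(specs, ok) if good]
    P = P[:, ok]
    L = len(specs)

    cv_risks = {s.name: _risk(P[:, j], y, binom) for j, s in enumerate(specs)}

    if L == 1:
        w = np.array([1.0])
    elif binom:
        Pc = np.clip(P, *PROB_CLIP)

        def negll(w):
            p = np.clip(Pc @ w, *PROB_CLIP)
            return -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))

        res = minimize(
            negll, np.full(L, 1.0 / L), method="SLSQP",
            bounds=[(0.0, 1.0)] * L,
            constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0}],
            options={"maxiter": 200, "ftol": 1e-10})
        w = np.clip(res.x, 0, None)
        w = w / w.sum()
    else:
        w, _ = nnls(P, y)
        if w.sum() <= 0:
            w = np.zeros(L)
            w[int(np.argmin([cv_risks[s.name] for s in specs]))] = 1.0
        w = w / w.sum()

    ens_risk = _risk(np.clip(P @ w, *PROB_CLIP) if binom else P @ w, y, binom)
    best_j = int(np.argmin([cv_risks[s.name] for s in specs]))
    if ens_risk > cv_risks[specs[best_j].name] + 1e-10:
        w = np.zeros(L)
        w[best_j] = 1.0
        ens_risk = cv_risks[specs[best_j].name]

    models = []
    for j, spec in enumerate(specs):
        model = make_learner(spec, seed=seed + 101 * j)
        model.fit(X, y)
        models.append(model)

    return EnsembleFit(library=list(specs), weights=w, models=models,
                       family=family, cv_risks=cv_risks,
                       cv_risk_ensemble=ens_risk, feature_names=feature_names)


def ensemble_predict(fit: EnsembleFit, newdesign) -> np.ndarray:
    """Weighted combination of base-learner predictions."""
    X, _ = _as_array(newdesign, fit.feature_names)
    binom = fit.family == "binomial"
    preds = np.column_stack([_predict(m, X, binom) for m in fit.models])
    out = preds @ fit.weights
    if binom:
        out = np.clip(out, *PROB_CLIP)
    return out
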