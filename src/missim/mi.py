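"""Multiple imputation by fully conditional specification (FCS).

Univariate imputers: Bayesian-style logistic regression for binary
variables, predictive mean matching (PMM, type-1) for the continuous
outcome, and donor-leaf draws from classification/regression trees or small
random forests.  Interaction and power terms used as predictors are
"passive": recomputed inside every cycle from the current imputed values,
and never used to predict a variable they contain.

Pooling across completed data sets follows Rubin's rules with the
large-sample degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

ANALYSIS_VARIABLES = ["X", "Z1", "Z2", "Z3", "Z4", "Z5", "Y"]
HIGHER_ORDER_POOL = ["Z1", "Z3", "Z4", "Z5"]  # Z2 excluded (low prevalence)


class UnimputableVariableError(RuntimeError):
    """A variable has no observed values to learn from."""


class PoolSizeError(ValueError):
    """The PMM donor pool exceeds the number of observed records."""


@dataclass
class ImputationSpec:
    """Configuration of one FCS run."""

    m: int = 5
    max_iter: int = 5
    method_map: dict[str, str] = field(default_factory=dict)
    predictor_sets: dict[str, list[str]] = field(default_factory=dict)
    donor_k: int = 5
    cart_params: dict = field(default_factory=lambda: {"min_samples_leaf": 5,
                                                       "ccp_alpha": 1e-4})
    rf_params: dict = field(default_factory=lambda: {"n_trees": 10,
                                                     "min_samples_leaf": 5})
    seed: int = 0

    def validate(self) -> None:
        if self.m < 2:
            raise ValueError("m must be at least 2")
        for var, terms in self.predictor_sets.items():
            for t in terms:
                if var in t.split("*"):
                    raise ValueError(
                        f"passive term {t!r} may not predict {var!r}")


def build_design(df: pd.DataFrame, terms: Sequence[str]) -> np.ndarray:
    """Design matrix for a term list; products are recomputed on the fly."""
    cols = []
    for t in terms:
        if "*" in t:
            parts = t.split("*")
            col = np.ones(len(df))
            for p in parts:
                col = col * df[p].to_numpy(dtype=float)
            cols.append(col)
        else:
            cols.append(df[t].to_numpy(dtype=float))
    return np.column_stack(cols)


# -- univariate imputers -------------------------------------------------

def _ridge_logistic(D: np.ndarray, y: np.ndarray, lam: float = 1e-3,
                    max_iter: int = 50):
    """Penalized IRLS returning the fit and its approximate covariance."""
    X = np.column_stack([np.ones(len(D)), D])
    p_dim = X.shape[1]
    beta = np.zeros(p_dim)
    pen = lam * np.eye(p_dim)
    pen[0, 0] = 0.0  # do not shrink the intercept
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        W = mu * (1 - mu)
        H = X.T @ (X * W[:, None]) + pen
        grad = X.T @ (y - mu) - pen @ beta
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    mu = expit(X @ beta)
    W = mu * (1 - mu)
    cov = np.linalg.inv(X.T @ (X * W[:, None]) + pen)
    return beta, cov


def impute_logistic(y_obs: np.ndarray, X_obs: np.ndarray, X_mis: np.ndarray,
                    rng: np.random.Generator, draw_coefs: bool = True,
                    beta_override: np.ndarray | None = None) -> np.ndarray:
    """Proper imputation from a ridge-penalized logistic model.

    Coefficients are drawn from the asymptotic normal approximation before
    each record's Bernoulli draw.  With a single observed class the model is
    degenerate and a constant-class draw is returned with a warning.
    """
    y_obs = np.asarray(y_obs, dtype=float)
    classes = np.unique(y_obs)
    if classes.size < 2:
        warnings.warn("single observed class; imputing the constant class")
        return np.full(len(X_mis), classes[0])
    if beta_override is not None:
        beta = np.asarray(beta_override, dtype=float)
    else:
        beta_hat, cov = _ridge_logistic(X_obs, y_obs)
        if draw_coefs:
            beta = rng.multivariate_normal(beta_hat, cov, method="cholesky")
        else:
            beta = beta_hat
    Xm = np.column_stack([np.ones(len(X_mis)), X_mis])
    p = expit(Xm @ beta)
    return (rng.random(len(X_mis)) < p).astype(float)


def _bayes_linear_draw(D_obs: np.ndarray, y_obs: np.ndarray,
                       rng: np.random.Generator, ridge: float = 1e-8):
    """Posterior draw for a normal linear model (as in chained-equation MI)."""
    X = np.column_stack([np.ones(len(D_obs)), D_obs])
    n, p = X.shape
    XtX = X.T @ X + ridge * np.eye(p)
    beta_hat = np.linalg.solve(XtX, X.T @ y_obs)
    resid = y_obs - X @ beta_hat
    df = max(n - p, 1)
    sigma2 = float(resid @ resid) / stats.chi2.rvs(df, random_state=rng)
    V = np.linalg.inv(XtX)
    L = np.linalg.cholesky((V + V.T) / 2)
    beta_tilde = beta_hat + np.sqrt(sigma2) * (L @ rng.standard_normal(p))
    return beta_hat, beta_tilde


def impute_pmm(y_obs: np.ndarray, X_obs: np.ndarray, X_mis: np.ndarray,
               donor_k: int, rng: np.random.Generator) -> np.ndarray:
    """Predictive mean matching (type-1).

    Predicted means for donors use the least-squares fit; means for targets
    use a posterior coefficient draw.  Each target receives the observed
    value of one of its ``donor_k`` nearest donors, chosen uniformly.
    """
    y_obs = np.asarray(y_obs, dtype=float)
    if donor_k > len(y_obs):
        raise PoolSizeError(f"donor_k={donor_k} exceeds {len(y_obs)} donors")
    beta_hat, beta_tilde = _bayes_linear_draw(X_obs, y_obs, rng)
    pred_obs = np.column_stack([np.ones(len(X_obs)), X_obs]) @ beta_hat
    pred_mis = np.column_stack([np.ones(len(X_mis)), X_mis]) @ beta_tilde
    out = np.empty(len(X_mis))
    for i, pm in enumerate(pred_mis):
        d = np.abs(pred_obs - pm)
        pool = np.argpartition(d, donor_k - 1)[:donor_k]
        out[i] = y_obs[pool[rng.integers(donor_k)]]
    return out


def _leaf_donors(tree, X_obs, X_mis):
    """Map each target record to the observed indices in its leaf."""
    leaves_obs = tree.apply(X_obs)
    leaves_mis = tree.apply(X_mis)
    by_leaf: dict[int, np.ndarray] = {}
    for leaf in np.unique(leaves_obs):
        by_leaf[leaf] = np.flatnonzero(leaves_obs == leaf)
    return [by_leaf.get(leaf, np.arange(len(X_obs))) for leaf in leaves_mis]


def impute_cart(y_obs: np.ndarray, X_obs: np.ndarray, X_mis: np.ndarray,
                cart_params: dict | None = None,
                rng: np.random.Generator | None = None) -> np.ndarray:
    """Tree imputation: a uniform draw from the donor leaf's observed values."""
    rng = rng or np.random.default_rng()
    cart_params = cart_params or {}
    y_obs = np.asarray(y_obs, dtype=float)
    binary = set(np.unique(y_obs)) <= {0.0, 1.0}
    cls = DecisionTreeClassifier if binary else DecisionTreeRegressor
    tree = cls(min_samples_leaf=cart_params.get("min_samples_leaf", 5),
               ccp_alpha=cart_params.get("ccp_alpha", 1e-4),
               max_features=cart_params.get("max_features"),
               random_state=int(rng.integers(2**31)))
    tree.fit(X_obs, y_obs)
    donors = _leaf_donors(tree, X_obs, X_mis)
    return np.array([y_obs[d[rng.integers(len(d))]] for d in donors])


def impute_rf(y_obs: np.ndarray, X_obs: np.ndarray, X_mis: np.ndarray,
              rf_params: dict | None = None,
              rng: np.random.Generator | None = None) -> np.ndarray:
    """Random-forest imputation.

    Each of ``n_trees`` trees is fitted on a bootstrap resample with
    ``floor(sqrt(p))`` candidate variables per split; every tree contributes
    a donor leaf and the imputed value is drawn uniformly from the pooled
    donors' observed values.
    """
    rng = rng or np.random.default_rng()
    rf_params = rf_params or {}
    y_obs = np.asarray(y_obs, dtype=float)
    n_trees = rf_params.get("n_trees", 10)
    bootstrap = rf_params.get("bootstrap", True)
    p = X_obs.shape[1]
    max_features = rf_params.get("max_features", max(1, int(np.floor(np.sqrt(p)))))
    binary = set(np.unique(y_obs)) <= {0.0, 1.0}
    cls = DecisionTreeClassifier if binary else DecisionTreeRegressor

    n_mis = len(X_mis)
    donor_sets: list[list[np.ndarray]] = []  # per tree: donors per record
    for _ in range(n_trees):
        idx = (rng.integers(len(y_obs), size=len(y_obs))
               if bootstrap else np.arange(len(y_obs)))
        yb, Xb = y_obs[idx], X_obs[idx]
        if binary and np.unique(yb).size < 2:
            donor_sets.append([yb[:1]] * n_mis)
            continue
        tree = cls(min_samples_leaf=rf_params.get("min_samples_leaf", 5),
                   max_features=max_features,
                   random_state=int(rng.integers(2**31)))
        tree.fit(Xb, yb)
        donor_sets.append([yb[d] for d in _leaf_donors(tree, Xb, X_mis)])
    # uniform draw over the pooled multiset of donor values without
    # materializing the concatenation per record
    counts = np.array([[len(donor_sets[t][i]) for t in range(n_trees)]
                       for i in range(n_mis)])
    totals = counts.sum(axis=1)
    picks = rng.integers(totals)
    cum = np.cumsum(counts, axis=1)
    trees = (picks[:, None] >= cum).sum(axis=1)
    within = picks - np.where(trees > 0, cum[np.arange(n_mis), trees - 1], 0)
    return np.array([donor_sets[t][i][w]
                     for i, (t, w) in enumerate(zip(trees, within))])


_IMPUTERS = {"logreg": "logistic", "pmm": "pmm", "cart": "cart", "rf": "rf"}


@dataclass
class ImputedStack:
    """m completed copies of one incomplete cohort."""

    datasets: list[pd.DataFrame]
    spec: ImputationSpec
    chain_means: dict[str, np.ndarray]  # (m, cycles) mean of imputed values
    chain_sds: dict[str, np.ndarray]
    original: pd.DataFrame | None = None

    def to_long(self) -> pd.DataFrame:
        """Long format with an imputation index: .imp 0 is the original
        (incomplete) data, 1..m the completed copies."""
        frames = []
        if self.original is not None:
            f = self.original.copy()
            f.insert(0, ".imp", 0)
            frames.append(f)
        for i, d in enumerate(self.datasets, start=1):
            f = d.copy()
            f.insert(0, ".imp", i)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)


def fcs_impute(data: pd.DataFrame, spec: ImputationSpec) -> ImputedStack:
    """Run chained-equation imputation and return the completed stack.

    Missing entries are NaN.  Each of the ``m`` chains starts from a random
    fill drawn from the observed margins and cycles through the incomplete
    variables in column order, refreshing passive terms implicitly because
    designs are rebuilt from current values at every step.
    """
    spec.validate()
    work_cols = [c for c in data.columns if not c.startswith("M_")]
    base = data[work_cols].copy()
    incomplete = [c for c in work_cols if base[c].isna().any()]
    for var in incomplete:
        if base[var].notna().sum() == 0:
            raise UnimputableVariableError(f"{var} has no observed values")
        if var not in spec.predictor_sets:
            raise ValueError(f"no predictor set for incomplete variable {var}")
        if var not in spec.method_map:
            raise ValueError(f"no imputer for incomplete variable {var}")

    masks = {var: base[var].isna().to_numpy() for var in incomplete}
    streams = np.random.SeedSequence(spec.seed).spawn(spec.m)
    datasets = []
    chain_means = {v: np.zeros((spec.m, spec.max_iter)) for v in incomplete}
    chain_sds = {v: np.zeros((spec.m, spec.max_iter)) for v in incomplete}

    for chain, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        df = base.copy()
        for var in incomplete:
            obs_vals = df[var].dropna().to_numpy()
            df.loc[masks[var], var] = rng.choice(obs_vals, size=masks[var].sum())
        for cycle in range(spec.max_iter):
            for var in incomplete:
                mask = masks[var]
                D = build_design(df, spec.predictor_sets[var])
                D_obs, D_mis = D[~mask], D[mask]
                y_obs = df.loc[~mask, var].to_numpy(dtype=float)
                kind = spec.method_map[var]
                if kind == "logreg":
                    imp = impute_logistic(y_obs, D_obs, D_mis, rng)
                elif kind == "pmm":
                    imp = impute_pmm(y_obs, D_obs, D_mis, spec.donor_k, rng)
                elif kind == "cart":
                    imp = impute_cart(y_obs, D_obs, D_mis, spec.cart_params, rng)
                elif kind == "rf":
                    imp = impute_rf(y_obs, D_obs, D_mis, spec.rf_params, rng)
                else:
                    raise ValueError(f"unknown imputer {kind!r}")
                df.loc[mask, var] = imp
                chain_means[var][chain, cycle] = float(np.mean(imp))
                chain_sds[var][chain, cycle] = float(np.std(imp))
        datasets.append(df)
    return ImputedStack(datasets=datasets, spec=spec,
                        chain_means=chain_means, chain_sds=chain_sds,
                        original=base)


# -- predictor-set builders ----------------------------------------------

def mi_predictor_sets(flavor: str,
                      variables: Sequence[str] = ANALYSIS_VARIABLES,
                      auxiliary: Sequence[str] = ("A",)) -> dict[str, list[str]]:
    """Predictor sets per imputed variable for the parametric/tree flavors.

    ``main``: all other analysis variables plus the auxiliaries.
    ``2way``: adds every pairwise product of analysis variables not
    containing the imputed variable.  ``higher``: additionally all 3- and
    4-way products among Z1, Z3, Z4, Z5 (Z2 never enters interactions).
    """
    sets = {}
    for v in variables:
        terms = [u for u in variables if u != v] + list(auxiliary)
        if flavor in ("2way", "higher"):
            for a, b in combinations(variables, 2):
                if v not in (a, b):
                    terms.append(f"{a}*{b}")
        if flavor == "higher":
            for k in (3, 4):
                for combo in combinations(HIGHER_ORDER_POOL, k):
                    if v not in combo:
                        terms.append("*".join(combo))
        sets[v] = terms
    return sets


def mi_method_map(flavor: str,
                  variables: Sequence[str] = ANALYSIS_VARIABLES) -> dict[str, str]:
    """Imputer per variable: trees for the tree flavors, else logistic for
    binary variables and PMM for the continuous outcome."""
    if flavor in ("cart", "rf"):
        return {v: flavor for v in variables}
    return {v: ("pmm" if v == "Y" else "logreg") for v in variables}


# -- pooling -------------------------------------------------------------

@dataclass
class PooledEstimate:
    psi_bar: float
    W: float          # within-imputation variance
    B: float          # between-imputation variance
    T: float          # total variance
    df: float
    se: float
    ci_low: float
    ci_high: float
    m: int


def rubin_pool(estimates: Sequence[float], ses: Sequence[float],
               alpha: float = 0.05) -> PooledEstimate:
    """Pool per-imputation estimates and SEs by Rubin's rules."""
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    m = len(est)
    if m < 2:
        raise ValueError("Rubin pooling requires at least 2 imputations")
    if (se < 0).any():
        raise ValueError("standard errors must be non-negative")
    psi_bar = float(est.mean())
    W = float(np.mean(se**2))
    B = float(np.var(est, ddof=1))
    if B < 1e-14 * (1.0 + psi_bar**2):  # numerically identical estimates
        B = 0.0
    T = W + (1 + 1 / m) * B
    if B == 0:
        df = np.inf
        q = stats.norm.ppf(1 - alpha / 2)
    else:
        df = (m - 1) * (1 + W / ((1 + 1 / m) * B)) ** 2
        q = stats.t.ppf(1 - alpha / 2, df)
    se_pool = float(np.sqrt(T))
    return PooledEstimate(psi_bar=psi_bar, W=W, B=B, T=T, df=float(df),
                          se=se_pool, ci_low=psi_bar - q * se_pool,
                          ci_high=psi_bar + q * se_pool, m=m)
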