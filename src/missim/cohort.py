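"""Complete-cohort generation with prevalence-calibrated intercepts.

Variables are drawn in causal order A -> Z1..Z5 -> X -> Y, each from its own
random sub-stream so that switching between the simple and complex scenarios
leaves the auxiliary and confounder draws (and the uniform/normal noise used
for X and Y) untouched for a given seed.
"""

from __future__ import annotations

from functools import lru_cache
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .params import (
    ETA_INTERACTIONS,
    THETA_INTERACTIONS,
    TARGET_PREVALENCE,
    ParameterError,
    PopulationParams,
    expit,
    interaction_product,
    logit,
)

COHORT_COLUMNS = ["A", "Z1", "Z2", "Z3", "Z4", "Z5", "X", "Y"]

# Non-intercept defaults of the generating models: moderate conditional
# associations (log-OR / mean shift 0.4-0.5 for confounder effects, with
# completed parental education protective), and interaction coefficients
# inflated four-fold from base values of 0.1 (pairwise) and 0.075
# (higher-order) in the complex scenario.
DEFAULT_ETA_MAIN = {"Z1": 0.5, "Z2": 0.4, "Z3": 0.5, "Z4": 0.5, "Z5": -0.4, "A": 0.3}
DEFAULT_THETA_MAIN = {"Z1": 0.5, "Z2": 0.4, "Z3": 0.6, "Z4": 0.4, "Z5": -0.4}
DEFAULT_ETA_INTERACTION = 0.4
DEFAULT_THETA_INTERACTION_2WAY = 0.4
DEFAULT_THETA_INTERACTION_HIGHER = 0.3
DEFAULT_TRUE_ACE = 0.2

CALIBRATION_N = 200_000
CALIBRATION_TOL = 0.002
_DEFAULT_CALIBRATION_SEED = 190_493


class CalibrationError(RuntimeError):
    """Raised when an intercept calibration cannot reach its target."""

    def __init__(self, message: str, best_intercept: float | None = None,
                 achieved: float | dict | None = None):
        super().__init__(message)
        self.best_intercept = best_intercept
        self.achieved = achieved


class DegenerateTargetError(ValueError):
    """Raised when a prevalence target of exactly 0 or 1 is requested."""


def calibrate_intercept(
    coeffs: np.ndarray,
    covariate_sampler: Callable[[int, np.random.Generator], np.ndarray],
    target_prev: float,
    tol: float = CALIBRATION_TOL,
    n_cal: int = CALIBRATION_N,
    seed: int = 0,
    bracket: tuple[float, float] = (-10.0, 10.0),
    max_iter: int = 200,
) -> float:
    """Find the logistic intercept matching a marginal prevalence.

    Bisection on the expected prevalence ``mean(expit(b + W @ coeffs))``
    over a single fixed covariate draw ``W`` of ``n_cal`` records.  The map
    is strictly monotone in ``b``, so bisection is exact up to ``tol``.  A
    fresh Bernoulli draw verifies the result within Monte-Carlo error.
    """
    if not 0.0 < target_prev < 1.0:
        raise DegenerateTargetError(f"target prevalence {target_prev} is degenerate")
    if n_cal < 10_000:
        raise ValueError("n_cal must be at least 10,000")
    rng = np.random.default_rng(seed)
    W = np.asarray(covariate_sampler(n_cal, rng), dtype=float)
    if W.ndim == 1:
        W = W[:, None]
    coeffs = np.asarray(coeffs, dtype=float)
    lin = W @ coeffs if coeffs.size else np.zeros(n_cal)

    def prev(b: float) -> float:
        return float(np.mean(expit(b + lin)))

    lo, hi = bracket
    if not prev(lo) < target_prev < prev(hi):
        raise CalibrationError(
            f"target {target_prev} not bracketed by intercepts {bracket}",
            achieved=(prev(lo), prev(hi)),
        )
    b = 0.0
    for _ in range(max_iter):
        b = 0.5 * (lo + hi)
        p = prev(b)
        if abs(p - target_prev) <= tol / 2:
            break
        if p < target_prev:
            lo = b
        else:
            hi = b
    else:
        raise CalibrationError(
            f"calibration did not converge for target {target_prev}",
            best_intercept=b, achieved=prev(b),
        )
    # verification with an independent draw; allowance for binomial noise
    check = float(np.mean(rng.random(n_cal) < expit(b + lin)))
    mc_sd = np.sqrt(target_prev * (1 - target_prev) / n_cal)
    if abs(check - target_prev) > tol + 4 * mc_sd:
        raise CalibrationError(
            f"verification draw missed target {target_prev}: got {check}",
            best_intercept=b, achieved=check,
        )
    return float(b)


def _exposure_linear(params: PopulationParams, A, Z):
    eta = params.eta
    lin = (
        eta[0]
        + eta[1] * Z[0] + eta[2] * Z[1] + eta[3] * Z[2]
        + eta[4] * Z[3] + eta[5] * Z[4] + eta[6] * A
    )
    if params.scenario == "complex":
        for coef, idx in zip(eta[7:], ETA_INTERACTIONS):
            lin = lin + coef * interaction_product(Z, idx)
    return lin


def _outcome_linear(params: PopulationParams, X, Z):
    th = params.theta
    lin = (
        th[0] + th[1] * X
        + th[2] * Z[0] + th[3] * Z[1] + th[4] * Z[2]
        + th[5] * Z[3] + th[6] * Z[4]
    )
    if params.scenario == "complex":
        for coef, idx in zip(th[7:], THETA_INTERACTIONS):
            lin = lin + coef * interaction_product(Z, idx)
    return lin


def generate_complete(params: PopulationParams, n: int, seed: int) -> pd.DataFrame:
    """Draw a complete cohort of ``n`` records.

    Returns a data frame with columns A, Z1..Z5, X, Y and the seed recorded
    in ``df.attrs``.  Deterministic given ``(params, n, seed)``.
    """
    if n < 1:
        raise ParameterError("n must be at least 1")
    params.validate()
    streams = np.random.SeedSequence(seed).spawn(8)
    rngs = [np.random.default_rng(s) for s in streams]
    r_a, r_z1, r_z2, r_z3, r_z4, r_z5, r_x, r_y = rngs

    A = r_a.standard_normal(n)
    Z1 = (r_z1.random(n) < expit(np.full(n, params.alpha0))).astype(np.int8)
    Z2 = (r_z2.random(n) < expit(params.beta0 + params.beta1 * A)).astype(np.int8)
    Z3 = (r_z3.random(n) < expit(params.gamma0 + params.gamma1 * A)).astype(np.int8)
    Z4 = (r_z4.random(n) < expit(params.delta0 + params.delta1 * A)).astype(np.int8)
    Z5 = (r_z5.random(n) < expit(np.full(n, params.zeta0))).astype(np.int8)
    Z = [Z1, Z2, Z3, Z4, Z5]

    X = (r_x.random(n) < expit(_exposure_linear(params, A, Z))).astype(np.int8)
    Y = _outcome_linear(params, X, Z) + params.residual_sd * r_y.standard_normal(n)

    df = pd.DataFrame(
        {"A": A, "Z1": Z1, "Z2": Z2, "Z3": Z3, "Z4": Z4, "Z5": Z5, "X": X, "Y": Y}
    )
    df.attrs["seed"] = seed
    df.attrs["scenario"] = params.scenario
    return df


def true_ace(params: PopulationParams) -> float:
    """True average causal effect implied by the generating models.

    Equal to the exposure coefficient of the outcome model: with no
    exposure-confounder interaction the conditional effect is constant, so
    standardizing over any confounder distribution returns the same value.
    """
    params.validate()
    return params.true_ace


def g_computation_ace(params: PopulationParams, n: int = 1_000_000, seed: int = 0) -> float:
    """Large-sample g-computation with the true outcome model.

    Draws ``n`` records and averages ``E[Y|X=1,Z] - E[Y|X=0,Z]`` evaluated
    with the true outcome coefficients.  Serves as a simulation-based check
    of :func:`true_ace`.
    """
    df = generate_complete(params, n, seed)
    Z = [df[f"Z{i}"].to_numpy() for i in range(1, 6)]
    ones = np.ones(n)
    zeros = np.zeros(n)
    return float(np.mean(_outcome_linear(params, ones, Z) - _outcome_linear(params, zeros, Z)))


@lru_cache(maxsize=8)
def default_population_params(
    scenario: str = "simple",
    seed: int = _DEFAULT_CALIBRATION_SEED,
    n_cal: int = CALIBRATION_N,
) -> PopulationParams:
    """Default parameter set with intercepts calibrated to the target table.

    Marginal prevalences of Z1..Z5 and X are matched to the published
    descriptive table; the outcome intercept is chosen so that Y has mean
    approximately zero (it is generated on the z-score scale).
    """
    eta = [0.0] * 13
    for j, name in enumerate(["Z1", "Z2", "Z3", "Z4", "Z5", "A"], start=1):
        eta[j] = DEFAULT_ETA_MAIN[name]
    theta = [0.0] * 18
    theta[1] = DEFAULT_TRUE_ACE
    for j, name in enumerate(["Z1", "Z2", "Z3", "Z4", "Z5"], start=2):
        theta[j] = DEFAULT_THETA_MAIN[name]
    if scenario == "complex":
        eta[7:] = [DEFAULT_ETA_INTERACTION] * 6
        theta[7:13] = [DEFAULT_THETA_INTERACTION_2WAY] * 6
        theta[13:] = [DEFAULT_THETA_INTERACTION_HIGHER] * 5

    p = PopulationParams(scenario=scenario, eta=eta, theta=theta)
    p.alpha0 = float(logit(TARGET_PREVALENCE["Z1"]))
    p.zeta0 = float(logit(TARGET_PREVALENCE["Z5"]))

    a_sampler = lambda m, rng: rng.standard_normal((m, 1))
    p.beta0 = calibrate_intercept(
        [p.beta1], a_sampler, TARGET_PREVALENCE["Z2"], n_cal=n_cal, seed=seed)
    p.gamma0 = calibrate_intercept(
        [p.gamma1], a_sampler, TARGET_PREVALENCE["Z3"], n_cal=n_cal, seed=seed + 1)
    p.delta0 = calibrate_intercept(
        [p.delta1], a_sampler, TARGET_PREVALENCE["Z4"], n_cal=n_cal, seed=seed + 2)

    # exposure intercept: sample upstream covariates from the partially
    # calibrated model, build the exposure design (main + interaction terms)
    def x_sampler(m: int, rng: np.random.Generator) -> np.ndarray:
        df = generate_complete(p, m, int(rng.integers(2**31)))
        Z = [df[f"Z{i}"].to_numpy(dtype=float) for i in range(1, 6)]
        cols = Z + [df["A"].to_numpy()]
        if scenario == "complex":
            cols += [interaction_product(Z, idx) for idx in ETA_INTERACTIONS]
        return np.column_stack(cols)

    p.eta[0] = calibrate_intercept(
        np.asarray(p.eta[1:7] + (p.eta[7:] if scenario == "complex" else [])),
        x_sampler, TARGET_PREVALENCE["X"], n_cal=n_cal, seed=seed + 3)

    # outcome intercept: center Y at zero in the marginal distribution
    df = generate_complete(p, n_cal, seed + 4)
    p.theta[0] = float(p.theta[0] - df["Y"].mean())
    p.validate()
    return p


# -- CSV interface -------------------------------------------------------

def write_cohort_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table; missing entries become empty fields."""
    df.to_csv(path, index=False, float_format="%.6g", na_rep="")


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
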