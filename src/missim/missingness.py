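"""Imposition of missingness via sequential logistic indicator models.

Missingness indicators M_Z2, M_Z3, M_Z4, M_X, M_Y (1 = missing) are drawn in
that order, each conditioning on the cohort variables and on previously drawn
indicators.  Two missingness DAGs are supported: under m-DAG A the outcome
does not influence missingness in any variable (outcome coefficient 0);
under m-DAG B it does (coefficient 0.1, plus a Y^2 coefficient of 0.08 in
the complex model set).  A, Z1 and Z5 are treated as fully observed.

Structural coefficients (confounders, exposure, and exposure-confounder
interactions in the complex set) default to 0.9.  The indicator-on-indicator
coefficients and all intercepts are free and are calibrated jointly so that
per-variable missingness rates and the exclusion fractions of the
deletion-based analysis paths match their targets.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import CalibrationError, DegenerateTargetError, generate_complete
from .params import (
    EXCLUSION_TARGETS,
    MISSINGNESS_TARGETS,
    ParameterError,
    PopulationParams,
    expit,
)

INDICATOR_ORDER = ["M_Z2", "M_Z3", "M_Z4", "M_X", "M_Y"]
MASKED_VARIABLES = {"M_Z2": "Z2", "M_Z3": "Z3", "M_Z4": "Z4", "M_X": "X", "M_Y": "Y"}

# Terms of each indicator model, in equation order.  "1" is the intercept;
# "Y2" the squared outcome; "X*Zk" an exposure-confounder product.  The
# complex2 model set appends the nonlinear/interaction terms.
MODEL_TERMS = {
    "simple": {
        "M_Z2": ["1", "Z1", "Z5", "Z2", "X", "Y"],
        "M_Z3": ["1", "Z1", "Z5", "Z3", "X", "Y", "M_Z2"],
        "M_Z4": ["1", "Z1", "Z5", "Z4", "X", "Y", "M_Z2", "M_Z3"],
        "M_X": ["1", "Z1", "Z5", "Z2", "Z3", "Z4", "X", "Y", "M_Z2", "M_Z3", "M_Z4"],
        "M_Y": ["1", "Z1", "Z5", "Z2", "Z3", "Z4", "X", "Y",
                "M_Z2", "M_Z3", "M_Z4", "M_X"],
    },
    "complex2": {
        "M_Z2": ["1", "Z1", "Z5", "Z2", "X", "Y", "X*Z2", "Y2"],
        "M_Z3": ["1", "Z1", "Z5", "Z3", "X", "Y", "M_Z2", "X*Z3", "Y2"],
        "M_Z4": ["1", "Z1", "Z5", "Z4", "X", "Y", "M_Z2", "M_Z3", "X*Z4", "Y2"],
        "M_X": ["1", "Z1", "Z5", "Z2", "Z3", "Z4", "X", "Y", "M_Z2", "M_Z3", "M_Z4",
                "X*Z2", "X*Z3", "X*Z4", "Y2"],
        "M_Y": ["1", "Z1", "Z5", "Z2", "Z3", "Z4", "X", "Y",
                "M_Z2", "M_Z3", "M_Z4", "M_X", "X*Z2", "X*Z3", "X*Z4"],
    },
}

STRUCTURAL_COEF = 0.9           # confounders, exposure, X*Z products
Y_COEF = {"A": 0.0, "B": 0.1}   # outcome coefficient per m-DAG
Y2_COEF = {"A": 0.0, "B": 0.08}  # squared-outcome coefficient (complex2 only)


@dataclass
class MissingnessParams:
    """Coefficients of the five missingness-indicator models."""

    mdag: str
    model_set: str = "simple"
    models: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.mdag not in ("A", "B"):
            raise ParameterError(f"unknown m-DAG {self.mdag!r}")
        if self.model_set not in MODEL_TERMS:
            raise ParameterError(f"unknown model set {self.model_set!r}")
        terms = MODEL_TERMS[self.model_set]
        for name in INDICATOR_ORDER:
            if name not in self.models:
                raise ParameterError(f"missing model for {name}")
            extra = set(self.models[name]) - set(terms[name])
            if extra:
                raise ParameterError(f"{name} model has unknown terms {extra}")

    def copy(self) -> "MissingnessParams":
        return MissingnessParams(
            mdag=self.mdag, model_set=self.model_set,
            models=copy.deepcopy(self.models),
        )


def default_missingness_params(mdag: str, model_set: str = "simple") -> MissingnessParams:
    """Structural coefficients at their stated values; intercepts and
    indicator-dependence coefficients zero, pending calibration."""
    models: dict[str, dict[str, float]] = {}
    for name, terms in MODEL_TERMS[model_set].items():
        coefs: dict[str, float] = {}
        for t in terms:
            if t == "1":
                coefs[t] = 0.0
            elif t == "Y":
                coefs[t] = Y_COEF[mdag]
            elif t == "Y2":
                coefs[t] = Y2_COEF[mdag]
            elif t.startswith("M_"):
                coefs[t] = 0.0
            else:  # confounders, exposure, X*Z products
                coefs[t] = STRUCTURAL_COEF
        models[name] = coefs
    return MissingnessParams(mdag=mdag, model_set=model_set, models=models)


def _term_column(term: str, cohort: pd.DataFrame, indicators: Mapping[str, np.ndarray]):
    if term == "1":
        return 1.0
    if term == "Y2":
        return cohort["Y"].to_numpy() ** 2
    if term.startswith("M_"):
        return indicators[term]
    if "*" in term:
        a, b = term.split("*")
        return cohort[a].to_numpy(dtype=float) * cohort[b].to_numpy(dtype=float)
    return cohort[term].to_numpy(dtype=float)


def _draw_indicators(cohort: pd.DataFrame, mparams: MissingnessParams,
                     uniforms: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
    indicators: dict[str, np.ndarray] = {}
    for name in INDICATOR_ORDER:
        lin = np.zeros(len(cohort))
        for term, coef in mparams.models[name].items():
            if coef != 0.0:
                lin = lin + coef * _term_column(term, cohort, indicators)
        indicators[name] = (uniforms[name] < expit(lin)).astype(np.int8)
    return indicators


@dataclass
class IncompleteCohort:
    """A cohort with masked entries plus its (internal) complete version.

    ``data`` carries the analysis view: masked columns hold NaN where the
    corresponding indicator is 1, with indicator columns M_Z2..M_Y attached.
    The complete values are retained for oracle checks only and are never
    consumed by the estimators.
    """

    data: pd.DataFrame
    complete: pd.DataFrame
    mparams: MissingnessParams
    seed: int

    @property
    def indicators(self) -> pd.DataFrame:
        return self.data[INDICATOR_ORDER]


def impose_missingness(cohort: pd.DataFrame, mparams: MissingnessParams,
                       seed: int) -> IncompleteCohort:
    """Mask Z2, Z3, Z4, X, Y according to the sequential indicator models."""
    mparams.validate()
    if cohort.isna().any().any():
        raise ParameterError("cohort must be complete before imposing missingness")
    streams = np.random.SeedSequence(seed).spawn(len(INDICATOR_ORDER))
    uniforms = {
        name: np.random.default_rng(s).random(len(cohort))
        for name, s in zip(INDICATOR_ORDER, streams)
    }
    indicators = _draw_indicators(cohort, mparams, uniforms)
    masked = cohort.copy()
    for name, var in MASKED_VARIABLES.items():
        col = masked[var].astype(float).to_numpy()
        col[indicators[name] == 1] = np.nan
        masked[var] = col
    for name in INDICATOR_ORDER:
        masked[name] = indicators[name]
    return IncompleteCohort(data=masked, complete=cohort, mparams=mparams, seed=seed)


# -- calibration ---------------------------------------------------------

# indicator-dependence terms adjusted to control overlap among the
# confounder/exposure indicators (outer dial 1) and between those and the
# outcome indicator (outer dial 2)
_DEP_ZX = [("M_Z3", "M_Z2"), ("M_Z4", "M_Z2"), ("M_Z4", "M_Z3"),
           ("M_X", "M_Z2"), ("M_X", "M_Z3"), ("M_X", "M_Z4")]
_DEP_Y = [("M_Y", "M_Z2"), ("M_Y", "M_Z3"), ("M_Y", "M_Z4"), ("M_Y", "M_X")]


def _marginal_bisect(name: str, target: float, cohort, mparams, uniforms,
                     tol: float, bracket=(-45.0, 45.0), max_iter: int = 100) -> None:
    """Bisect the intercept of one indicator model to its marginal rate.

    Uses common random numbers so the drawn rate is monotone in the
    intercept.  Mutates ``mparams`` in place.
    """
    if not 0.0 < target < 1.0:
        raise DegenerateTargetError(f"degenerate missingness target {target}")
    lo, hi = bracket

    def rate(b: float) -> float:
        mparams.models[name]["1"] = b
        inds = _draw_indicators(cohort, mparams, uniforms)
        return float(inds[name].mean())

    if not rate(lo) < target < rate(hi):
        raise CalibrationError(
            f"marginal target {target} for {name} not bracketed",
            achieved=(rate(lo), rate(hi)))
    for _ in range(max_iter):
        b = 0.5 * (lo + hi)
        r = rate(b)
        if abs(r - target) <= tol:
            return
        if r < target:
            lo = b
        else:
            hi = b
    raise CalibrationError(
        f"marginal calibration for {name} did not converge",
        best_intercept=b, achieved=r)


def calibrate_missingness_intercepts(
    cohort: pd.DataFrame,
    mparams: MissingnessParams,
    marginal_targets: Mapping[str, float] | None = None,
    exclusion_targets: Mapping[str, float] | None = None,
    tol: float = 0.002,
    union_tol: float = 0.004,
    seed: int = 0,
) -> tuple[MissingnessParams, dict[str, float]]:
    """Calibrate intercepts and overlap coefficients on a reference cohort.

    Two nested loops: the per-variable intercepts are bisected to the
    marginal missingness targets; around these, a shared dependence
    coefficient on the prior indicators of the Z/X models is bisected so
    that the fraction of records with any of Z2, Z3, Z4, X missing hits its
    exclusion target (overlap grows with the coefficient, shrinking the
    union), and a second shared coefficient in the M_Y model controls the
    complete-case exclusion fraction.

    Returns the calibrated parameters and the achieved proportions.
    """
    marginal_targets = dict(marginal_targets or MISSINGNESS_TARGETS)
    exclusion_targets = dict(exclusion_targets or EXCLUSION_TARGETS)
    mp = mparams.copy()
    n = len(cohort)
    rng = np.random.default_rng(seed)
    uniforms = {name: rng.random(n) for name in INDICATOR_ORDER}

    # M_X marginal equals the exposure-deletion exclusion fraction
    marginal_targets["M_X"] = exclusion_targets.get("x_missing", marginal_targets["M_X"])

    def set_dep(pairs, value: float) -> None:
        for model, term in pairs:
            mp.models[model][term] = value

    def calibrate_marginals(names) -> None:
        for name in names:
            _marginal_bisect(name, marginal_targets[name], cohort, mp, uniforms, tol)

    def unions() -> tuple[float, float]:
        inds = _draw_indicators(cohort, mp, uniforms)
        zx = (inds["M_Z2"] | inds["M_Z3"] | inds["M_Z4"] | inds["M_X"]).astype(bool)
        any_ = zx | inds["M_Y"].astype(bool)
        return float(zx.mean()), float(any_.mean())

    def zx_union_at(d: float) -> float:
        set_dep(_DEP_ZX, d)
        calibrate_marginals(["M_Z2", "M_Z3", "M_Z4", "M_X"])
        return unions()[0]

    target_zx = exclusion_targets["zx_missing"]
    lo, hi = 0.0, 8.0
    u_lo, u_hi = zx_union_at(lo), zx_union_at(hi)
    if not (u_hi - union_tol <= target_zx <= u_lo + union_tol):
        raise CalibrationError(
            f"exclusion target {target_zx} infeasible; achievable range "
            f"({u_hi:.4f}, {u_lo:.4f})", achieved={"zx": (u_hi, u_lo)})
    for _ in range(60):
        d = 0.5 * (lo + hi)
        u = zx_union_at(d)
        if abs(u - target_zx) <= union_tol:
            break
        if u > target_zx:
            lo = d  # more overlap needed
        else:
            hi = d
    else:
        raise CalibrationError("joint calibration (Z/X overlap) did not converge",
                               achieved={"zx_union": u})

    def any_union_at(d: float) -> float:
        set_dep(_DEP_Y, d)
        calibrate_marginals(["M_Y"])
        return unions()[1]

    target_any = exclusion_targets["any_missing"]
    lo, hi = -6.0, 8.0
    u_lo, u_hi = any_union_at(lo), any_union_at(hi)
    if not (u_hi - union_tol <= target_any <= u_lo + union_tol):
        raise CalibrationError(
            f"exclusion target {target_any} infeasible; achievable range "
            f"({u_hi:.4f}, {u_lo:.4f})", achieved={"any": (u_hi, u_lo)})
    for _ in range(60):
        d = 0.5 * (lo + hi)
        u = any_union_at(d)
        if abs(u - target_any) <= union_tol:
            break
        if u > target_any:
            lo = d
        else:
            hi = d
    else:
        raise CalibrationError("joint calibration (Y overlap) did not converge",
                               achieved={"any_union": u})

    inds = _draw_indicators(cohort, mp, uniforms)
    zx_u, any_u = unions()
    achieved = {name: float(inds[name].mean()) for name in INDICATOR_ORDER}
    achieved["zx_missing"] = zx_u
    achieved["any_missing"] = any_u
    return mp, achieved


_calibration_cache: dict[tuple, MissingnessParams] = {}


def calibrated_missingness(
    pop_params: PopulationParams,
    mdag: str,
    model_set: str = "simple",
    n_cal: int = 200_000,
    seed: int = 57_221,
) -> MissingnessParams:
    """Convenience wrapper: default structure calibrated on a fresh cohort.

    Results are memoized per parameter set within a process, since the
    calibration is deterministic and takes several seconds.
    """
    key = (repr(sorted(pop_params.to_dict().items())), mdag, model_set,
           n_cal, seed)
    if key not in _calibration_cache:
        cohort = generate_complete(pop_params, n_cal, seed)
        base = default_missingness_params(mdag, model_set)
        mp, _ = calibrate_missingness_intercepts(cohort, base, seed=seed + 1)
        _calibration_cache[key] = mp
    return _calibration_cache[key].copy()
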