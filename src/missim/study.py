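"""Dispatch of the eight missing-data methods and the replication grid.

The eight methods are: complete-case analysis (CCA); extended TMLE on the
subsample with complete exposure and confounders (Ext-TMLE+CEC); extended
TMLE plus the missing covariate missing indicator device (Ext-TMLE+MCMI);
and five chained-equation MI flavors (main effects, 2-way interactions,
2/3/4-way interactions, CART, random forest), each followed by TMLE within
every completed data set and Rubin pooling.

The replication grid crosses the data-generating scenarios (simple,
complex1, complex2) with the two missingness DAGs; performance per cell is
summarized as percent relative bias, empirical SE and percent error of the
model-based SE, each with a Monte-Carlo standard error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import default_population_params, generate_complete, true_ace
from .mi import (
    ImputationSpec,
    fcs_impute,
    mi_method_map,
    mi_predictor_sets,
    rubin_pool,
)
from .missingness import (
    IncompleteCohort,
    calibrated_missingness,
    impose_missingness,
)
from .superlearner import DEFAULT_LIBRARY
from .tmle import (
    DEFAULT_ADJUSTMENT,
    EstimateResult,
    TmleConfig,
    estimate_ate_ext_tmle,
    estimate_ate_tmle,
)

logger = logging.getLogger("missim")

MASKABLE = ["Z2", "Z3", "Z4", "X", "Y"]


class MethodID(str, Enum):
    CCA = "CCA"
    EXT_TMLE_CEC = "Ext-TMLE+CEC"
    EXT_TMLE_MCMI = "Ext-TMLE+MCMI"
    MI_NO_INT = "MI-no int"
    MI_2WAY_INT = "MI-2-way int"
    MI_HIGHER_INT = "MI-higher int"
    MI_CART = "MI-CART"
    MI_RF = "MI-RF"


ALL_METHODS = list(MethodID)

_MI_FLAVOR = {
    MethodID.MI_NO_INT: "main",
    MethodID.MI_2WAY_INT: "2way",
    MethodID.MI_HIGHER_INT: "higher",
    MethodID.MI_CART: "cart",
    MethodID.MI_RF: "rf",
}

# grid scenario -> (generation scenario, missingness model set)
SCENARIO_MAP = {
    "simple": ("simple", "simple"),
    "complex1": ("complex", "simple"),
    "complex2": ("complex", "complex2"),
}


@dataclass
class StudyConfig:
    """Settings shared by every method in a run."""

    library: Sequence[str] = tuple(DEFAULT_LIBRARY)
    v_folds: int = 5
    m: int = 5
    mi_cycles: int = 5
    donor_k: int = 5
    g_bounds: tuple[float, float] = (0.01, 0.99)
    pi_bounds: tuple[float, float] = (0.01, 0.99)
    seed: int = 0

    def tmle(self, seed: int | None = None) -> TmleConfig:
        return TmleConfig(library=self.library, v_folds=self.v_folds,
                          g_bounds=self.g_bounds, pi_bounds=self.pi_bounds,
                          seed=self.seed if seed is None else seed)


def _as_frame(data) -> pd.DataFrame:
    if isinstance(data, IncompleteCohort):
        return data.data
    return data


def _with_indicators(df: pd.DataFrame) -> pd.DataFrame:
    """Ensure M_* columns exist, deriving them from NaN patterns if needed."""
    df = df.copy()
    for var in MASKABLE:
        col = f"M_{var}"
        if col not in df.columns:
            df[col] = df[var].isna().astype(np.int8)
    return df


def apply_method(method: MethodID | str, data, config: StudyConfig | None = None,
                 ) -> EstimateResult:
    """Apply one missing-data method and estimate the ACE.

    ``data`` is an incomplete cohort (NaN marks missing entries).  The
    auxiliary variable ``A`` participates only in imputation models, never
    in the confounding adjustment set.
    """
    method = MethodID(method)
    config = config or StudyConfig()
    df = _with_indicators(_as_frame(data))
    seeds = np.random.SeedSequence(config.seed).generate_state(2) % (2**31)

    if method is MethodID.CCA:
        keep = df[MASKABLE].notna().all(axis=1)
        sub = df.loc[keep]
        if sub.empty:
            raise ValueError("no complete cases remain")
        res = estimate_ate_tmle(sub, config.tmle(int(seeds[0])),
                                method=method.value)
        res.diagnostics["n_excluded"] = int(len(df) - keep.sum())
        return res

    if method is MethodID.EXT_TMLE_CEC:
        keep = df[["Z2", "Z3", "Z4", "X"]].notna().all(axis=1)
        sub = df.loc[keep]
        if sub.empty:
            raise ValueError("no records with complete exposure and confounders")
        res = estimate_ate_ext_tmle(sub, config.tmle(int(seeds[0])),
                                    method=method.value)
        res.diagnostics["n_excluded"] = int(len(df) - keep.sum())
        return res

    if method is MethodID.EXT_TMLE_MCMI:
        keep = df["X"].notna()
        sub = df.loc[keep].copy()
        if sub.empty:
            raise ValueError("no records with observed exposure")
        for z in ("Z2", "Z3", "Z4"):
            sub[z] = sub[z].fillna(0.0)  # placeholder; indicator carries signal
        adjustment = DEFAULT_ADJUSTMENT + ["M_Z2", "M_Z3", "M_Z4"]
        res = estimate_ate_ext_tmle(sub, config.tmle(int(seeds[0])),
                                    adjustment=adjustment, method=method.value)
        res.diagnostics["n_excluded"] = int(len(df) - keep.sum())
        return res

    # MI methods
    flavor = _MI_FLAVOR[method]
    spec = ImputationSpec(
        m=config.m, max_iter=config.mi_cycles,
        method_map=mi_method_map(flavor),
        predictor_sets=mi_predictor_sets(flavor),
        donor_k=config.donor_k, seed=int(seeds[1]))
    analysis_cols = ["A", "Z1", "Z2", "Z3", "Z4", "Z5", "X", "Y"]
    stack = fcs_impute(df[analysis_cols], spec)
    estimates, ses = [], []
    for completed in stack.datasets:
        r = estimate_ate_tmle(completed, config.tmle(int(seeds[0])),
                              method=method.value)
        estimates.append(r.psi)
        ses.append(r.se)
    pooled = rubin_pool(estimates, ses)
    return EstimateResult(
        psi=pooled.psi_bar, se=pooled.se, ci_low=pooled.ci_low,
        ci_high=pooled.ci_high, method=method.value, n_analyzed=len(df),
        diagnostics={"W": pooled.W, "B": pooled.B, "df": pooled.df,
                     "m": pooled.m, "per_imputation_psi": estimates})


# -- performance metrics -------------------------------------------------

@dataclass
class PerformanceMetrics:
    rel_bias_pct: float
    rel_bias_mcse: float
    emp_se: float
    emp_se_mcse: float
    model_se: float
    model_se_err_pct: float
    model_se_err_mcse: float
    n_sim: int
    n_failed: int = 0

    def to_row(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


class RelativeBiasUndefinedError(ZeroDivisionError):
    """Relative bias is undefined for a zero true value."""


def compute_metrics(estimates: Sequence[float], model_ses: Sequence[float],
                    truth: float, n_failed: int = 0) -> PerformanceMetrics:
    """Standard simulation performance metrics with Monte-Carlo SEs.

    Percent relative bias, empirical SE (SD of the estimates) and percent
    error of the average model-based SE, where the model-SE summary is the
    root mean square of the per-replicate SEs.
    """
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(model_ses, dtype=float)
    n = len(est)
    if n < 2:
        raise ValueError("at least 2 estimates are required")
    if truth == 0:
        raise RelativeBiasUndefinedError(
            f"truth is 0; absolute bias is {est.mean():.6g}")
    emp_se = float(np.std(est, ddof=1))
    rel_bias = 100.0 * (est.mean() - truth) / truth
    rel_bias_mcse = 100.0 * emp_se / (abs(truth) * np.sqrt(n))
    emp_se_mcse = emp_se / np.sqrt(2 * (n - 1))
    model_se = float(np.sqrt(np.mean(se**2)))
    err = 100.0 * (model_se / emp_se - 1.0)
    # delta method: variance of mean(se^2) plus sampling noise of emp SE
    var_mean_se2 = np.var(se**2, ddof=1) / n
    err_mcse = 100.0 * (model_se / emp_se) * np.sqrt(
        var_mean_se2 / (4 * model_se**4) + 1.0 / (2 * (n - 1)))
    return PerformanceMetrics(
        rel_bias_pct=float(rel_bias), rel_bias_mcse=float(rel_bias_mcse),
        emp_se=emp_se, emp_se_mcse=float(emp_se_mcse), model_se=model_se,
        model_se_err_pct=float(err), model_se_err_mcse=float(err_mcse),
        n_sim=n, n_failed=n_failed)


def rejection_rate(estimates: Sequence[float], model_ses: Sequence[float],
                   alpha: float = 0.05) -> float:
    """Fraction of replicates rejecting the null of no effect."""
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(model_ses, dtype=float)
    if len(est) != len(se):
        raise ValueError("estimates and SEs must have equal length")
    ok = se > 0
    if not ok.all():
        import warnings
        warnings.warn(f"excluding {int((~ok).sum())} replicates with zero SE")
    z = stats.norm.ppf(1 - alpha / 2)
    return float(np.mean(np.abs(est[ok] / se[ok]) > z))


# -- replication grid ----------------------------------------------------

@dataclass
class SimulationSummary:
    scenario: str
    mdag: str
    metrics: dict[str, PerformanceMetrics]
    truth: float
    n_sim: int
    n: int
    root_seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for method, m in self.metrics.items():
            row = {"scenario": self.scenario, "mdag": self.mdag,
                   "method": method, "truth": self.truth, **m.to_row()}
            rows.append(row)
        return pd.DataFrame(rows)


def run_cell(scenario: str, mdag: str, methods: Iterable[MethodID | str],
             n_sim: int, n: int, root_seed: int,
             config: StudyConfig | None = None,
             pop_params=None, mparams=None) -> pd.DataFrame:
    """Run one scenario x m-DAG cell; returns one row per method/replicate."""
    config = config or StudyConfig()
    gen_scenario, model_set = SCENARIO_MAP[scenario]
    if pop_params is None:
        pop_params = default_population_params(gen_scenario)
    if mparams is None:
        mparams = calibrated_missingness(pop_params, mdag, model_set)
    methods = [MethodID(m) for m in methods]
    rows = []
    rep_seeds = np.random.SeedSequence(root_seed).generate_state(2 * n_sim) % (2**31)
    for rep in range(n_sim):
        cohort = generate_complete(pop_params, n, int(rep_seeds[2 * rep]))
        inc = impose_missingness(cohort, mparams, int(rep_seeds[2 * rep + 1]))
        for method in methods:
            rec = {"scenario": scenario, "mdag": mdag, "method": method.value,
                   "replicate": rep}
            try:
                cfg = replace(config, seed=int(rep_seeds[2 * rep]) ^ 0x5A5A5A)
                res = apply_method(method, inc, cfg)
                rec.update(psi=res.psi, se=res.se, ci_low=res.ci_low,
                           ci_high=res.ci_high, n_analyzed=res.n_analyzed,
                           eps=res.diagnostics.get("eps", np.nan),
                           failed=False, note="")
            except Exception as exc:
                logger.warning("replicate %d method %s failed: %s",
                               rep, method.value, exc)
                rec.update(psi=np.nan, se=np.nan, ci_low=np.nan,
                           ci_high=np.nan, n_analyzed=0, eps=np.nan,
                           failed=True, note=str(exc))
            rows.append(rec)
        if (rep + 1) % 25 == 0:
            logger.info("%s/m-DAG %s: replicate %d/%d done",
                        scenario, mdag, rep + 1, n_sim)
    return pd.DataFrame(rows)


def summarize_cell(results: pd.DataFrame, truth: float) -> dict[str, PerformanceMetrics]:
    out = {}
    for method, grp in results.groupby("method", sort=False):
        ok = ~grp["failed"]
        if ok.sum() < 2:
            logger.warning("cell summary for %s invalid: %d successes",
                           method, int(ok.sum()))
            continue
        out[method] = compute_metrics(
            grp.loc[ok, "psi"], grp.loc[ok, "se"], truth,
            n_failed=int((~ok).sum()))
    return out


def run_grid(scenarios: Sequence[str], mdags: Sequence[str],
             methods: Iterable[MethodID | str], n_sim: int, n: int,
             root_seed: int, config: StudyConfig | None = None
             ) -> tuple[pd.DataFrame, list[SimulationSummary]]:
    """Run the full scenario x m-DAG grid.

    Replicate seeds are derived deterministically from ``root_seed`` and the
    cell position, so re-running with the same seed reproduces the results
    table exactly.
    """
    if n_sim < 2:
        raise ValueError("n_sim must be at least 2")
    config = config or StudyConfig()
    methods = [MethodID(m) for m in methods]
    all_results = []
    summaries = []
    cell_seeds = np.random.SeedSequence(root_seed).generate_state(
        len(scenarios) * len(mdags)) % (2**31)
    idx = 0
    for scenario in scenarios:
        gen_scenario, model_set = SCENARIO_MAP[scenario]
        pop_params = default_population_params(gen_scenario)
        truth = true_ace(pop_params)
        for mdag in mdags:
            mparams = calibrated_missingness(pop_params, mdag, model_set)
            res = run_cell(scenario, mdag, methods, n_sim, n,
                           int(cell_seeds[idx]), config,
                           pop_params=pop_params, mparams=mparams)
            all_results.append(res)
            summaries.append(SimulationSummary(
                scenario=scenario, mdag=mdag,
                metrics=summarize_cell(res, truth), truth=truth,
                n_sim=n_sim, n=n, root_seed=root_seed))
            idx += 1
    return pd.concat(all_results, ignore_index=True), summaries
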