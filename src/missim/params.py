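"""Parameter containers for the data-generating and missingness models.

The synthetic cohort emulates a female adolescent cohort (n = 1000 in the
motivating study) with one continuous auxiliary variable ``A`` (standardized
age), five binary confounders ``Z1``-``Z5`` (parental divorce, antisocial
behavior, depression/anxiety, alcohol use, parental education), a binary
exposure ``X`` (frequent cannabis use) and a continuous standardized outcome
``Y`` (mental-health score on the z-score scale).

All binary variables are generated from logistic models and the outcome from
a linear model with unit residual SD.  Intercepts are not hard-coded: they
are calibrated by simulation so that marginal prevalences match the published
descriptive table (see :mod:`missim.cohort`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

# Marginal prevalences of the binary variables in the motivating cohort.
TARGET_PREVALENCE = {
    "Z1": 0.221,  # parental divorce
    "Z2": 0.146,  # antisocial behavior
    "Z3": 0.599,  # depression and anxiety
    "Z4": 0.372,  # alcohol use
    "Z5": 0.377,  # parental education
    "X": 0.124,   # frequent cannabis use
}

# Per-variable missingness proportions targeted by the simulation: the
# confounder rates mirror the motivating cohort; exposure missingness is set
# to 30% and outcome missingness raised to 20%.
MISSINGNESS_TARGETS = {
    "M_Z2": 0.274,
    "M_Z3": 0.138,
    "M_Z4": 0.210,
    "M_X": 0.30,
    "M_Y": 0.20,
}

# Fractions of records excluded by the three deletion-based analysis paths:
# complete-case (any of Z2, Z3, Z4, X, Y missing), complete exposure and
# confounders (any of Z2, Z3, Z4, X missing), and exposure-only deletion.
EXCLUSION_TARGETS = {"any_missing": 0.50, "zx_missing": 0.40, "x_missing": 0.30}

SCENARIOS = ("simple", "complex")

# Index pairs/tuples (into Z1..Z5) of the confounder-confounder interaction
# products entering the complex exposure and outcome models.  Z2 is excluded
# from every interaction because of its low prevalence.
ETA_INTERACTIONS = [(1, 3), (1, 4), (1, 5), (3, 4), (3, 5), (4, 5)]
THETA_INTERACTIONS = ETA_INTERACTIONS + [
    (1, 3, 4),
    (1, 3, 5),
    (1, 4, 5),
    (3, 4, 5),
    (1, 3, 4, 5),
]


class ParameterError(ValueError):
    """Raised when a parameter set violates its structural invariants."""


@dataclass
class PopulationParams:
    """Coefficients of the cohort data-generating models.

    ``eta`` holds the 13 exposure-model log-odds coefficients
    (intercept, Z1..Z5, A, then the six pairwise interactions); ``theta``
    holds the 18 outcome-model coefficients (intercept, X, Z1..Z5, then the
    six pairwise, four three-way and one four-way interactions).  In the
    simple scenario every interaction coefficient is zero.

    ``theta[1]`` is, by construction, the true average causal effect: the
    outcome model contains no exposure-confounder interaction, so the
    conditional effect of ``X`` is constant across covariate strata.
    """

    alpha0: float = 0.0            # Z1 ~ logit^-1(alpha0)
    beta0: float = 0.0             # Z2 ~ logit^-1(beta0 + beta1*A)
    beta1: float = 0.3
    gamma0: float = 0.0            # Z3 ~ logit^-1(gamma0 + gamma1*A)
    gamma1: float = 0.3
    delta0: float = 0.0            # Z4 ~ logit^-1(delta0 + delta1*A)
    delta1: float = 0.3
    zeta0: float = 0.0             # Z5 ~ logit^-1(zeta0)
    eta: list[float] = field(default_factory=lambda: [0.0] * 13)
    theta: list[float] = field(default_factory=lambda: [0.0] * 18)
    residual_sd: float = 1.0
    scenario: str = "simple"

    def __post_init__(self) -> None:
        self.eta = [float(v) for v in self.eta]
        self.theta = [float(v) for v in self.theta]
        self.validate()

    def validate(self) -> None:
        if self.residual_sd <= 0:
            raise ParameterError("residual_sd must be positive")
        if self.scenario not in SCENARIOS:
            raise ParameterError(f"unknown scenario {self.scenario!r}")
        if len(self.eta) != 13:
            raise ParameterError("eta must have 13 coefficients")
        if len(self.theta) != 18:
            raise ParameterError("theta must have 18 coefficients")
        if self.scenario == "simple":
            if any(v != 0.0 for v in self.eta[7:]):
                raise ParameterError("simple scenario requires eta7..eta12 = 0")
            if any(v != 0.0 for v in self.theta[7:]):
                raise ParameterError("simple scenario requires theta7..theta17 = 0")

    @property
    def true_ace(self) -> float:
        """The average causal effect implied by the outcome model."""
        return self.theta[1]

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationParams":
        return cls(**d)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def from_file(cls, path: str | Path) -> "PopulationParams":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)


def logit(p: float | np.ndarray) -> float | np.ndarray:
    return np.log(p / (1.0 - p))


def expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def interaction_product(z_cols: Sequence[np.ndarray], idx: Sequence[int]) -> np.ndarray:
    """Product of the Z columns named by 1-based indices ``idx``."""
    out = np.ones_like(np.asarray(z_cols[0], dtype=float))
    for i in idx:
        out = out * z_cols[i - 1]
    return out
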