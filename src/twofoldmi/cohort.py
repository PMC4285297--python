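"""Synthetic primary-care-like cohort generator and the consultation
driven MCAR missingness mechanism.

The generator produces a complete panel of male-cohort risk factors over
T annual blocks plus an exponential time-to-event outcome whose hazard
depends on the first-block covariate values.  Two mechanisms differ in
how smoking status evolves:

* mechanism I  — smoking is generated once and held constant
  (time-independent);
* mechanism II — about half the cohort are constant non-smokers; the
  rest alternate between current smoker and ex-smoker from a random
  initial state, which exercises time-dependent categorical imputation.

Weight and systolic blood pressure are stationary Gaussian processes
(patient-level shared factor + AR(1) residual) calibrated so their
block-1 to block-2 correlations hit configurable targets, with a
cross-sectional weight/SBP correlation induced by the shared factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

from .panel import (
    BINARY,
    CATEGORICAL,
    CONTINUOUS,
    LongitudinalPanel,
    PanelError,
    SurvivalOutcome,
    VariableSpec,
)

__all__ = [
    "DgmConfig",
    "TRUE_COEFFICIENTS",
    "SUBSTANTIVE_COVARIATES",
    "default_specs",
    "generate_cohort",
    "impose_mcar",
    "expected_observation_gap",
]

AGE_LEVELS = ("40-44", "45-49", "50-54", "55-59", "60-64", "65-69", "70-74", "75-79", "80+")
AGE_PROBS = (0.17, 0.16, 0.15, 0.13, 0.11, 0.09, 0.08, 0.06, 0.05)
TOWNSEND_LEVELS = ("1", "2", "3", "4", "5")
SMOKING_LEVELS = ("non-smoker", "ex-smoker", "current-smoker")
SMOKING_PROBS_I = (0.5, 0.3, 0.2)

#: Covariates of the substantive hazard model, in reporting order.
SUBSTANTIVE_COVARIATES = ["townsend", "weight", "sbp", "antihyp", "smoking", "age_group"]

#: True log-hazard-ratio coefficients used by the generator, keyed by the
#: design-column names produced by :func:`twofoldmi.survival.build_design`.
TRUE_COEFFICIENTS: dict[str, float] = {
    "constant": -5.1993,
    "townsend[2]": 0.1520,
    "townsend[3]": 0.2377,
    "townsend[4]": 0.2433,
    "townsend[5]": 0.4034,
    "weight": 0.0019,
    "sbp": 0.0048,
    "antihyp[yes]": 0.2935,
    "smoking[ex-smoker]": 0.0679,
    "smoking[current-smoker]": 0.2386,
    "age_group[40-44]": -1.2820,
    "age_group[45-49]": -1.0632,
    "age_group[50-54]": -0.6402,
    "age_group[55-59]": -0.3589,
    "age_group[60-64]": -0.2485,
    "age_group[65-69]": -0.0396,
    "age_group[75-79]": 0.1108,
    "age_group[80+]": 0.1387,
}


@dataclass(frozen=True)
class DgmConfig:
    """Generator settings; defaults reproduce the reference scenario."""

    n_patients: int = 5000
    n_blocks: int = 10
    mechanism: str = "I"  # "I" or "II"
    weight_mean: float = 82.0
    weight_sd: float = 14.0
    weight_lag1: float = 0.96
    sbp_mean: float = 138.0
    sbp_sd: float = 18.0
    sbp_lag1: float = 0.65
    cross_corr: float = 0.2  # cross-sectional corr(weight, sbp) via shared factor
    p_consult: float = 0.3
    p_unrecorded: float = 0.05
    censor_horizon: Optional[float] = None  # default: n_blocks - 1 years
    p_new_registration: float = 0.1
    antihyp_slope: float = 0.04  # on (sbp_1 - sbp_mean), logit scale
    antihyp_intercept: float = -1.1
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_blocks < 2:
            raise PanelError("need n_patients >= 1 and n_blocks >= 2")
        if self.mechanism not in ("I", "II"):
            raise PanelError("mechanism must be 'I' or 'II'")
        for p in (self.p_consult, self.p_unrecorded, self.p_new_registration):
            if not 0.0 <= p <= 1.0:
                raise PanelError("probabilities must lie in [0, 1]")
        for rho in (self.weight_lag1, self.sbp_lag1):
            if not -1.0 < rho < 1.0:
                raise PanelError("lag-1 correlation targets must lie in (-1, 1)")
        if not 0.0 <= self.cross_corr < min(self.weight_lag1, self.sbp_lag1):
            raise PanelError("cross_corr must be < both lag-1 targets (shared-factor model)")

    @property
    def horizon(self) -> float:
        # time runs from the start of block 2 to the end of block T
        return self.censor_horizon if self.censor_horizon is not None else self.n_blocks - 1.0


def default_specs(mechanism: str = "I") -> list[VariableSpec]:
    """Variable schema for the generated cohort."""
    smoking_td = mechanism == "II"
    return [
        VariableSpec("age_group", CATEGORICAL, AGE_LEVELS, time_dependent=False,
                     imputable=False, reference="70-74"),
        VariableSpec("townsend", CATEGORICAL, TOWNSEND_LEVELS, time_dependent=False,
                     imputable=False, reference="1"),
        VariableSpec("new_registration", BINARY, ("no", "yes"), time_dependent=False,
                     imputable=False),
        VariableSpec("antihyp", BINARY, ("no", "yes"), time_dependent=False,
                     imputable=False),
        VariableSpec(
            "smoking", CATEGORICAL, SMOKING_LEVELS,
            time_dependent=smoking_td, imputable=True, reference="non-smoker",
            anchor_level="non-smoker" if smoking_td else None,
        ),
        VariableSpec("weight", CONTINUOUS, time_dependent=True),
        VariableSpec("sbp", CONTINUOUS, time_dependent=True),
    ]


def _stationary_process(
    n: int, t: int, shared: np.ndarray, mean: float, sd: float,
    lag1: float, cross: float, rng: np.random.Generator,
) -> np.ndarray:
    """Shared-factor + AR(1) trajectories with marginal N(mean, sd^2),
    lag-1 autocorrelation ``lag1`` and shared-factor loading sqrt(cross)."""
    rho = (lag1 - cross) / (1.0 - cross)  # AR(1) coefficient of the residual
    a = np.empty((n, t))
    a[:, 0] = rng.standard_normal(n)
    innov_sd = np.sqrt(1.0 - rho**2)
    for j in range(1, t):
        a[:, j] = rho * a[:, j - 1] + innov_sd * rng.standard_normal(n)
    f_load = sd * np.sqrt(cross)
    a_load = sd * np.sqrt(1.0 - cross)
    return mean + f_load * shared[:, None] + a_load * a


def generate_cohort(config: DgmConfig,
                    rng: Optional[np.random.Generator] = None
                    ) -> tuple[LongitudinalPanel, SurvivalOutcome]:
    """Generate one complete cohort and its time-to-event outcome."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, t = config.n_patients, config.n_blocks
    specs = default_specs(config.mechanism)
    panel = LongitudinalPanel(np.arange(1, n + 1), range(1, t + 1), specs)
    all_rows = np.ones(n, dtype=bool)

    age = rng.choice(len(AGE_LEVELS), size=n, p=np.asarray(AGE_PROBS))
    panel.set_cells("age_group", all_rows, age.astype(np.int16))
    townsend = rng.integers(0, len(TOWNSEND_LEVELS), size=n)
    panel.set_cells("townsend", all_rows, townsend.astype(np.int16))
    newreg = (rng.random(n) < config.p_new_registration).astype(np.int16)
    panel.set_cells("new_registration", all_rows, newreg)

    shared = rng.standard_normal(n)
    weight = _stationary_process(n, t, shared, config.weight_mean, config.weight_sd,
                                 config.weight_lag1, config.cross_corr, rng)
    sbp = _stationary_process(n, t, shared, config.sbp_mean, config.sbp_sd,
                              config.sbp_lag1, config.cross_corr, rng)
    panel.set_cells("weight", np.ones((n, t), dtype=bool), weight)
    panel.set_cells("sbp", np.ones((n, t), dtype=bool), sbp)

    p_treat = expit(config.antihyp_intercept
                    + config.antihyp_slope * (sbp[:, 0] - config.sbp_mean))
    antihyp = (rng.random(n) < p_treat).astype(np.int16)
    panel.set_cells("antihyp", all_rows, antihyp)

    non, ex, cur = 0, 1, 2  # codes of SMOKING_LEVELS
    if config.mechanism == "I":
        smoke = rng.choice(3, size=n, p=np.asarray(SMOKING_PROBS_I)).astype(np.int16)
        panel.set_cells("smoking", all_rows, smoke)
        smoke_baseline = smoke
    else:
        is_non = rng.random(n) < 0.5
        start_current = rng.random(n) < 0.5  # initial state of alternators
        states = np.empty((n, t), dtype=np.int16)
        for j in range(t):
            alt = np.where((start_current ^ (j % 2 == 1)), cur, ex)
            states[:, j] = np.where(is_non, non, alt)
        panel.set_cells("smoking", np.ones((n, t), dtype=bool), states)
        smoke_baseline = states[:, 0]

    # hazard from first-block covariates
    eta = np.full(n, TRUE_COEFFICIENTS["constant"])
    for lev in TOWNSEND_LEVELS[1:]:
        eta += TRUE_COEFFICIENTS[f"townsend[{lev}]"] * (townsend == TOWNSEND_LEVELS.index(lev))
    eta += TRUE_COEFFICIENTS["weight"] * weight[:, 0]
    eta += TRUE_COEFFICIENTS["sbp"] * sbp[:, 0]
    eta += TRUE_COEFFICIENTS["antihyp[yes]"] * antihyp
    eta += TRUE_COEFFICIENTS["smoking[ex-smoker]"] * (smoke_baseline == ex)
    eta += TRUE_COEFFICIENTS["smoking[current-smoker]"] * (smoke_baseline == cur)
    for i, lev in enumerate(AGE_LEVELS):
        if lev == "70-74":
            continue
        eta += TRUE_COEFFICIENTS[f"age_group[{lev}]"] * (age == i)

    raw_time = rng.exponential(1.0, size=n) / np.exp(eta)
    horizon = config.horizon
    event = (raw_time <= horizon).astype(np.int8)
    time = np.minimum(raw_time, horizon)
    panel.validate()
    return panel, SurvivalOutcome(event, time)


def impose_mcar(
    panel: LongitudinalPanel,
    p_consult: float,
    p_unrecorded: float,
    rng: np.random.Generator,
    targets: Optional[Sequence[str]] = None,
) -> LongitudinalPanel:
    """Consultation-driven MCAR missingness.

    One consultation indicator is drawn per patient-block.  In a block
    without consultation every targeted time-dependent variable is
    missing; given consultation each is independently unrecorded with
    probability ``p_unrecorded``.  A targeted time-independent variable
    (smoking under mechanism I) is treated as baseline-only: it is
    missing unless the block-1 measurement round succeeded for it.
    """
    if targets is None:
        targets = [n for n, s in panel.specs.items() if s.imputable]
    n, t = panel.n_patients, panel.n_blocks
    consulted = rng.random((n, t)) < p_consult
    out = panel.copy()
    for name in targets:
        s = panel.spec(name)
        recorded = rng.random((n, t)) >= p_unrecorded
        observed = consulted & recorded
        if s.time_dependent:
            drop = ~observed
        else:
            drop = ~observed[:, 0]
        v, m = out._values[name], out._mask[name]
        if s.is_categorical:
            v[drop] = -1
        else:
            v[drop] = np.nan
        m[drop] = False
    out.validate()
    return out


def expected_observation_gap(p_consult: float, p_record: float) -> float:
    """Expected blocks between successive observations of one variable:
    the mean of a geometric waiting time with per-block success
    probability ``p_consult * p_record``."""
    for p in (p_consult, p_record):
        if not 0.0 < p <= 1.0:
            raise PanelError("probabilities must lie in (0, 1]")
    return 1.0 / (p_consult * p_record)
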