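"""Two-fold chained-equations scheduler for longitudinal panels.

Imputation models for time block t' condition only on values at blocks
within a window of half-width tau around t' (restricted at the panel
boundaries).  An inner "within-time" FCS pass of b_within iterations is
run at each block; an outer "among-time" sweep visits every block in
time order and is repeated b_among times, so information propagates
along the timeline.  Time-independent variables are imputed once at the
start of each among-time sweep, conditioning on the outcome, the fully
observed time-independent variables and the time-dependent values at a
baseline block.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from typing import Optional, Sequence

import numpy as np

from . import imputers
from .fcs import FcsError, FcsPlan, PlanStep, Work, _impute_step, _order_steps, fcs_iteration
from .panel import (
    OUTCOME_TERMS,
    ImputedSet,
    LongitudinalPanel,
    PanelError,
    SurvivalOutcome,
    Term,
)

__all__ = [
    "TwofoldConfig",
    "window_blocks",
    "build_within_plan",
    "time_independent_steps",
    "impute_time_independent_step",
    "semideterministic_preprocess",
    "run_twofold",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TwofoldConfig:
    """Settings for the two-fold scheduler."""

    tau: int = 1
    b_within: int = 5
    b_among: int = 20
    k: int = 5
    baseline_block: int = 1
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.tau < 1:
            raise PanelError("tau must be >= 1")
        if self.b_within < 1 or self.b_among < 1 or self.k < 1:
            raise PanelError("iteration and imputation counts must be >= 1")
        if self.baseline_block < 1:
            raise PanelError("baseline_block must be >= 1")


def window_blocks(t_prime: int, tau: int, n_blocks: int) -> tuple[int, ...]:
    """Blocks conditioned on when imputing at ``t_prime``:
    {max(1, t'-tau), ..., min(T, t'+tau)}."""
    if not 1 <= t_prime <= n_blocks:
        raise PanelError(f"block {t_prime} outside 1..{n_blocks}")
    return tuple(range(max(1, t_prime - tau), min(n_blocks, t_prime + tau) + 1))


def build_within_plan(
    panel: LongitudinalPanel,
    t_prime: int,
    tau: int,
    outcome_terms: Sequence[Term] = OUTCOME_TERMS,
    b_within: int = 5,
    k: int = 1,
) -> FcsPlan:
    """Within-time plan for block ``t_prime``.

    Responses are the imputable time-dependent variables at ``t_prime``.
    Predictors are every time-dependent variable (imputable or fully
    observed) at the window blocks except the response slot itself, plus
    all time-independent variables and the outcome terms.  Values at
    other window blocks are predictors only — they are not imputed at
    this stage.
    """
    wblocks = window_blocks(t_prime, tau, panel.n_blocks)
    td_terms = [
        Term(name, t)
        for name, s in panel.specs.items()
        if s.time_dependent
        for t in wblocks
    ]
    ti_terms = [Term(name, None) for name, s in panel.specs.items() if not s.time_dependent]
    steps = []
    for name, s in panel.specs.items():
        if not (s.time_dependent and s.imputable):
            continue
        resp = Term(name, t_prime)
        preds = tuple(t for t in td_terms if t != resp) + tuple(ti_terms) + tuple(outcome_terms)
        steps.append(PlanStep(resp, preds))
    return FcsPlan(_order_steps(panel, steps), b=b_within, k=k)


def time_independent_steps(
    panel: LongitudinalPanel,
    baseline_block: int,
    outcome_terms: Sequence[Term] = OUTCOME_TERMS,
) -> tuple[PlanStep, ...]:
    """Steps imputing the imputable time-independent variables,
    conditional on the outcome, the fully observed time-independent
    variables and the (current) time-dependent values at the baseline
    block."""
    if baseline_block not in panel.blocks:
        raise PanelError(f"baseline block {baseline_block} outside 1..{panel.n_blocks}")
    fully_obs_ti = [
        Term(name, None)
        for name, s in panel.specs.items()
        if not s.time_dependent and panel.mask(name).all()
    ]
    td_at_baseline = [
        Term(name, baseline_block)
        for name, s in panel.specs.items()
        if s.time_dependent
    ]
    steps = []
    for name, s in panel.specs.items():
        if s.time_dependent or not s.imputable:
            continue
        if panel.mask(name).all():
            continue  # fully observed: predictor only
        resp = Term(name, None)
        preds = (
            tuple(t for t in fully_obs_ti if t != resp)
            + tuple(td_at_baseline)
            + tuple(outcome_terms)
        )
        steps.append(PlanStep(resp, preds))
    return _order_steps(panel, steps)


def impute_time_independent_step(
    work: Work,
    steps: Sequence[PlanStep],
    rng: np.random.Generator,
) -> None:
    for step in steps:
        _impute_step(work, step, rng)


def semideterministic_preprocess(
    panel: LongitudinalPanel, variable: str, anchor_level: str
) -> tuple[LongitudinalPanel, np.ndarray]:
    """Deterministically fill a monotone-constrained categorical variable.

    Patients whose every observed value of ``variable`` equals
    ``anchor_level`` get all their missing values for it set to that
    level (flagged as deterministic, i.e. treated as known thereafter).
    Patients with no observation at all are *not* anchored — they remain
    eligible for stochastic imputation over the non-anchor levels — and
    their count is logged.
    """
    s = panel.spec(variable)
    if not (s.is_categorical and s.time_dependent):
        raise PanelError(f"{variable}: anchor preprocessing needs a time-dependent categorical")
    if anchor_level not in s.levels:
        raise PanelError(f"{variable}: unknown anchor level {anchor_level!r}")
    code = s.code_of(anchor_level)
    v = panel.values(variable)
    m = panel.mask(variable)
    has_obs = m.any(axis=1)
    only_anchor = has_obs & np.all(~m | (v == code), axis=1)
    n_unobserved = int((~has_obs).sum())
    if n_unobserved:
        log.info(
            "%s: %d patients with no observed value treated as non-%s",
            variable, n_unobserved, anchor_level,
        )
    out = panel.copy()
    fill = only_anchor[:, None] & ~m
    out.set_cells(variable, fill, code)
    return out, only_anchor


def run_twofold(
    panel: LongitudinalPanel,
    outcome: SurvivalOutcome,
    config: TwofoldConfig,
    rng: Optional[np.random.Generator] = None,
) -> ImputedSet:
    """Run the two-fold scheduler and return K completed panels.

    Variables whose spec declares an ``anchor_level`` are first passed
    through :func:`semideterministic_preprocess`.  Each of the K
    imputations is separated from the previous one by a fresh run of
    ``b_among`` among-time sweeps.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    src = panel
    anchored: dict[str, np.ndarray] = {}
    for name, s in panel.specs.items():
        if s.anchor_level is not None and s.time_dependent and s.is_categorical:
            src, flags = semideterministic_preprocess(src, name, s.anchor_level)
            anchored[name] = flags

    completed = imputers.initialize_missing(src, rng)
    work = Work(completed, src, outcome)
    work.anchored_vars = set(anchored)
    within_plans = [
        build_within_plan(src, t, config.tau, b_within=config.b_within)
        for t in src.blocks
    ]
    ti_steps = time_independent_steps(src, config.baseline_block)

    panels = []
    for _k in range(config.k):
        for sweep in range(config.b_among):
            try:
                impute_time_independent_step(work, ti_steps, rng)
                for t in src.blocks:
                    plan = within_plans[t - 1]
                    for _ in range(config.b_within):
                        fcs_iteration(work, plan, rng, iteration=sweep + 1)
            except FcsError as exc:
                raise FcsError(
                    f"two-fold failure (imputation {_k + 1}, sweep {sweep + 1}): {exc}",
                    exc.term,
                    exc.iteration,
                ) from exc
        panels.append(work.snapshot())
    return ImputedSet(
        panels,
        method="twofold",
        config=asdict(config),
    )
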