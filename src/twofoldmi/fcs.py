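"""Chained-equations (FCS) imputation engine.

An :class:`FcsPlan` is an ordered list of (response slot, predictor
slots) pairs; :func:`run_fcs` cycles through it, refitting each
univariate imputation model on the originally-observed rows (with
missing predictor cells at their current imputed values) and redrawing
the missing cells.  Plans restricted to one block give the "baseline"
comparator; plans over every variable-block pair give the "full"
comparator; the two-fold scheduler feeds window-restricted plans
through the same machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import imputers
from .imputers import ImputerError
from .panel import (
    EVENT,
    TIME,
    OUTCOME_TERMS,
    ImputedSet,
    LongitudinalPanel,
    PanelError,
    SurvivalOutcome,
    Term,
    VariableSpec,
)

__all__ = [
    "PlanStep",
    "FcsPlan",
    "FcsError",
    "Work",
    "build_baseline_plan",
    "build_full_plan",
    "run_fcs",
]


class FcsError(RuntimeError):
    """Imputer failure annotated with (variable, block, iteration) context."""

    def __init__(self, message: str, term: Term, iteration: Optional[int] = None):
        super().__init__(message)
        self.term = term
        self.iteration = iteration


@dataclass(frozen=True)
class PlanStep:
    response: Term
    predictors: tuple[Term, ...]

    def __post_init__(self) -> None:
        if self.response in self.predictors:
            raise PanelError(f"response {self.response} appears in its own predictors")


@dataclass
class FcsPlan:
    """Imputation schedule: visiting order, iteration counts, K."""

    steps: tuple[PlanStep, ...]
    b: int = 10
    k: int = 5
    spacing: Optional[int] = None  # iterations between imputed sets; default b

    def __post_init__(self) -> None:
        responses = [s.response for s in self.steps]
        if len(set(responses)) != len(responses):
            raise PanelError("each response must appear exactly once per cycle")
        if self.b < 1 or self.k < 1:
            raise PanelError("b and k must be >= 1")
        if self.spacing is None:
            self.spacing = self.b


# ---------------------------------------------------------------------------
# Working state: a completed panel plus the original observedness mask
# ---------------------------------------------------------------------------

class Work:
    """Mutable completed data used inside chained-equations cycles.

    Holds current (observed + imputed) values for every variable and the
    *original* mask, so observed cells are never overwritten and missing
    cells can be redrawn each iteration.
    """

    def __init__(self, completed: LongitudinalPanel, original: LongitudinalPanel,
                 outcome: SurvivalOutcome):
        if not completed.is_complete():
            raise PanelError("work requires a completed panel")
        self.panel = completed.copy()
        self.orig_mask = {n: original.mask(n).copy() for n in original.specs}
        self.outcome = outcome
        if outcome.n != completed.n_patients:
            raise PanelError("outcome length does not match panel")
        # design columns of never-changing slots (fully observed variables,
        # outcome terms) are cached per static-term tuple
        self._static_cache: dict[tuple[Term, ...], np.ndarray] = {}
        # responses that needed the ridge retry skip the unpenalised fit
        # on later visits (separation there is structural, not incidental)
        self._ridge_hint: dict[Term, bool] = {}
        # variables put through semideterministic anchor preprocessing;
        # only these get level-restricted imputation (opt-in)
        self.anchored_vars: set[str] = set()

    def spec(self, name: str) -> VariableSpec:
        return self.panel.spec(name)

    def _slot(self, term: Term) -> np.ndarray:
        s = self.panel.spec(term.var)
        v = self.panel.values(term.var)
        if s.time_dependent:
            if term.block is None:
                raise PanelError(f"{term.var}: time-dependent term needs a block")
            return v[:, term.block - 1]
        return v

    def missing_of(self, term: Term) -> np.ndarray:
        s = self.panel.spec(term.var)
        m = self.orig_mask[term.var]
        return ~(m[:, term.block - 1] if s.time_dependent else m)

    def columns(self, term: Term) -> np.ndarray:
        """Design columns for one predictor term (2-D, n x q)."""
        if term == EVENT:
            return self.outcome.event.astype(float)[:, None]
        if term == TIME:
            return self.outcome.time[:, None]
        s = self.panel.spec(term.var)
        vals = self._slot(term)
        if not s.is_categorical:
            return vals.astype(float)[:, None]
        # dummy-encode against the first declared level
        return np.column_stack(
            [(vals == code).astype(float) for code in range(1, len(s.levels))]
        )

    def _is_static(self, term: Term) -> bool:
        if term.var.startswith("@"):
            return True
        return not self.panel.spec(term.var).imputable

    def design(self, terms: Sequence[Term]) -> np.ndarray:
        n = self.panel.n_patients
        if not terms:
            return np.empty((n, 0))
        dynamic = [t for t in terms if not self._is_static(t)]
        static = tuple(t for t in terms if self._is_static(t))
        blocks = [self.columns(t) for t in dynamic]
        if static:
            cached = self._static_cache.get(static)
            if cached is None:
                cached = np.column_stack([self.columns(t) for t in static])
                self._static_cache[static] = cached
            blocks.append(cached)
        return np.column_stack(blocks) if len(blocks) > 1 else blocks[0]

    def set_missing(self, term: Term, values: np.ndarray) -> None:
        """Write imputations into the originally-missing cells of a slot."""
        mis = self.missing_of(term)
        slot = self._slot(term)
        slot[mis] = values

    def snapshot(self) -> LongitudinalPanel:
        p = self.panel.copy()
        p.validate()
        return p


def _impute_step(work: Work, step: PlanStep, rng: np.random.Generator) -> None:
    """Refit the univariate model for one response slot and redraw its
    originally-missing cells in place."""
    term = step.response
    s = work.spec(term.var)
    mis = work.missing_of(term)
    if not mis.any():
        return
    X = work.design(step.predictors)
    y = work._slot(term)

    if not s.is_categorical:
        res = imputers.impute_continuous(y, X, mis, rng)
        work.set_missing(term, res.values)
        return

    hint = work._ridge_hint.get(term, False)
    n_levels = len(s.levels)
    if s.anchor_level is not None and term.var in work.anchored_vars:
        # monotone-category preprocessing: anchor-valued rows are predictors
        # only; fitting and imputation run over the non-anchor levels.
        anchor = s.code_of(s.anchor_level)
        obs_rows = ~mis
        fit_rows = obs_rows & (y != anchor)
        others = [c for c in range(n_levels) if c != anchor]
        if len(others) == 2:
            # rows observed at the anchor are excluded from the fit but are
            # not re-imputed: impute on mis only, using fit_rows as observed.
            yb = (y == others[1]).astype(float)
            res = _binary_on_subset(yb, X, fit_rows, mis, rng, hint)
            work._ridge_hint[term] = res.ridged
            work.set_missing(
                term, np.where(res.values == 1, others[1], others[0]).astype(np.int16)
            )
        else:
            res = _categorical_on_subset(y, X, fit_rows, mis, rng, n_levels, hint)
            work._ridge_hint[term] = res.ridged
            work.set_missing(term, res.values)
        return

    if n_levels == 2:
        res = imputers.impute_binary((y == 1).astype(float), X, mis, rng, hint)
        work.set_missing(term, res.values.astype(np.int16))
    else:
        res = imputers.impute_categorical(y, X, mis, rng, n_levels, hint)
        work.set_missing(term, res.values)
    work._ridge_hint[term] = res.ridged


def _binary_on_subset(
    yb: np.ndarray, X: np.ndarray, fit_rows: np.ndarray, mis: np.ndarray,
    rng: np.random.Generator, start_ridged: bool = False,
) -> imputers.ImputerResult:
    """Binary imputation where the fitting subset differs from ~mis."""
    sel = fit_rows | mis
    return imputers.impute_binary(yb[sel], X[sel], mis[sel], rng, start_ridged)


def _categorical_on_subset(
    y: np.ndarray, X: np.ndarray, fit_rows: np.ndarray, mis: np.ndarray,
    rng: np.random.Generator, n_levels: int, start_ridged: bool = False,
) -> imputers.ImputerResult:
    # levels absent from the fitting subset get zero draw probability, so
    # an anchor level excluded via fit_rows never reappears in imputations
    sel = fit_rows | mis
    return imputers.impute_categorical(y[sel], X[sel], mis[sel], rng, n_levels, start_ridged)


# ---------------------------------------------------------------------------
# Plan builders
# ---------------------------------------------------------------------------

def _missing_fraction(panel: LongitudinalPanel, term: Term) -> float:
    s = panel.spec(term.var)
    m = panel.mask(term.var)
    col = m[:, term.block - 1] if s.time_dependent else m
    return 1.0 - float(col.mean())


def _order_steps(panel: LongitudinalPanel, steps: list[PlanStep]) -> tuple[PlanStep, ...]:
    # ascending missing fraction; ties keep construction (declaration) order
    decorated = sorted(
        enumerate(steps), key=lambda p: (_missing_fraction(panel, p[1].response), p[0])
    )
    return tuple(s for _, s in decorated)


def build_baseline_plan(
    panel: LongitudinalPanel,
    block: int,
    outcome_terms: Sequence[Term] = OUTCOME_TERMS,
    b: int = 10,
    k: int = 5,
) -> FcsPlan:
    """Standard FCS over one block only: each imputable variable at
    ``block`` (plus imputable time-independent variables) is regressed on
    the other variables of that block, the time-independent variables and
    the outcome terms."""
    if block not in panel.blocks:
        raise PanelError(f"block {block} outside 1..{panel.n_blocks}")
    terms: list[Term] = []
    for name, s in panel.specs.items():
        terms.append(Term(name, block) if s.time_dependent else Term(name, None))
    steps = []
    for name, s in panel.specs.items():
        if not s.imputable:
            continue
        resp = Term(name, block) if s.time_dependent else Term(name, None)
        preds = tuple(t for t in terms if t != resp) + tuple(outcome_terms)
        steps.append(PlanStep(resp, preds))
    return FcsPlan(_order_steps(panel, steps), b=b, k=k)


def build_full_plan(
    panel: LongitudinalPanel,
    outcome_terms: Sequence[Term] = OUTCOME_TERMS,
    b: int = 10,
    k: int = 5,
) -> FcsPlan:
    """Standard FCS treating every variable-block pair as a distinct
    covariate: each response conditions on all other variable-blocks, the
    time-independent variables and the outcome terms."""
    terms: list[Term] = []
    for name, s in panel.specs.items():
        if s.time_dependent:
            terms.extend(Term(name, t) for t in panel.blocks)
        else:
            terms.append(Term(name, None))
    steps = []
    for name, s in panel.specs.items():
        if not s.imputable:
            continue
        resp_terms = (
            [Term(name, t) for t in panel.blocks] if s.time_dependent else [Term(name, None)]
        )
        for resp in resp_terms:
            preds = tuple(t for t in terms if t != resp) + tuple(outcome_terms)
            steps.append(PlanStep(resp, preds))
    return FcsPlan(_order_steps(panel, steps), b=b, k=k)


# ---------------------------------------------------------------------------
# Runner
# ---------------------------------------------------------------------------

def fcs_iteration(work: Work, plan: FcsPlan, rng: np.random.Generator,
                  iteration: Optional[int] = None) -> None:
    """One full cycle over the plan's responses."""
    for step in plan.steps:
        try:
            _impute_step(work, step, rng)
        except ImputerError as exc:
            raise FcsError(
                f"imputation failed for {step.response} "
                f"(iteration {iteration}): {exc}",
                step.response,
                iteration,
            ) from exc


def run_fcs(
    panel: LongitudinalPanel,
    outcome: SurvivalOutcome,
    plan: FcsPlan,
    rng: np.random.Generator,
    method: str = "fcs",
) -> ImputedSet:
    """Run chained-equations imputation and return K completed panels.

    The panel is initialised by marginal resampling, ``plan.b``
    iterations are run before the first snapshot, and ``plan.spacing``
    further iterations separate successive snapshots so the K sets are
    approximately independent.
    """
    completed = imputers.initialize_missing(panel, rng)
    work = Work(completed, panel, outcome)
    panels = []
    for j in range(plan.k):
        n_iter = plan.b if j == 0 else plan.spacing
        for it in range(n_iter):
            fcs_iteration(work, plan, rng, iteration=it + 1)
        panels.append(work.snapshot())
    return ImputedSet(
        panels,
        method=method,
        config={"b": plan.b, "k": plan.k, "spacing": plan.spacing},
    )
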