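"""Monte-Carlo evaluation harness.

Each replication: generate a complete cohort; fit the substantive
exponential model to the full data; impose the consultation-driven MCAR
mechanism; fit the complete records; impute with each configured method,
fit each completed panel and pool with Rubin's rules.  Replications are
aggregated into per-coefficient summaries: bias, empirical and mean
analytic SE, coverage, relative efficiency versus the full-data
estimator, information loss and effective sample size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import cohort as cohort_mod
from .cohort import DgmConfig, SUBSTANTIVE_COVARIATES, TRUE_COEFFICIENTS
from .fcs import FcsError, build_baseline_plan, build_full_plan, run_fcs
from .panel import complete_records
from .pooling import pool_fits
from .survival import SurvivalError, build_design, fit_exponential
from .twofold import TwofoldConfig, run_twofold

__all__ = [
    "StudyConfig",
    "MethodResult",
    "run_replication",
    "aggregate",
    "compare_se_reduction",
    "run_study",
]

FULL = "full"
COMPLETE_RECORDS = "complete_records"
BASELINE_FCS = "baseline_fcs"
FULL_FCS = "full_fcs"
TWOFOLD = "twofold"


@dataclass(frozen=True)
class StudyConfig:
    """Study-level settings.  ``scale`` < 1 shrinks patients and
    replications jointly for desk-scale runs."""

    n_reps: int = 1000
    dgm: DgmConfig = field(default_factory=DgmConfig)
    methods: tuple[str, ...] = (COMPLETE_RECORDS, BASELINE_FCS, TWOFOLD)
    k: int = 5
    baseline_iterations: int = 10
    twofold: TwofoldConfig = field(default_factory=TwofoldConfig)
    level: float = 0.95
    seed: int = 0

    def scaled(self, scale: float) -> "StudyConfig":
        if scale >= 1.0:
            return self
        dgm = DgmConfig(**{**_dgm_dict(self.dgm),
                           "n_patients": max(200, int(self.dgm.n_patients * scale))})
        return StudyConfig(
            n_reps=max(10, int(self.n_reps * scale)),
            dgm=dgm,
            methods=self.methods,
            k=self.k,
            baseline_iterations=self.baseline_iterations,
            twofold=self.twofold,
            level=self.level,
            seed=self.seed,
        )


def _dgm_dict(dgm: DgmConfig) -> dict:
    from dataclasses import asdict

    return asdict(dgm)


@dataclass
class MethodResult:
    ok: bool
    coef: Optional[dict[str, float]] = None
    se: Optional[dict[str, float]] = None
    ci: Optional[dict[str, tuple[float, float]]] = None
    error: Optional[str] = None


def _fit_to_result(fit, level: float) -> MethodResult:
    z = stats.norm.ppf(0.5 + level / 2)
    coef, se, ci = {}, {}, {}
    for nm, (b, s) in fit.coef_table().items():
        coef[nm], se[nm] = b, s
        ci[nm] = (b - z * s, b + z * s)
    return MethodResult(True, coef, se, ci)


def _pooled_to_result(pooled) -> MethodResult:
    coef = {nm: p.estimate for nm, p in pooled.items()}
    se = {nm: p.se for nm, p in pooled.items()}
    ci = {nm: (p.ci_low, p.ci_high) for nm, p in pooled.items()}
    return MethodResult(True, coef, se, ci)


def replication_rng(seed: int, rep_id: int) -> np.random.Generator:
    """Independent child stream per replication (counter-keyed)."""
    return np.random.default_rng(np.random.SeedSequence((seed, rep_id)))


def run_replication(rep_id: int, config: StudyConfig) -> dict[str, MethodResult]:
    """One full replication; a method's failure never aborts the others."""
    rng = replication_rng(config.seed, rep_id)
    panel, outcome = cohort_mod.generate_cohort(config.dgm, rng)
    results: dict[str, MethodResult] = {}

    X, names = build_design(panel, SUBSTANTIVE_COVARIATES, at_block=1)
    full_fit = fit_exponential(X, outcome, names)
    results[FULL] = _fit_to_result(full_fit, config.level)

    observed = cohort_mod.impose_mcar(
        panel, config.dgm.p_consult, config.dgm.p_unrecorded, rng
    )

    if COMPLETE_RECORDS in config.methods:
        try:
            sub, sub_out, _ = complete_records(
                observed, outcome, at_block=1, covariates=SUBSTANTIVE_COVARIATES
            )
            Xc, nc = build_design(sub, SUBSTANTIVE_COVARIATES, at_block=1)
            results[COMPLETE_RECORDS] = _fit_to_result(
                fit_exponential(Xc, sub_out, nc), config.level
            )
        except SurvivalError as exc:
            results[COMPLETE_RECORDS] = MethodResult(False, error=str(exc))

    def _mi_method(name: str, runner: Callable) -> None:
        if name not in config.methods:
            return
        try:
            imputed = runner()
            fits = []
            for p in imputed.panels:
                Xi, ni = build_design(p, SUBSTANTIVE_COVARIATES, at_block=1)
                fits.append(fit_exponential(Xi, outcome, ni))
            results[name] = _pooled_to_result(pool_fits(fits, level=config.level))
        except (FcsError, SurvivalError) as exc:
            results[name] = MethodResult(False, error=str(exc))

    _mi_method(
        BASELINE_FCS,
        lambda: run_fcs(
            observed, outcome,
            build_baseline_plan(observed, block=1, b=config.baseline_iterations, k=config.k),
            rng, method=BASELINE_FCS,
        ),
    )
    _mi_method(
        FULL_FCS,
        lambda: run_fcs(
            observed, outcome,
            build_full_plan(observed, b=config.baseline_iterations, k=config.k),
            rng, method=FULL_FCS,
        ),
    )
    _mi_method(
        TWOFOLD,
        lambda: run_twofold(observed, outcome, config.twofold, rng),
    )
    return results


def aggregate(
    reps: Sequence[dict[str, MethodResult]],
    truth: Optional[dict[str, float]] = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Per (method, coefficient) Monte-Carlo summary table.

    Columns: n_ok, n_fail, mean_estimate, bias, empirical_se,
    mean_analytic_se, coverage, relative_efficiency, information_loss,
    effective_n_per_1000.  Relative efficiency is the full-data empirical
    variance over the method's empirical variance.
    """
    if truth is None:
        truth = TRUE_COEFFICIENTS
    methods: list[str] = []
    for r in reps:
        for m in r:
            if m not in methods:
                methods.append(m)
    rows = []
    emp_var_full: dict[str, float] = {}
    for method in methods:
        oks = [r[method] for r in reps if method in r and r[method].ok]
        n_fail = sum(1 for r in reps if method in r and not r[method].ok)
        if not oks:
            continue
        names = list(oks[0].coef)
        for nm in names:
            est = np.array([o.coef[nm] for o in oks])
            ses = np.array([o.se[nm] for o in oks])
            tv = truth.get(nm, np.nan)
            cover = np.mean([
                (o.ci[nm][0] <= tv <= o.ci[nm][1]) for o in oks
            ]) if np.isfinite(tv) else np.nan
            emp_var = float(est.var(ddof=1)) if len(est) > 1 else np.nan
            if method == FULL:
                emp_var_full[nm] = emp_var
            rel_eff = np.nan
            if method != FULL and nm in emp_var_full and emp_var and emp_var > 0:
                rel_eff = emp_var_full[nm] / emp_var
            rows.append({
                "method": method,
                "coefficient": nm,
                "n_ok": len(oks),
                "n_fail": n_fail,
                "mean_estimate": float(est.mean()),
                "bias": float(est.mean() - tv) if np.isfinite(tv) else np.nan,
                "empirical_se": float(np.sqrt(emp_var)) if emp_var == emp_var else np.nan,
                "mean_analytic_se": float(ses.mean()),
                "coverage": float(cover) if cover == cover else np.nan,
                "relative_efficiency": rel_eff,
                "information_loss": 1.0 - rel_eff if rel_eff == rel_eff else np.nan,
                "effective_n_per_1000": 1000.0 * rel_eff if rel_eff == rel_eff else np.nan,
            })
    return pd.DataFrame(rows)


def compare_se_reduction(
    report: pd.DataFrame, method_a: str, method_b: str, coefficient: str
) -> float:
    """Percent reduction in empirical SE going from method_a to method_b:
    100 * (1 - SE_b / SE_a)."""
    def _se(method: str) -> float:
        sel = report[(report["method"] == method) & (report["coefficient"] == coefficient)]
        if sel.empty:
            raise KeyError(f"no row for ({method}, {coefficient})")
        return float(sel["empirical_se"].iloc[0])

    se_a, se_b = _se(method_a), _se(method_b)
    if se_a == 0:
        raise ZeroDivisionError("reference empirical SE is zero")
    return 100.0 * (1.0 - se_b / se_a)


def tabulate_report(report: pd.DataFrame, value: str = "mean_estimate") -> pd.DataFrame:
    """Pivot a study report into a coefficient-by-method table (one row
    per coefficient, one column per method), for side-by-side reading of
    estimates or standard errors."""
    methods = [m for m in (FULL, COMPLETE_RECORDS, BASELINE_FCS, FULL_FCS, TWOFOLD)
               if m in set(report["method"])]
    table = report.pivot(index="coefficient", columns="method", values=value)
    order = [c for c in report["coefficient"].unique()]
    return table.loc[order, methods]


def run_study(
    config: StudyConfig,
    progress: Optional[Callable[[int, int], None]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[dict[str, MethodResult]]]:
    """Run all replications serially and aggregate.

    Returns (report, raw per-replication estimates, raw results).
    """
    reps = []
    raw_rows = []
    for rep in range(config.n_reps):
        res = run_replication(rep, config)
        reps.append(res)
        for method, r in res.items():
            if r.ok:
                for nm in r.coef:
                    raw_rows.append({
                        "rep": rep, "method": method, "coefficient": nm,
                        "estimate": r.coef[nm], "se": r.se[nm],
                    })
            else:
                raw_rows.append({
                    "rep": rep, "method": method, "coefficient": None,
                    "estimate": np.nan, "se": np.nan,
                })
        if progress is not None:
            progress(rep + 1, config.n_reps)
    report = aggregate(reps, level=config.level)
    return report, pd.DataFrame(raw_rows), reps
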