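"""Exponential proportional-hazards substantive model.

The hazard for patient i is exp(x_i beta), constant over follow-up, so
the log-likelihood is sum_i [ Delta_i * x_i beta - T_i * exp(x_i beta) ].
Fitting is Newton-Raphson with step-halving from a deterministic start
(intercept at log(events / person-time), other coefficients zero), which
makes the fit reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel import LongitudinalPanel, PanelError, SurvivalOutcome

__all__ = ["ExponentialFit", "SurvivalError", "build_design", "fit_exponential"]

CONSTANT_LABEL = "constant"


class SurvivalError(RuntimeError):
    pass


@dataclass
class ExponentialFit:
    names: list[str]
    coef: np.ndarray
    cov: np.ndarray
    loglik: float
    n: int
    n_events: int

    @property
    def se(self) -> np.ndarray:
        d = np.diag(self.cov)
        # near-singular information can leave tiny negative diagonals;
        # surface them as NaN rather than a runtime warning
        return np.sqrt(np.where(d >= 0, d, np.nan))

    def coef_table(self) -> dict[str, tuple[float, float]]:
        return {nm: (float(b), float(s)) for nm, b, s in zip(self.names, self.coef, self.se)}


def build_design(
    panel: LongitudinalPanel,
    covariates: list[str],
    at_block: int,
) -> tuple[np.ndarray, list[str]]:
    """Covariate table for the substantive model, without intercept.

    Categorical covariates are dummy-encoded against their spec's
    reference level; continuous covariates enter untransformed.  Values
    are taken at ``at_block`` for time-dependent variables.  All cells
    must be observed (fit a completed or complete-records panel).
    """
    if at_block not in panel.blocks:
        raise PanelError(f"block {at_block} outside 1..{panel.n_blocks}")
    cols: list[np.ndarray] = []
    names: list[str] = []
    for name in covariates:
        s = panel.spec(name)
        m = panel.mask(name)
        v = panel.values(name)
        if s.time_dependent:
            m, v = m[:, at_block - 1], v[:, at_block - 1]
        if not m.all():
            raise PanelError(f"{name}: missing values in design at block {at_block}")
        if s.is_categorical:
            ref = s.ref_level
            for lev in s.levels:
                if lev == ref:
                    continue
                cols.append((v == s.code_of(lev)).astype(float))
                names.append(f"{name}[{lev}]")
        else:
            cols.append(v.astype(float))
            names.append(name)
    X = np.column_stack(cols) if cols else np.empty((panel.n_patients, 0))
    return X, names


def fit_exponential(
    X: np.ndarray,
    outcome: SurvivalOutcome,
    names: list[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> ExponentialFit:
    """Maximum-likelihood fit; covariance is the inverse observed
    information at the optimum."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if outcome.n != n:
        raise SurvivalError("design and outcome sizes differ")
    d = outcome.event.astype(float)
    t = outcome.time
    n_events = int(d.sum())
    if n_events == 0:
        raise SurvivalError("no events: exponential rate is not identified")
    Xi = np.column_stack([np.ones(n), X])
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    all_names = [CONSTANT_LABEL] + list(names)
    p = Xi.shape[1]

    beta = np.zeros(p)
    beta[0] = np.log(n_events / t.sum())

    def loglik(b: np.ndarray) -> float:
        eta = Xi @ b
        return float(d @ eta - t @ np.exp(eta))

    ll = loglik(beta)
    for _ in range(max_iter):
        eta = Xi @ beta
        mu = t * np.exp(eta)
        g = Xi.T @ (d - mu)
        h = (Xi * mu[:, None]).T @ Xi  # observed information
        try:
            step = np.linalg.solve(h, g)
        except np.linalg.LinAlgError:
            raise SurvivalError("singular information matrix (collinear design?)") from None
        for _ in range(30):
            cand = beta + step
            ll_c = loglik(cand)
            if np.isfinite(ll_c) and ll_c >= ll - 1e-12:
                break
            step = step / 2
        beta = beta + step
        if abs(ll_c - ll) < tol * (abs(ll) + 1.0):
            ll = ll_c
            break
        ll = ll_c
    else:
        gnorm = float(np.linalg.norm(Xi.T @ (d - t * np.exp(Xi @ beta))))
        raise SurvivalError(f"no convergence after {max_iter} iterations (|grad|={gnorm:.3g})")

    mu = t * np.exp(Xi @ beta)
    h = (Xi * mu[:, None]).T @ Xi
    cov = np.linalg.inv(h)
    return ExponentialFit(all_names, beta, cov, ll, n, n_events)
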