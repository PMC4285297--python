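"""Univariate regression imputers drawing from approximate posterior
predictive distributions.

These are the inner step of every chained-equations cycle: each fits a
regression of one incomplete variable on a predictor matrix using the
originally-observed rows, draws model parameters from their (approximate)
posterior, and then draws imputations for the missing rows — "proper"
imputation, so that between-imputation variance reflects parameter
uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import qr as _qr, solve_triangular
from scipy.special import expit, softmax

from .panel import LongitudinalPanel, PanelError

__all__ = [
    "ImputerResult",
    "ImputerError",
    "SeparationError",
    "impute_continuous",
    "impute_binary",
    "impute_categorical",
    "initialize_missing",
]

#: relative tolerance for rank detection when pruning collinear columns
RANK_RTOL = 1e-9
#: |coefficient| beyond this (on standardised predictors) flags separation
SEPARATION_BOUND = 30.0


def _retry_ridge(n_total: int) -> float:
    """Penalty used on the one retry after a divergent GLM fit: at least a
    weakly-informative prior (sd 2.5 per standardised coefficient), which
    keeps perfectly-predicted responses imputable instead of fatal."""
    return max(1e-6 * n_total, 1.0 / 2.5**2)


class ImputerError(RuntimeError):
    pass


class SeparationError(ImputerError):
    """Perfect separation / divergent GLM fit that survived the ridge retry."""


@dataclass
class ImputerResult:
    """Imputed values for the missing rows plus fit diagnostics."""

    values: np.ndarray
    n_obs: int
    n_predictors: int
    dropped: list[int] = field(default_factory=list)
    ridged: bool = False

    @property
    def n_imputed(self) -> int:
        return len(self.values)


def _with_intercept(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(len(X)), X])


def _prune_collinear(X: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Drop columns that are (numerically) linear combinations of earlier
    ones, detected from the QR decomposition's R diagonal."""
    if X.shape[1] == 0:
        return X, []
    _, r, piv = _qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag[0] * RANK_RTOL * max(X.shape) if diag.size and diag[0] > 0 else 0.0
    rank = int(np.sum(diag > tol))
    keep = sorted(piv[:rank])
    dropped = sorted(set(range(X.shape[1])) - set(keep))
    return X[:, keep], dropped


def _maybe_prune(X: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Cheap full-rank check via unpivoted QR; fall back to the pivoted
    prune only when the R diagonal flags rank deficiency."""
    if X.shape[1] == 0:
        return X, []
    r = np.linalg.qr(X, mode="r")
    diag = np.abs(np.diag(r))
    tol = diag.max() * RANK_RTOL * max(X.shape) if diag.size else 0.0
    if diag.size and diag.min() > tol:
        return X, []
    return _prune_collinear(X)


def _check_rows(n_obs: int, n_pred: int) -> None:
    if n_obs < n_pred + 2:
        raise ImputerError(
            f"too few observed rows ({n_obs}) for {n_pred} predictors"
        )


def impute_continuous(
    y: np.ndarray,
    X: np.ndarray,
    missing: np.ndarray,
    rng: np.random.Generator,
    *,
    deterministic: bool = False,
) -> ImputerResult:
    """Bayesian-draw normal linear imputation.

    Fits OLS on observed rows, draws the residual variance from its
    scaled inverse-chi-square posterior and the coefficients from their
    conditional normal posterior, then imputes each missing row as
    linear predictor plus normal noise.  ``deterministic=True`` skips
    all draws and returns the least-squares prediction (regression-test
    hook).
    """
    y = np.asarray(y, dtype=float)
    missing = np.asarray(missing, dtype=bool)
    obs = ~missing
    if not missing.any():
        return ImputerResult(np.empty(0), int(obs.sum()), X.shape[1])
    Xi = _with_intercept(np.asarray(X, dtype=float))
    Xo = Xi[obs]
    # fast path: normal equations via Cholesky; fall back to a pivoted-QR
    # prune when the cross-product matrix is not (numerically) PD
    dropped_i: list[int] = []
    Xp = Xo
    L = None
    try:
        g = Xo.T @ Xo
        L = np.linalg.cholesky(g)
        dl = np.diag(L)
        if dl.min() <= dl.max() * 1e-7:
            L = None
    except np.linalg.LinAlgError:
        L = None
    if L is None:
        Xp, dropped_i = _prune_collinear(Xo)
        L = np.linalg.cholesky(Xp.T @ Xp)
    dropped = [d - 1 for d in dropped_i]  # report in caller's column indices
    n_obs, p = Xp.shape
    _check_rows(n_obs, p)
    keep = sorted(set(range(Xi.shape[1])) - set(dropped_i))
    Xmis = Xi[missing][:, keep]

    yo = y[obs]
    beta_hat = solve_triangular(
        L.T, solve_triangular(L, Xp.T @ yo, lower=True), lower=False
    )
    resid = yo - Xp @ beta_hat
    rss = float(resid @ resid)
    df = n_obs - p
    if deterministic:
        return ImputerResult(Xmis @ beta_hat, n_obs, Xi.shape[1] - 1, dropped)
    sigma2 = rss / rng.chisquare(df) if df > 0 else rss
    # beta | sigma2 ~ N(beta_hat, sigma2 (X'X)^-1); (X'X) = L L'
    z = rng.standard_normal(p)
    beta_star = beta_hat + np.sqrt(sigma2) * solve_triangular(L.T, z, lower=False)
    draws = Xmis @ beta_star + np.sqrt(sigma2) * rng.standard_normal(Xmis.shape[0])
    return ImputerResult(draws, n_obs, Xi.shape[1] - 1, dropped)


# ---------------------------------------------------------------------------
# GLM machinery (logistic / multinomial Newton with ridge retry)
# ---------------------------------------------------------------------------

def _logistic_fit(
    X: np.ndarray, y: np.ndarray, ridge: float, max_iter: int = 50, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Newton-Raphson logistic regression; returns (beta, cov, converged)."""
    n, p = X.shape
    beta = np.zeros(p)
    ybar = np.clip(y.mean(), 1e-6, 1 - 1e-6)
    beta[0] = np.log(ybar / (1 - ybar))
    lam = ridge * np.eye(p)
    lam[0, 0] = 0.0  # never penalise the intercept
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum()) - 0.5 * beta @ lam @ beta
        w = mu * (1 - mu)
        g = X.T @ (y - mu) - lam @ beta
        h = (X * w[:, None]).T @ X + lam
        try:
            step = np.linalg.solve(h, g)
        except np.linalg.LinAlgError:
            return beta, np.full((p, p), np.nan), False
        # step-halving
        for _ in range(20):
            cand = beta + step
            eta_c = X @ cand
            ll_c = float(y @ eta_c - np.logaddexp(0.0, eta_c).sum()) - 0.5 * cand @ lam @ cand
            if ll_c >= ll - 1e-12:
                break
            step = step / 2
        beta = beta + step
        if np.max(np.abs(beta)) > 2 * SEPARATION_BOUND:
            return beta, np.full((p, p), np.nan), False  # running away: abort early
        if abs(ll_c - ll_old) < tol * (abs(ll_old) + 1.0):
            converged = True
            break
        ll_old = ll_c
    eta = X @ beta
    mu = expit(eta)
    w = mu * (1 - mu)
    h = (X * w[:, None]).T @ X + lam
    try:
        cov = np.linalg.inv(h)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        converged = False
    return beta, cov, converged


def _scale_columns(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scale non-intercept columns to unit sd (guards the separation
    bound and conditions the Newton solve); returns (scaled, scales)."""
    scales = X.std(axis=0)
    scales[0] = 1.0
    scales[scales < 1e-12] = 1.0
    return X / scales, scales


def _glm_beta_draw(
    X: np.ndarray,
    y: np.ndarray,
    n_total: int,
    rng: np.random.Generator,
    start_ridged: bool = False,
) -> tuple[np.ndarray, bool]:
    """Fit logistic, retry once with a small ridge on divergence, and draw
    beta from the N(beta_hat, cov) posterior approximation.
    ``start_ridged`` skips straight to the penalised fit (hint from a
    caller that keeps seeing separation on this response)."""
    ridged = start_ridged
    if not start_ridged:
        beta, cov, ok = _logistic_fit(X, y, ridge=0.0)
        if not ok or not np.all(np.isfinite(cov)) or np.max(np.abs(beta)) > SEPARATION_BOUND:
            ridged = True
    if ridged:
        beta, cov, ok = _logistic_fit(X, y, ridge=_retry_ridge(n_total))
        # the penalised optimum is finite; convergence is the only criterion
        if not ok or not np.all(np.isfinite(cov)):
            raise SeparationError(
                f"divergent logistic fit (max|beta|={np.max(np.abs(beta)):.3g})"
            )
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh((cov + cov.T) / 2)
        chol = v * np.sqrt(np.clip(w, 0, None))
    beta_star = beta + chol @ rng.standard_normal(len(beta))
    return beta_star, ridged


def impute_binary(
    y: np.ndarray,
    X: np.ndarray,
    missing: np.ndarray,
    rng: np.random.Generator,
    start_ridged: bool = False,
) -> ImputerResult:
    """Logistic-regression imputation with an asymptotic-normal posterior
    draw of the coefficients; y is 0/1 on observed rows."""
    missing = np.asarray(missing, dtype=bool)
    obs = ~missing
    if not missing.any():
        return ImputerResult(np.empty(0, dtype=np.int16), int(obs.sum()), X.shape[1])
    yo = np.asarray(y, dtype=float)[obs]
    if yo.min() == yo.max():
        raise SeparationError("observed response is constant")
    Xi = _with_intercept(np.asarray(X, dtype=float))
    Xp, dropped_i = _maybe_prune(Xi[obs])
    dropped = [d - 1 for d in dropped_i]
    _check_rows(Xp.shape[0], Xp.shape[1])
    Xs, scales = _scale_columns(Xp)
    beta_star, ridged = _glm_beta_draw(Xs, yo, Xi.shape[0], rng, start_ridged)
    keep = sorted(set(range(Xi.shape[1])) - set(dropped_i))
    Xmis = Xi[missing][:, keep] / scales
    p_mis = expit(Xmis @ beta_star)
    draws = (rng.random(len(p_mis)) < p_mis).astype(np.int16)
    return ImputerResult(draws, Xp.shape[0], Xi.shape[1] - 1, dropped, ridged)


def _multinomial_fit(
    X: np.ndarray, Y: np.ndarray, ridge: float, max_iter: int = 60, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Newton multinomial logit: Y is n x (L-1) indicator matrix (reference
    level = all-zero row).  Returns (beta (L-1)*p flat, cov, converged)."""
    n, p = X.shape
    m = Y.shape[1]
    beta = np.zeros(m * p)
    lam = ridge * np.eye(m * p)
    for j in range(m):
        lam[j * p, j * p] = 0.0
    ll_old = -np.inf
    converged = False

    def loglik(b: np.ndarray) -> tuple[float, np.ndarray]:
        eta = X @ b.reshape(m, p).T  # n x m
        full = np.column_stack([np.zeros(n), eta])
        pr = softmax(full, axis=1)  # n x (m+1); column 0 = reference
        lse = np.log(np.exp(full - full.max(axis=1, keepdims=True)).sum(axis=1))
        ll = float(np.sum(eta * Y) - np.sum(lse + full.max(axis=1)))
        return ll - 0.5 * b @ lam @ b, pr[:, 1:]

    for _ in range(max_iter):
        ll, P = loglik(beta)
        g = (X.T @ (Y - P)).T.reshape(-1) - lam @ beta  # (m*p,)
        h = np.empty((m * p, m * p))
        for a in range(m):
            for b_ in range(m):
                w = P[:, a] * ((a == b_) - P[:, b_])
                h[a * p : (a + 1) * p, b_ * p : (b_ + 1) * p] = (X * w[:, None]).T @ X
        h += lam
        try:
            step = np.linalg.solve(h, g)
        except np.linalg.LinAlgError:
            return beta, np.full((m * p, m * p), np.nan), False
        for _ in range(20):
            cand = beta + step
            ll_c, _ = loglik(cand)
            if ll_c >= ll - 1e-12:
                break
            step = step / 2
        beta = beta + step
        if np.max(np.abs(beta)) > 2 * SEPARATION_BOUND:
            return beta, np.full((m * p, m * p), np.nan), False
        if abs(ll_c - ll_old) < tol * (abs(ll_old) + 1.0):
            converged = True
            break
        ll_old = ll_c
    _, P = loglik(beta)
    h = np.empty((m * p, m * p))
    for a in range(m):
        for b_ in range(m):
            w = P[:, a] * ((a == b_) - P[:, b_])
            h[a * p : (a + 1) * p, b_ * p : (b_ + 1) * p] = (X * w[:, None]).T @ X
    h += lam
    try:
        cov = np.linalg.inv(h)
    except np.linalg.LinAlgError:
        cov = np.full_like(h, np.nan)
        converged = False
    return beta, cov, converged


def impute_categorical(
    y: np.ndarray,
    X: np.ndarray,
    missing: np.ndarray,
    rng: np.random.Generator,
    n_levels: int,
    start_ridged: bool = False,
) -> ImputerResult:
    """Multinomial-logit imputation over integer level codes 0..L-1.

    The most frequent observed level is the reference (ties broken by
    lowest code).  Declared levels never observed get probability zero.
    """
    missing = np.asarray(missing, dtype=bool)
    obs = ~missing
    if not missing.any():
        return ImputerResult(np.empty(0, dtype=np.int16), int(obs.sum()), X.shape[1])
    yo = np.asarray(y)[obs].astype(int)
    counts = np.bincount(yo, minlength=n_levels)
    present = np.flatnonzero(counts > 0)
    if len(present) < 2:
        if len(present) == 0:
            raise ImputerError("no observed values for categorical response")
        draws = np.full(int(missing.sum()), present[0], dtype=np.int16)
        return ImputerResult(draws, int(obs.sum()), X.shape[1])
    ref = int(present[np.argmax(counts[present])])  # argmax keeps lowest on ties
    others = [lev for lev in present if lev != ref]

    if len(others) == 1:
        # two observed levels: delegate to the binary imputer
        res = impute_binary(
            (np.asarray(y) == others[0]).astype(float), X, missing, rng, start_ridged
        )
        out = np.where(res.values == 1, others[0], ref).astype(np.int16)
        return ImputerResult(out, res.n_obs, res.n_predictors, res.dropped, res.ridged)

    Xi = _with_intercept(np.asarray(X, dtype=float))
    Xp, dropped_i = _maybe_prune(Xi[obs])
    dropped = [d - 1 for d in dropped_i]
    _check_rows(Xp.shape[0], Xp.shape[1] * len(others))
    Xs, scales = _scale_columns(Xp)
    Y = np.column_stack([(yo == lev).astype(float) for lev in others])
    n_total = Xi.shape[0]
    ridged = start_ridged
    if not start_ridged:
        beta, cov, ok = _multinomial_fit(Xs, Y, ridge=0.0)
        if not ok or not np.all(np.isfinite(cov)) or np.max(np.abs(beta)) > SEPARATION_BOUND:
            ridged = True
    if ridged:
        beta, cov, ok = _multinomial_fit(Xs, Y, ridge=_retry_ridge(n_total))
        if not ok or not np.all(np.isfinite(cov)):
            raise SeparationError("divergent multinomial fit")
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh((cov + cov.T) / 2)
        chol = v * np.sqrt(np.clip(w, 0, None))
    beta_star = beta + chol @ rng.standard_normal(len(beta))

    keep = sorted(set(range(Xi.shape[1])) - set(dropped_i))
    Xmis = Xi[missing][:, keep] / scales
    m = len(others)
    p = Xmis.shape[1]
    eta = Xmis @ beta_star.reshape(m, p).T
    full = np.column_stack([np.zeros(len(Xmis)), eta])
    probs = softmax(full, axis=1)  # columns: ref, others...
    cum = np.cumsum(probs, axis=1)
    u = rng.random(len(Xmis))
    pick = (u[:, None] > cum).sum(axis=1)
    level_order = np.array([ref] + others, dtype=np.int16)
    draws = level_order[np.clip(pick, 0, m)]
    return ImputerResult(draws, Xp.shape[0], Xi.shape[1] - 1, dropped, ridged)


# ---------------------------------------------------------------------------
# Initialisation
# ---------------------------------------------------------------------------

def initialize_missing(
    panel: LongitudinalPanel, rng: np.random.Generator
) -> LongitudinalPanel:
    """Fill every missing cell by sampling with replacement from the
    observed marginal of the same variable at the same block (same
    variable, for time-independent ones).  Returns a completed copy;
    the input panel is untouched."""
    out = panel.copy()
    for name, s in panel.specs.items():
        if not s.imputable:
            if not panel.mask(name).all():
                raise PanelError(f"{name}: missing values in non-imputable variable")
            continue
        v = out._values[name]
        m = out._mask[name]
        if s.time_dependent:
            for b in range(panel.n_blocks):
                mis = ~m[:, b]
                if not mis.any():
                    continue
                pool = v[m[:, b], b]
                if pool.size == 0:
                    raise PanelError(f"{name}: no observed values at block {b + 1}")
                v[mis, b] = rng.choice(pool, size=int(mis.sum()), replace=True)
                m[mis, b] = True
        else:
            mis = ~m
            if mis.any():
                pool = v[m]
                if pool.size == 0:
                    raise PanelError(f"{name}: no observed values")
                v[mis] = rng.choice(pool, size=int(mis.sum()), replace=True)
                m[mis] = True
    out.validate()
    return out
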