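"""Rubin's-rules combination of estimates across multiply imputed fits.

Pooled estimate is the mean across the K completed-data fits; total
variance is the within-imputation variance plus (1 + 1/K) times the
between-imputation variance.  Degrees of freedom use the Barnard-Rubin
small-sample adjustment when a complete-data df is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = ["PooledEstimate", "pool", "pool_fits"]


@dataclass
class PooledEstimate:
    estimate: float
    within: float
    between: float
    variance: float
    df: float
    k: int
    level: float
    ci_low: float
    ci_high: float

    @property
    def se(self) -> float:
        return float(np.sqrt(self.variance))


def _barnard_rubin_df(k: int, within: float, between: float, df_complete: Optional[float]) -> float:
    if between <= 0:
        return np.inf
    total = within + (1 + 1 / k) * between
    r = (1 + 1 / k) * between / total  # fraction of missing information
    if r**2 == 0.0:
        return np.inf
    df_old = (k - 1) / r**2
    if df_complete is None or not np.isfinite(df_complete):
        return df_old
    df_obs = (df_complete + 1) / (df_complete + 3) * df_complete * (1 - r)
    return 1.0 / (1.0 / df_old + 1.0 / df_obs)


def pool(
    estimates: Sequence[float],
    variances: Sequence[float],
    level: float = 0.95,
    df_complete: Optional[float] = None,
) -> PooledEstimate:
    """Combine K point estimates and their squared standard errors."""
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.ndim != 1 or q.shape != u.shape:
        raise ValueError("estimates and variances must be equal-length vectors")
    k = len(q)
    if k < 1:
        raise ValueError("need at least one imputed fit")
    if np.any(u < 0):
        raise ValueError("negative input variance")
    qbar = float(q.mean())
    w = float(u.mean())
    b = float(q.var(ddof=1)) if k > 1 else 0.0
    total = w + (1 + 1 / k) * b if k > 1 else w
    df = _barnard_rubin_df(k, w, b, df_complete) if k > 1 else (df_complete or np.inf)
    se = np.sqrt(total)
    if np.isfinite(df):
        tcrit = float(stats.t.ppf(0.5 + level / 2, df))
    else:
        tcrit = float(stats.norm.ppf(0.5 + level / 2))
    return PooledEstimate(
        estimate=qbar,
        within=w,
        between=b,
        variance=total,
        df=float(df),
        k=k,
        level=level,
        ci_low=qbar - tcrit * se,
        ci_high=qbar + tcrit * se,
    )


def pool_fits(
    fits: Sequence,
    level: float = 0.95,
) -> dict[str, PooledEstimate]:
    """Pool a sequence of :class:`~twofoldmi.survival.ExponentialFit`
    objects coefficient by coefficient.  Complete-data df = n - p."""
    if not fits:
        raise ValueError("no fits to pool")
    names = fits[0].names
    for f in fits:
        if f.names != names:
            raise ValueError("fits have mismatched coefficient sets")
    df_complete = fits[0].n - len(names)
    out: dict[str, PooledEstimate] = {}
    for j, nm in enumerate(names):
        ests = [float(f.coef[j]) for f in fits]
        variances = [float(f.cov[j, j]) for f in fits]
        out[nm] = pool(ests, variances, level=level, df_complete=df_complete)
    return out
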