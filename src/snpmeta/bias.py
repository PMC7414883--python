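"""Publication-bias diagnostics: Egger regression, Begg rank correlation,
and funnel-plot geometry.

Both tests probe funnel-plot asymmetry -- the tendency of small studies with
unexciting results to stay unpublished, which skews the scatter of effect
size against precision.

Egger's test regresses the standardized effect ``z_i = log_or_i / se_i`` on
the precision ``1 / se_i`` by ordinary least squares; under no small-study
effect the intercept is zero, and ``t = intercept / SE(intercept)`` is
referred to a t distribution with k - 2 df.

Begg's test rank-correlates the variance-standardized effects with their
variances using the tie-corrected Kendall tau-b and the standard normal
approximation for its significance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import InsufficientStudiesError, SingularDesignError
from .meta import Z_CRIT, EffectEstimate

__all__ = ["EggerResult", "BeggResult", "FunnelData",
           "egger_test", "begg_test", "funnel_data"]


@dataclass(frozen=True)
class EggerResult:
    intercept: float
    se: float
    t: float
    df: int
    p: float
    slope: float


@dataclass(frozen=True)
class BeggResult:
    tau: float
    z: float
    p: float


@dataclass(frozen=True)
class FunnelData:
    """Scatter points (log_or, se) plus pseudo-95%-CI funnel bounds.

    ``center`` is the fixed inverse-variance pooled log-OR; the bounds are
    ``center +/- 1.96 * se`` evaluated over ``se_grid``.
    """

    log_or: np.ndarray
    se: np.ndarray
    center: float
    se_grid: np.ndarray
    lower: np.ndarray
    upper: np.ndarray


def egger_test(effects: Sequence[EffectEstimate]) -> EggerResult:
    """Egger's linear-regression test for funnel asymmetry.

    Needs k >= 3 studies; a design with (numerically) identical precisions
    is singular and rejected.
    """
    k = len(effects)
    if k < 3:
        raise InsufficientStudiesError("Egger's test needs at least 3 studies")
    se = np.array([e.se for e in effects])
    z = np.array([e.log_or for e in effects]) / se
    precision = 1.0 / se
    if np.ptp(precision) < 1e-12 * max(1.0, float(np.abs(precision).max())):
        raise SingularDesignError("all precisions equal; Egger design is singular")
    x = np.column_stack([np.ones(k), precision])
    coef, *_ = np.linalg.lstsq(x, z, rcond=None)
    resid = z - x @ coef
    df = k - 2
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(x.T @ x)
    intercept = float(coef[0])
    se_int = math.sqrt(cov[0, 0])
    t = intercept / se_int
    p = float(2.0 * stats.t.sf(abs(t), df=df))
    return EggerResult(intercept=intercept, se=se_int, t=t, df=df, p=p,
                       slope=float(coef[1]))


def begg_test(effects: Sequence[EffectEstimate]) -> BeggResult:
    """Begg-Mazumdar rank-correlation test for funnel asymmetry.

    Each effect is centred on the fixed inverse-variance mean and divided by
    the adjusted standard error ``sqrt(var_i - 1/sum(1/var_j))`` (the
    variance of the deviation from the pooled mean); Kendall's tau-b between
    these standardized deviates and the variances is then referred to the
    normal approximation ``z = tau / sqrt(2(2k+5) / (9k(k-1)))`` with no
    continuity correction.
    """
    k = len(effects)
    if k < 3:
        raise InsufficientStudiesError("Begg's test needs at least 3 studies")
    var = np.array([e.var_log_or for e in effects])
    theta = np.array([e.log_or for e in effects])
    w = 1.0 / var
    theta_iv = float(np.sum(w * theta) / np.sum(w))
    v_star = var - 1.0 / np.sum(w)
    t_star = (theta - theta_iv) / np.sqrt(v_star)
    tau = float(stats.kendalltau(t_star, var).statistic)
    z = tau / math.sqrt(2.0 * (2 * k + 5) / (9.0 * k * (k - 1)))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return BeggResult(tau=tau, z=z, p=p)


def funnel_data(effects: Sequence[EffectEstimate],
                n_grid: int = 50) -> FunnelData:
    """Points and pseudo-95% bounds for a Begg-style funnel plot."""
    if not effects:
        raise InsufficientStudiesError("funnel needs at least 1 study")
    se = np.array([e.se for e in effects])
    log_or = np.array([e.log_or for e in effects])
    w = 1.0 / se**2
    center = float(np.sum(w * log_or) / np.sum(w))
    se_grid = np.linspace(0.0, float(se.max()) * 1.05, n_grid)
    return FunnelData(
        log_or=log_or,
        se=se,
        center=center,
        se_grid=se_grid,
        lower=center - Z_CRIT * se_grid,
        upper=center + Z_CRIT * se_grid,
    )
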