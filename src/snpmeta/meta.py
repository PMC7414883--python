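"""Per-study odds ratios, heterogeneity, and pooled meta-analysis.

The pooling rule mirrors classical two-step practice for case-control SNP
meta-analysis:

1. compute each study's log odds ratio with its Woolf variance
   ``1/a + 1/b + 1/c + 1/d``;
2. test between-study heterogeneity with Cochran's Q (inverse-variance
   weights around the inverse-variance mean) and summarise it as
   ``I^2 = max(0, 100 * (Q - df) / Q)``;
3. pool by the fixed-effect Mantel-Haenszel method when the Q-test p-value
   exceeds the gate (0.05 by default), otherwise by DerSimonian-Laird
   random effects.

The Mantel-Haenszel log-OR standard error uses the Robins-Breslow-Greenland
variance, which is consistent under both sparse-data and large-stratum
asymptotics and reduces exactly to the Woolf variance for a single study.
Significance of the pooled OR is a two-sided normal Z-test on the log scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

from scipy import stats

from .exceptions import InsufficientStudiesError, ZeroCellError
from .models import TwoByTwo, continuity_correct

__all__ = [
    "Z_CRIT",
    "EffectEstimate",
    "Heterogeneity",
    "PooledResult",
    "study_effect",
    "cochran_q",
    "pool_fixed_mh",
    "pool_random_dl",
    "select_and_pool",
]

#: Two-sided 95% normal critical value.
Z_CRIT = 1.959964


@dataclass(frozen=True)
class EffectEstimate:
    """One study's effect: log odds ratio with Woolf variance."""

    log_or: float
    var_log_or: float

    def __post_init__(self) -> None:
        if self.var_log_or <= 0:
            raise ValueError("variance of the log odds ratio must be > 0")

    @property
    def se(self) -> float:
        return math.sqrt(self.var_log_or)

    @property
    def or_(self) -> float:
        return math.exp(self.log_or)

    @property
    def ci_low(self) -> float:
        return math.exp(self.log_or - Z_CRIT * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.log_or + Z_CRIT * self.se)


class Heterogeneity(NamedTuple):
    """Cochran's Q with its chi-square p-value and the I^2 percentage."""

    q: float
    p: float
    i2: float


@dataclass(frozen=True)
class PooledResult:
    """A pooled odds ratio with its inference and heterogeneity summary.

    ``method`` is ``"fixed_MH"`` or ``"random_DL"``.  Heterogeneity fields
    (``q``, ``p_het``, ``i2``, ``tau2``) are ``None`` for single-study
    "pools", where no heterogeneity assessment exists.
    """

    k: int
    method: str
    log_or: float
    se: float
    z: float
    p: float
    q: float | None = None
    p_het: float | None = None
    i2: float | None = None
    tau2: float | None = None

    @property
    def pooled_or(self) -> float:
        return math.exp(self.log_or)

    @property
    def ci_low(self) -> float:
        return math.exp(self.log_or - Z_CRIT * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.log_or + Z_CRIT * self.se)


def _z_p(log_or: float, se: float) -> tuple[float, float]:
    z = log_or / se
    return z, float(2.0 * stats.norm.sf(abs(z)))


def study_effect(table: TwoByTwo) -> EffectEstimate:
    """Woolf log odds ratio and variance for one 2x2 table.

    All four cells must be positive; zero cells raise
    :class:`~snpmeta.exceptions.ZeroCellError` directing the caller to
    :func:`~snpmeta.models.continuity_correct`.
    """
    a, b, c, d = table.cells
    if min(a, b, c, d) <= 0:
        raise ZeroCellError(
            "2x2 table has an empty cell; apply continuity_correct first"
        )
    return EffectEstimate(
        log_or=math.log(a * d / (b * c)),
        var_log_or=1 / a + 1 / b + 1 / c + 1 / d,
    )


def effects_from_tables(tables: Sequence[TwoByTwo]) -> list[EffectEstimate]:
    """Continuity-correct each table and return its Woolf effect estimate."""
    return [study_effect(continuity_correct(t)) for t in tables]


def cochran_q(effects: Sequence[EffectEstimate],
              center: float | None = None) -> Heterogeneity:
    """Cochran's Q heterogeneity test on inverse-variance weighted effects.

    Q is the weighted sum of squared deviations of the study log-ORs from
    a pooled mean; its null distribution is chi-square with k-1 df.
    I^2 = max(0, 100*(Q - (k-1))/Q) expresses the share of total variation
    attributable to between-study heterogeneity.

    ``center`` defaults to the inverse-variance pooled mean.  The 2x2-table
    pipeline instead passes the Mantel-Haenszel pooled log-OR, the
    convention of the classical meta-analysis software for count data (the
    two agree closely; the choice only moves the last printed digit).
    """
    k = len(effects)
    if k < 2:
        raise InsufficientStudiesError("heterogeneity needs at least 2 studies")
    w = [1.0 / e.var_log_or for e in effects]
    if center is None:
        center = sum(wi * e.log_or for wi, e in zip(w, effects)) / sum(w)
    q = sum(wi * (e.log_or - center) ** 2 for wi, e in zip(w, effects))
    p = float(stats.chi2.sf(q, df=k - 1))
    i2 = max(0.0, 100.0 * (q - (k - 1)) / q) if q > 0 else 0.0
    return Heterogeneity(q=q, p=p, i2=i2)


def _mh_log_or_se(tables: Sequence[TwoByTwo]) -> tuple[float, float]:
    """Mantel-Haenszel pooled log-OR and its Robins-Breslow-Greenland SE."""
    R = S = 0.0
    sum_PR = sum_PSQR = sum_QS = 0.0
    for t in tables:
        a, b, c, d = t.cells
        n = t.n
        Ri = a * d / n
        Si = b * c / n
        Pi = (a + d) / n
        Qi = (b + c) / n
        R += Ri
        S += Si
        sum_PR += Pi * Ri
        sum_PSQR += Pi * Si + Qi * Ri
        sum_QS += Qi * Si
    if R == 0 or S == 0:
        raise ZeroCellError(
            "Mantel-Haenszel sums are zero; apply continuity correction"
        )
    var = sum_PR / (2 * R * R) + sum_PSQR / (2 * R * S) + sum_QS / (2 * S * S)
    return math.log(R / S), math.sqrt(var)


def pool_fixed_mh(tables: Sequence[TwoByTwo],
                  het: Heterogeneity | None = None) -> PooledResult:
    """Fixed-effect Mantel-Haenszel pooled odds ratio.

    ``OR_MH = sum(a_i d_i / n_i) / sum(b_i c_i / n_i)`` with the
    Robins-Breslow-Greenland variance for its log.  Heterogeneity fields are
    filled from Cochran's Q on the Woolf effects (computed here unless an
    already-computed ``het`` is passed in); they stay ``None`` for k = 1.
    """
    k = len(tables)
    if k < 1:
        raise InsufficientStudiesError("pooling needs at least 1 study")
    corrected = [continuity_correct(t) for t in tables]
    log_or, se = _mh_log_or_se(corrected)
    z, p = _z_p(log_or, se)
    if het is None and k >= 2:
        het = cochran_q([study_effect(t) for t in corrected], center=log_or)
    if het is None:
        return PooledResult(k=k, method="fixed_MH", log_or=log_or, se=se, z=z, p=p)
    return PooledResult(
        k=k, method="fixed_MH", log_or=log_or, se=se, z=z, p=p,
        q=het.q, p_het=het.p, i2=het.i2, tau2=0.0,
    )


def pool_random_dl(effects: Sequence[EffectEstimate],
                   het: Heterogeneity | None = None) -> PooledResult:
    """DerSimonian-Laird random-effects pooled odds ratio.

    The moment estimator ``tau2 = max(0, (Q - (k-1)) / (sum w - sum w^2 /
    sum w))`` inflates each study's variance; the pooled log-OR is the
    re-weighted mean with SE ``1/sqrt(sum w*)``.  With Q <= k-1 the
    estimator truncates to zero and the result coincides with
    inverse-variance fixed pooling.
    """
    k = len(effects)
    if k < 2:
        raise InsufficientStudiesError("random-effects pooling needs >= 2 studies")
    if het is None:
        het = cochran_q(effects)
    w = [1.0 / e.var_log_or for e in effects]
    sw = sum(w)
    tau2 = max(0.0, (het.q - (k - 1)) / (sw - sum(wi * wi for wi in w) / sw))
    w_star = [1.0 / (e.var_log_or + tau2) for e in effects]
    sws = sum(w_star)
    log_or = sum(wi * e.log_or for wi, e in zip(w_star, effects)) / sws
    se = math.sqrt(1.0 / sws)
    z, p = _z_p(log_or, se)
    return PooledResult(
        k=k, method="random_DL", log_or=log_or, se=se, z=z, p=p,
        q=het.q, p_het=het.p, i2=het.i2, tau2=tau2,
    )


def select_and_pool(tables: Sequence[TwoByTwo],
                    het_alpha: float = 0.05) -> PooledResult:
    """Heterogeneity-gated pooling of 2x2 tables.

    Computes the Q-test on the Woolf effects; pools fixed Mantel-Haenszel
    when the heterogeneity p-value is strictly greater than ``het_alpha``
    (a p-value exactly at the gate routes to random effects), otherwise
    DerSimonian-Laird.  A single table is returned as its own study-level
    estimate with no heterogeneity fields.
    """
    k = len(tables)
    if k < 1:
        raise InsufficientStudiesError("pooling needs at least 1 study")
    if k == 1:
        return pool_fixed_mh(tables)
    corrected = [continuity_correct(t) for t in tables]
    effects = [study_effect(t) for t in corrected]
    mh_log_or, _ = _mh_log_or_se(corrected)
    het = cochran_q(effects, center=mh_log_or)
    if het.p > het_alpha:
        return pool_fixed_mh(tables, het=het)
    return pool_random_dl(effects, het=het)
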