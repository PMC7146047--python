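"""Per-study odds ratios, heterogeneity, and fixed/random-effects pooling.

Per-study effects are Woolf log odds ratios with a Haldane-Anscombe 0.5
correction applied to all four cells of a table only when a zero cell
occurs.  Heterogeneity is Cochran's Q on inverse-variance weights with the
DerSimonian-Laird moment estimate of the between-study variance tau^2.
Fixed-effect pooling is Mantel-Haenszel on the raw count tables, with the
Robins-Breslow-Greenland variance for its log odds ratio; random-effects
pooling is DerSimonian-Laird inverse-variance on the log scale.  Model
selection follows the conventional heterogeneity rule: fixed effects when
the Q-test p-value exceeds a threshold (default 0.10), random effects
otherwise, applied independently to each analysis set.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .genetic_models import ContrastTable, GeneticModel

__all__ = [
    "EffectModel",
    "EffectEstimate",
    "HeterogeneityResult",
    "PooledResult",
    "study_effect",
    "cochran_q",
    "pool_mh",
    "pool_dl",
    "select_and_pool",
]

Z975 = 1.959963984540054  # normal 97.5% quantile for Wald intervals


class EffectModel(str, enum.Enum):
    FIXED_MH = "fixed_MH"
    RANDOM_DL = "random_DL"


@dataclass(frozen=True)
class EffectEstimate:
    """One study's log odds ratio with its standard error and 95% Wald CI."""

    study_id: str
    log_or: float
    se: float
    or_: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran Q with df, p, I^2, and the DL tau^2 moment estimate."""

    q: float
    df: int
    p_value: float
    i2: float
    tau2: float


@dataclass(frozen=True)
class PooledResult:
    """A pooled odds ratio with CI, Z test, and heterogeneity diagnostics."""

    model: Optional[GeneticModel]
    effect_model: EffectModel
    or_: float
    ci_low: float
    ci_high: float
    z: float
    p_value: float
    heterogeneity: Optional[HeterogeneityResult]
    k: int
    per_study: tuple[EffectEstimate, ...]


def study_effect(table: ContrastTable, continuity: float = 0.5) -> EffectEstimate:
    """Woolf log-OR and SE for a 2x2 table.

    If any cell is zero, `continuity` is added to all four cells first.  A
    table with an empty row or column (two zero cells sharing a margin)
    leaves the OR undefined and raises ``ValueError``.
    """
    a, b, c, d = (float(x) for x in table.cells())
    if (a == 0 and b == 0) or (c == 0 and d == 0) or (a == 0 and c == 0) or (b == 0 and d == 0):
        raise ValueError(f"effect undefined for study {table.study_id!r}: empty margin")
    if min(a, b, c, d) == 0.0:
        a, b, c, d = a + continuity, b + continuity, c + continuity, d + continuity
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EffectEstimate(
        study_id=table.study_id,
        log_or=log_or,
        se=se,
        or_=math.exp(log_or),
        ci_low=math.exp(log_or - Z975 * se),
        ci_high=math.exp(log_or + Z975 * se),
    )


def cochran_q(effects: Sequence[EffectEstimate]) -> HeterogeneityResult:
    """Cochran's Q about the inverse-variance fixed-effect mean, plus DL tau^2.

    I^2 = max(0, (Q - df)/Q); tau^2 = max(0, (Q - df)/(sum w - sum w^2 / sum w)).
    """
    k = len(effects)
    if k < 2:
        raise ValueError("heterogeneity requires at least two studies")
    y = np.array([e.log_or for e in effects])
    w = np.array([1.0 / e.se**2 for e in effects])
    theta = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - theta) ** 2))
    df = k - 1
    p = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    return HeterogeneityResult(q=q, df=df, p_value=p, i2=i2, tau2=tau2)


def _finish(
    log_or: float,
    se: float,
    effect_model: EffectModel,
    het: Optional[HeterogeneityResult],
    effects: Sequence[EffectEstimate],
    model: Optional[GeneticModel],
) -> PooledResult:
    z = log_or / se
    return PooledResult(
        model=model,
        effect_model=effect_model,
        or_=math.exp(log_or),
        ci_low=math.exp(log_or - Z975 * se),
        ci_high=math.exp(log_or + Z975 * se),
        z=z,
        p_value=float(2 * stats.norm.sf(abs(z))),
        heterogeneity=het,
        k=len(effects),
        per_study=tuple(effects),
    )


def pool_mh(tables: Sequence[ContrastTable]) -> PooledResult:
    """Mantel-Haenszel fixed-effect pooled OR over raw 2x2 count tables.

    OR_MH = sum(a_i d_i / n_i) / sum(b_i c_i / n_i); the variance of
    log OR_MH is Robins-Breslow-Greenland.  Zero cells need no correction
    here, but a table with an empty margin contributes nothing and is
    rejected; with k = 1 the result reduces to the single-study estimate.
    """
    if not tables:
        raise ValueError("no tables to pool")
    a = np.array([t.a for t in tables], dtype=float)
    b = np.array([t.b for t in tables], dtype=float)
    c = np.array([t.c for t in tables], dtype=float)
    d = np.array([t.d for t in tables], dtype=float)
    n = a + b + c + d
    R = float(np.sum(a * d / n))
    S = float(np.sum(b * c / n))
    if R == 0.0 or S == 0.0:
        raise ValueError("Mantel-Haenszel OR undefined: a*d or b*c vanishes in every table")
    log_or = math.log(R / S)
    P = (a + d) / n
    Q = (b + c) / n
    var = (
        float(np.sum(P * a * d / n)) / (2 * R * R)
        + float(np.sum(P * b * c / n + Q * a * d / n)) / (2 * R * S)
        + float(np.sum(Q * b * c / n)) / (2 * S * S)
    )
    se = math.sqrt(var)
    effects = [study_effect(t) for t in tables]
    het = cochran_q(effects) if len(effects) >= 2 else None
    model = tables[0].model if len({t.model for t in tables}) == 1 else None
    return _finish(log_or, se, EffectModel.FIXED_MH, het, effects, model)


def pool_dl(
    effects: Sequence[EffectEstimate],
    model: Optional[GeneticModel] = None,
    het: Optional[HeterogeneityResult] = None,
) -> PooledResult:
    """DerSimonian-Laird random-effects pooled OR from per-study effects.

    Weights are 1/(se^2 + tau^2) with tau^2 the DL moment estimate (computed
    here unless supplied).  With homogeneous effects (tau^2 = 0) this
    coincides with inverse-variance fixed pooling.
    """
    if len(effects) < 2:
        raise ValueError("random-effects pooling requires at least two studies")
    if het is None:
        het = cochran_q(effects)
    y = np.array([e.log_or for e in effects])
    w = np.array([1.0 / (e.se**2 + het.tau2) for e in effects])
    theta = float(np.sum(w * y) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    return _finish(theta, se, EffectModel.RANDOM_DL, het, effects, model)


def select_and_pool(
    tables: Sequence[ContrastTable], threshold: float = 0.10
) -> PooledResult:
    """Heterogeneity-driven pooling: MH fixed if Q-test p > threshold, else DL.

    The returned result records which effect model was used.
    """
    if len(tables) < 2:
        raise ValueError("pooling with model selection requires at least two studies")
    effects = [study_effect(t) for t in tables]
    het = cochran_q(effects)
    if het.p_value > threshold:
        return pool_mh(tables)
    model = tables[0].model if len({t.model for t in tables}) == 1 else None
    return pool_dl(effects, model=model, het=het)
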