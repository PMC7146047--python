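"""Publication-bias diagnostics and leave-one-out sensitivity analysis.

Egger's test regresses each study's standard normal deviate (log OR / SE)
on its precision (1 / SE) by ordinary least squares; the intercept estimates
funnel-plot asymmetry and is tested against a t distribution with k - 2
degrees of freedom.  Begg's rank-correlation test computes the Kendall score
between effect sizes standardized against the inverse-variance pooled mean
(using v_i* = se_i^2 - (sum_j 1/se_j^2)^-1) and their variances; the
normalized score is referred to the normal distribution, optionally with the
+/-1 continuity adjustment.  Leave-one-out sensitivity re-pools after
omitting each study in turn and flags a study as influential when the
estimate is unstable: the re-pooled OR falls outside the all-study
confidence interval, or the all-study OR falls outside the re-pooled
interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .association_stats import (
    EffectEstimate,
    PooledResult,
    select_and_pool,
    study_effect,
)
from .genetic_models import ContrastTable

__all__ = [
    "BiasTestResult",
    "LeaveOneOutResult",
    "egger_test",
    "begg_test",
    "leave_one_out",
    "funnel_data",
    "BEGG_CONTINUITY_DEFAULT",
]

#: Global default for the Begg continuity adjustment.  The uncorrected
#: statistic is the primary one reported; the corrected variant is available
#: through the ``continuity`` flag.
BEGG_CONTINUITY_DEFAULT = False


@dataclass(frozen=True)
class BiasTestResult:
    """Egger regression and/or Begg rank-correlation outputs.

    Fields belonging to a test that was not run are ``None``.
    """

    k: int
    egger_intercept: Optional[float] = None
    egger_se: Optional[float] = None
    egger_t: Optional[float] = None
    egger_p: Optional[float] = None
    egger_ci_low: Optional[float] = None
    egger_ci_high: Optional[float] = None
    egger_slope: Optional[float] = None
    begg_s: Optional[int] = None
    begg_z: Optional[float] = None
    begg_p: Optional[float] = None


@dataclass(frozen=True)
class LeaveOneOutResult:
    """Re-pooled result after omitting one study, with the influence flag."""

    omitted_study: str
    pooled: PooledResult
    influential: bool


def egger_test(effects: Sequence[EffectEstimate]) -> BiasTestResult:
    """Egger's regression asymmetry test.

    OLS of log_or_i/se_i on 1/se_i; intercept, its SE, t = intercept/SE with
    k - 2 df, two-sided p, and the 95% t-based CI of the intercept.
    """
    k = len(effects)
    if k < 3:
        raise ValueError("Egger's test requires at least three studies")
    snd = np.array([e.log_or / e.se for e in effects])
    precision = np.array([1.0 / e.se for e in effects])
    if np.ptp(precision) == 0.0:
        raise ValueError("Egger regression degenerate: all study precisions equal")
    fit = sm.OLS(snd, sm.add_constant(precision)).fit()
    intercept, slope = fit.params
    se_int = fit.bse[0]
    t = intercept / se_int
    p = float(2 * stats.t.sf(abs(t), k - 2))
    tcrit = float(stats.t.ppf(0.975, k - 2))
    return BiasTestResult(
        k=k,
        egger_intercept=float(intercept),
        egger_se=float(se_int),
        egger_t=float(t),
        egger_p=p,
        egger_ci_low=float(intercept - tcrit * se_int),
        egger_ci_high=float(intercept + tcrit * se_int),
        egger_slope=float(slope),
    )


def begg_test(
    effects: Sequence[EffectEstimate], continuity: bool = BEGG_CONTINUITY_DEFAULT
) -> BiasTestResult:
    """Begg-Mazumdar rank-correlation test for funnel-plot asymmetry.

    Standardizes deviations from the inverse-variance pooled mean with
    v_i* = se_i^2 - (sum 1/se_j^2)^-1, computes the Kendall score S against
    the variances over all study pairs, and refers
    z = (|S| - adj) / sqrt(k(k-1)(2k+5)/18) to the standard normal
    (adj = 1 when ``continuity`` else 0).
    """
    k = len(effects)
    if k < 2:
        raise ValueError("Begg's test requires at least two studies")
    y = np.array([e.log_or for e in effects])
    v = np.array([e.se**2 for e in effects])
    w = 1.0 / v
    theta = float(np.sum(w * y) / np.sum(w))
    vstar = v - 1.0 / np.sum(w)
    u = (y - theta) / np.sqrt(vstar)
    s = 0
    for i, j in combinations(range(k), 2):
        s += int(np.sign((u[j] - u[i]) * (v[j] - v[i])))
    sd = math.sqrt(k * (k - 1) * (2 * k + 5) / 18.0)
    adj = 1.0 if continuity else 0.0
    z = max(0.0, abs(s) - adj) / sd
    return BiasTestResult(k=k, begg_s=s, begg_z=z, begg_p=float(2 * stats.norm.sf(z)))


def leave_one_out(
    tables: Sequence[ContrastTable], threshold: float = 0.10
) -> list[LeaveOneOutResult]:
    """Omit each study in turn and re-pool the remainder.

    A study is flagged influential when its omission destabilizes the
    estimate: the re-pooled OR lies outside the all-study CI, or the
    all-study OR lies outside the re-pooled CI.
    """
    k = len(tables)
    if k < 3:
        raise ValueError("leave-one-out requires at least three studies")
    full = select_and_pool(tables, threshold=threshold)
    out = []
    for i, omitted in enumerate(tables):
        rest = [t for j, t in enumerate(tables) if j != i]
        pooled = select_and_pool(rest, threshold=threshold)
        moved = not (full.ci_low <= pooled.or_ <= full.ci_high)
        full_moved = not (pooled.ci_low <= full.or_ <= pooled.ci_high)
        out.append(
            LeaveOneOutResult(
                omitted_study=omitted.study_id, pooled=pooled,
                influential=moved or full_moved,
            )
        )
    return out


def funnel_data(effects: Sequence[EffectEstimate], n_guide: int = 50) -> pd.DataFrame:
    """Funnel-plot coordinates: per-study points plus pseudo-95%-CI guides.

    Returns a tidy frame with a ``kind`` column: ``study`` rows carry
    (study_id, log_or, se); ``guide`` rows trace the fixed-effect pooled mean
    and the +/-1.96*se limits over a grid of standard errors from 0 to the
    largest observed SE.
    """
    rows = [
        {"kind": "study", "study_id": e.study_id, "log_or": e.log_or, "se": e.se}
        for e in effects
    ]
    if effects:
        y = np.array([e.log_or for e in effects])
        w = np.array([1.0 / e.se**2 for e in effects])
        theta = float(np.sum(w * y) / np.sum(w))
        for se in np.linspace(0.0, max(e.se for e in effects), n_guide):
            rows.append(
                {
                    "kind": "guide",
                    "study_id": "",
                    "log_or": theta,
                    "se": se,
                    "lower": theta - 1.959963984540054 * se,
                    "upper": theta + 1.959963984540054 * se,
                }
            )
    return pd.DataFrame(rows)


def effects_from_tables(tables: Sequence[ContrastTable]) -> list[EffectEstimate]:
    """Per-study effects for the bias tests, sharing the pooling conventions."""
    return [study_effect(t) for t in tables]
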