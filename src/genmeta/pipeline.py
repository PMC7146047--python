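"""End-to-end analysis: subgroup pooling, bias tests, sensitivity, reporting.

`run_analysis` takes one analysis set of studies and a plan naming the
strata (total, ethnicity, source of control, AMD type, genotyping method)
and genetic models to pool.  Each stratum x model cell with at least two
studies is pooled under the heterogeneity rule (fixed Mantel-Haenszel when
the Q-test p exceeds the threshold, DerSimonian-Laird otherwise, decided
cell by cell); single-study strata are reported un-pooled with the study's
own effect.  Egger and Begg tests and leave-one-out sensitivity run on the
full set per genetic model.  `reproduce_published` wires the three embedded
fixture tables through the exact stratification of the published analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .association_stats import EffectEstimate, PooledResult, select_and_pool, study_effect
from .bias_sensitivity import (
    BEGG_CONTINUITY_DEFAULT,
    BiasTestResult,
    LeaveOneOutResult,
    begg_test,
    egger_test,
    leave_one_out,
)
from .genetic_models import GeneticModel, build_contrast
from .study_table import StudyRecord, load_fixture, total_sample_sizes

__all__ = [
    "AnalysisPlan",
    "StratumResult",
    "ResultsTable",
    "run_analysis",
    "render_report",
    "default_plan",
    "reproduce_published",
]

_FACTORS = {
    "total": lambda r: True,
    "ethnicity": lambda r: r.ethnicity.value,
    "source_of_control": lambda r: r.source_of_control.value,
    "amd_type": lambda r: r.amd_type.value,
    "genotyping": lambda r: r.genotyping.value,
}


@dataclass(frozen=True)
class AnalysisPlan:
    """Which SNP, strata, and genetic models to analyse, and the thresholds."""

    snp: str
    strata: tuple[tuple[str, str], ...]
    models: tuple[GeneticModel, ...] = tuple(GeneticModel)
    q_threshold: float = 0.10
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.q_threshold < 1.0:
            raise ValueError("q_threshold must lie in (0, 1)")
        for factor, _level in self.strata:
            if factor not in _FACTORS:
                raise ValueError(
                    f"unknown stratum factor {factor!r}; known: {sorted(_FACTORS)}"
                )


@dataclass(frozen=True)
class StratumResult:
    """Pooling outcome for one stratum across all requested models.

    ``pooled[model]`` is None when the stratum has fewer than two studies;
    ``single_effects`` then carries the per-study estimate.
    """

    factor: str
    level: str
    k: int
    n_case: int
    n_control: int
    pooled: dict[GeneticModel, Optional[PooledResult]]
    single_effects: dict[GeneticModel, Optional[EffectEstimate]] = field(
        default_factory=dict
    )


@dataclass(frozen=True)
class ResultsTable:
    """Full analysis output mirroring a published meta-analysis table pair."""

    snp: str
    plan: AnalysisPlan
    rows: tuple[StratumResult, ...]
    bias: dict[GeneticModel, BiasTestResult]
    sensitivity: dict[GeneticModel, tuple[LeaveOneOutResult, ...]]


def _select(studies: Sequence[StudyRecord], factor: str, level: str) -> list[StudyRecord]:
    if factor == "total":
        return list(studies)
    key = _FACTORS[factor]
    return [s for s in studies if key(s) == level]


def default_plan(snp: str, studies: Sequence[StudyRecord]) -> AnalysisPlan:
    """A plan with one stratum per observed level of every subgroup factor.

    Always includes the total stratum; subgroup strata are emitted in order
    of first appearance.  With fewer than four studies only the total
    stratum is planned (subgroups too sparse to analyse separately).
    """
    strata: list[tuple[str, str]] = [("total", "all")]
    if len(studies) >= 4:
        for factor in ("ethnicity", "source_of_control", "amd_type", "genotyping"):
            seen: list[str] = []
            for s in studies:
                lvl = _FACTORS[factor](s)
                if lvl not in seen:
                    seen.append(lvl)
            if len(seen) > 1:
                strata.extend((factor, lvl) for lvl in seen)
    return AnalysisPlan(snp=snp, strata=tuple(strata))


def run_analysis(studies: Sequence[StudyRecord], plan: AnalysisPlan) -> ResultsTable:
    """Execute the plan on one analysis set.

    Raises ``ValueError`` when the study list is empty or a stratum matches
    no studies.
    """
    studies = [s for s in studies if s.snp == plan.snp]
    if not studies:
        raise ValueError(f"no studies for SNP {plan.snp!r}")

    rows: list[StratumResult] = []
    for factor, level in plan.strata:
        subset = _select(studies, factor, level)
        if not subset:
            raise ValueError(f"stratum {factor}={level!r} selects no studies")
        n_case, n_control = total_sample_sizes(subset)
        pooled: dict[GeneticModel, Optional[PooledResult]] = {}
        singles: dict[GeneticModel, Optional[EffectEstimate]] = {}
        for model in plan.models:
            tables = [build_contrast(s, model) for s in subset]
            if len(tables) >= 2:
                pooled[model] = select_and_pool(tables, threshold=plan.q_threshold)
                singles[model] = None
            else:
                pooled[model] = None
                singles[model] = study_effect(tables[0])
        rows.append(
            StratumResult(
                factor=factor,
                level=level,
                k=len(subset),
                n_case=n_case,
                n_control=n_control,
                pooled=pooled,
                single_effects=singles,
            )
        )

    bias: dict[GeneticModel, BiasTestResult] = {}
    sensitivity: dict[GeneticModel, tuple[LeaveOneOutResult, ...]] = {}
    for model in plan.models:
        tables = [build_contrast(s, model) for s in studies]
        if len(tables) >= 3:
            effects = [study_effect(t) for t in tables]
            eg = egger_test(effects)
            bg = begg_test(effects, continuity=BEGG_CONTINUITY_DEFAULT)
            bias[model] = BiasTestResult(
                k=eg.k,
                egger_intercept=eg.egger_intercept,
                egger_se=eg.egger_se,
                egger_t=eg.egger_t,
                egger_p=eg.egger_p,
                egger_ci_low=eg.egger_ci_low,
                egger_ci_high=eg.egger_ci_high,
                egger_slope=eg.egger_slope,
                begg_s=bg.begg_s,
                begg_z=bg.begg_z,
                begg_p=bg.begg_p,
            )
            sensitivity[model] = tuple(leave_one_out(tables, threshold=plan.q_threshold))
    return ResultsTable(snp=plan.snp, plan=plan, rows=tuple(rows), bias=bias,
                        sensitivity=sensitivity)


# ---------------------------------------------------------------------------
# rendering

def _fmt_p(p: float) -> str:
    """p-values to 3 decimals; below 0.0005 they print as 0.000."""
    return f"{p:.3f}"


def _fmt_or_ci(or_: float, lo: float, hi: float) -> str:
    return f"{or_:.2f} ({lo:.2f}–{hi:.2f})"


def results_frame(results: ResultsTable) -> pd.DataFrame:
    """Tidy per-cell frame: one row per stratum x genetic model."""
    recs = []
    for row in results.rows:
        for model in results.plan.models:
            pr = row.pooled[model]
            base = {
                "snp": results.snp,
                "factor": row.factor,
                "level": row.level,
                "k": row.k,
                "n_case": row.n_case,
                "n_control": row.n_control,
                "model": model.label,
            }
            if pr is not None:
                base.update(
                    effect_model=pr.effect_model.value,
                    or_=pr.or_,
                    ci_low=pr.ci_low,
                    ci_high=pr.ci_high,
                    p_h=pr.heterogeneity.p_value,
                    i2=pr.heterogeneity.i2,
                    tau2=pr.heterogeneity.tau2,
                    z=pr.z,
                    p=pr.p_value,
                )
            else:
                eff = row.single_effects.get(model)
                base.update(
                    effect_model="not_pooled",
                    or_=eff.or_ if eff else float("nan"),
                    ci_low=eff.ci_low if eff else float("nan"),
                    ci_high=eff.ci_high if eff else float("nan"),
                    p_h=float("nan"), i2=float("nan"), tau2=float("nan"),
                    z=float("nan"), p=float("nan"),
                )
            recs.append(base)
    return pd.DataFrame(recs)


def bias_frame(results: ResultsTable) -> pd.DataFrame:
    recs = []
    for model, b in results.bias.items():
        recs.append(
            {
                "snp": results.snp,
                "model": model.label,
                "k": b.k,
                "egger_intercept": b.egger_intercept,
                "egger_se": b.egger_se,
                "egger_t": b.egger_t,
                "egger_p": b.egger_p,
                "egger_ci_low": b.egger_ci_low,
                "egger_ci_high": b.egger_ci_high,
                "begg_s": b.begg_s,
                "begg_z": b.begg_z,
                "begg_p": b.begg_p,
            }
        )
    return pd.DataFrame(recs)


def sensitivity_frame(results: ResultsTable) -> pd.DataFrame:
    recs = []
    for model, loos in results.sensitivity.items():
        for loo in loos:
            recs.append(
                {
                    "snp": results.snp,
                    "model": model.label,
                    "omitted_study": loo.omitted_study,
                    "k": loo.pooled.k,
                    "effect_model": loo.pooled.effect_model.value,
                    "or_": loo.pooled.or_,
                    "ci_low": loo.pooled.ci_low,
                    "ci_high": loo.pooled.ci_high,
                    "p": loo.pooled.p_value,
                    "influential": loo.influential,
                }
            )
    return pd.DataFrame(recs)


def _json_payload(results: ResultsTable) -> dict:
    def cell(row: StratumResult, model: GeneticModel):
        pr = row.pooled[model]
        if pr is None:
            eff = row.single_effects.get(model)
            if eff is None:
                return None
            return {
                "effect_model": "not_pooled",
                "or": round(eff.or_, 2),
                "ci_low": round(eff.ci_low, 2),
                "ci_high": round(eff.ci_high, 2),
            }
        return {
            "effect_model": pr.effect_model.value,
            "or": round(pr.or_, 2),
            "ci_low": round(pr.ci_low, 2),
            "ci_high": round(pr.ci_high, 2),
            "p_h": round(pr.heterogeneity.p_value, 3),
            "p": round(pr.p_value, 3),
        }

    return {
        "snp": results.snp,
        "q_threshold": results.plan.q_threshold,
        "rows": [
            {
                "factor": r.factor,
                "level": r.level,
                "k": r.k,
                "n_case": r.n_case,
                "n_control": r.n_control,
                "cells": {m.label: cell(r, m) for m in results.plan.models},
            }
            for r in results.rows
        ],
        "bias": {
            m.label: {
                "egger_intercept": round(b.egger_intercept, 3),
                "egger_se": round(b.egger_se, 3),
                "egger_t": round(b.egger_t, 2),
                "egger_p": round(b.egger_p, 3),
                "begg_z": round(b.begg_z, 2),
                "begg_p": round(b.begg_p, 3),
            }
            for m, b in results.bias.items()
        },
        "sensitivity": {
            m.label: [
                {
                    "omitted_study": x.omitted_study,
                    "or": round(x.pooled.or_, 2),
                    "influential": x.influential,
                }
                for x in loos
            ]
            for m, loos in results.sensitivity.items()
        },
    }


def render_report(results: ResultsTable, format: str = "markdown") -> str:
    """Deterministic serialization of a ResultsTable.

    ``format`` is one of csv, json, markdown.  ORs and CI bounds print with
    2 decimals and p-values with 3 (sub-0.0005 p-values as "0.000").
    """
    if format == "csv":
        return results_frame(results).to_csv(index=False, float_format="%.6g")
    if format == "json":
        return json.dumps(_json_payload(results), indent=2)
    if format == "markdown":
        header = ["Variables", "N", "Case/Control"] + [
            f"{m.label} OR (95% CI) | P_h | P" for m in results.plan.models
        ]
        lines = ["| " + " | ".join(header) + " |",
                 "|" + "---|" * len(header)]
        for r in results.rows:
            cells = [f"{r.level}" if r.factor != "total" else "Total",
                     str(r.k), f"{r.n_case}/{r.n_control}"]
            for m in results.plan.models:
                pr = r.pooled[m]
                if pr is None:
                    eff = r.single_effects.get(m)
                    cells.append(
                        "—" if eff is None
                        else _fmt_or_ci(eff.or_, eff.ci_low, eff.ci_high) + " | — | —"
                    )
                else:
                    cells.append(
                        _fmt_or_ci(pr.or_, pr.ci_low, pr.ci_high)
                        + f" | {_fmt_p(pr.heterogeneity.p_value)} | {_fmt_p(pr.p_value)}"
                    )
            lines.append("| " + " | ".join(cells) + " |")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown report format {format!r}")


def reproduce_published() -> dict[str, ResultsTable]:
    """Run the embedded fixture tables through the published stratification.

    Returns three ResultsTables keyed by analysis set: the 12-study
    rs10033900 total-AMD pool (total, ethnicity, source-of-control, and
    genotyping strata), the 11 disease-subtype strata (neovascular and
    geographic-atrophy pools), and the 3-study rs2285714 pool (total only).
    """
    total = load_fixture("rs10033900_total")
    by_type = load_fixture("rs10033900_by_type")
    rs2 = load_fixture("rs2285714")

    plan_total = AnalysisPlan(
        snp="rs10033900",
        strata=(
            ("total", "all"),
            ("ethnicity", "Asian"),
            ("ethnicity", "Caucasian"),
            ("source_of_control", "HB"),
            ("source_of_control", "PB"),
            ("genotyping", "Sequencing"),
            ("genotyping", "TaqMan"),
            ("genotyping", "MALDI-TOF MS"),
            ("genotyping", "Mixed methods"),
        ),
    )
    plan_type = AnalysisPlan(
        snp="rs10033900",
        strata=(
            ("amd_type", "neovascular"),
            ("amd_type", "geographic_atrophy"),
        ),
    )
    plan_rs2 = AnalysisPlan(snp="rs2285714", strata=(("total", "all"),))
    return {
        "rs10033900_total": run_analysis(total, plan_total),
        "rs10033900_by_type": run_analysis(by_type, plan_type),
        "rs2285714": run_analysis(rs2, plan_rs2),
    }
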