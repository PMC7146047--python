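"""Synthetic case-control genotype-count study sets.

The generator mirrors the structure of the published study collection: a
set of k case-control studies at one biallelic SNP, each with genotype
counts in cases and controls.  Control genotypes are multinomial under
Hardy-Weinberg proportions at a specified mutant-allele frequency; each
study draws its own log odds ratio from Normal(log(true_or), tau2) and the
case allele frequency follows from the allelic odds (a multiplicative
allelic disease model, so the case group is also in HWE at its induced
allele frequency and every genotype-model OR is determined analytically).
An optional fraction of studies gets controls perturbed away from HWE by
mixing in homozygote excess (an inbreeding-style distortion), for testing
HWE screens.

Defaults emulate the published collection: 12 studies, control mutant-allele
frequency 0.45, allelic odds ratio 0.87, between-study variance 0.03, and
the fixture's range of sample sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .study_table import (
    AmdType,
    Ethnicity,
    GenotypeCounts,
    Genotyping,
    SourceOfControl,
    StudyRecord,
)

__all__ = ["SimulationConfig", "simulate_study", "simulate_meta"]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic study set.

    k               number of studies
    maf             control mutant-allele frequency, in (0, 1)
    true_or         allelic odds ratio (case vs control odds of the mutant allele)
    tau2            variance of per-study log odds ratios about log(true_or)
    n_case_range,
    n_control_range inclusive bounds for per-study group sizes, drawn uniformly
    hwe_violation_rate  fraction of studies whose controls are perturbed off HWE
    seed            integer seed for the single random generator
    """

    k: int = 12
    maf: float = 0.45
    true_or: float = 0.87
    tau2: float = 0.03
    n_case_range: tuple[int, int] = (100, 1100)
    n_control_range: tuple[int, int] = (55, 1260)
    hwe_violation_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be at least 1")
        if not 0.0 < self.maf < 1.0:
            raise ValueError("maf must lie strictly in (0, 1)")
        if self.true_or <= 0.0:
            raise ValueError("true_or must be positive")
        if self.tau2 < 0.0:
            raise ValueError("tau2 must be non-negative")
        for rng_ in (self.n_case_range, self.n_control_range):
            if rng_[0] < 1 or rng_[1] < rng_[0]:
                raise ValueError(f"invalid size range {rng_}")
        if not 0.0 <= self.hwe_violation_rate <= 1.0:
            raise ValueError("hwe_violation_rate must lie in [0, 1]")


def _hwe_probs(p: float) -> np.ndarray:
    """Genotype probabilities (CC, CT, TT) under HWE at mutant frequency p."""
    q = 1.0 - p
    return np.array([p * p, 2 * p * q, q * q])


def case_allele_frequency(maf: float, or_: float) -> float:
    """Case mutant-allele frequency implied by control frequency and allelic OR."""
    odds = maf / (1.0 - maf) * or_
    return odds / (1.0 + odds)


def _draw_counts(rng: np.random.Generator, n: int, probs: np.ndarray) -> GenotypeCounts:
    cc, ct, tt = rng.multinomial(n, probs)
    return GenotypeCounts(int(cc), int(ct), int(tt))


def simulate_study(
    config: SimulationConfig,
    rng: np.random.Generator,
    log_or: float,
    study_id: str = "sim 1",
    violate_hwe: bool = False,
) -> StudyRecord:
    """Draw one synthetic study with the given per-study log odds ratio.

    Controls are multinomial under HWE at ``config.maf``; the case allele
    frequency is the control allele odds times exp(log_or), and case
    genotypes are multinomial under HWE at that frequency.  With
    ``violate_hwe`` the control genotype probabilities get an inbreeding
    distortion (F = 0.3) that inflates both homozygote classes.
    """
    n_case = int(rng.integers(config.n_case_range[0], config.n_case_range[1] + 1))
    n_control = int(rng.integers(config.n_control_range[0], config.n_control_range[1] + 1))
    p_ctrl = config.maf
    p_case = case_allele_frequency(p_ctrl, math.exp(log_or))
    ctrl_probs = _hwe_probs(p_ctrl)
    if violate_hwe:
        f = 0.3  # inbreeding coefficient of the distortion
        q = 1.0 - p_ctrl
        ctrl_probs = np.array(
            [p_ctrl**2 + f * p_ctrl * q, 2 * p_ctrl * q * (1 - f), q**2 + f * p_ctrl * q]
        )
    if not np.all(ctrl_probs >= 0) or abs(ctrl_probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"invalid control genotype probabilities {ctrl_probs}")
    return StudyRecord(
        study_id=study_id,
        snp="sim",
        year=2020,
        country="simulated",
        ethnicity=Ethnicity.CAUCASIAN,
        amd_type=AmdType.AMD,
        source_of_control=SourceOfControl.POPULATION_BASED,
        genotyping=Genotyping.TAQMAN,
        case_counts=_draw_counts(rng, n_case, _hwe_probs(p_case)),
        control_counts=_draw_counts(rng, n_control, ctrl_probs),
    )


def simulate_meta(config: SimulationConfig) -> list[StudyRecord]:
    """Draw a full study set: k studies with heterogeneous true effects.

    Per-study log odds ratios are Normal(log(true_or), tau2); a
    ``hwe_violation_rate`` fraction of studies (rounded down, chosen at
    random) gets HWE-violating controls.  All randomness flows from
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    log_ors = rng.normal(math.log(config.true_or), math.sqrt(config.tau2), size=config.k)
    n_violate = int(config.hwe_violation_rate * config.k)
    violators = set(rng.choice(config.k, size=n_violate, replace=False)) if n_violate else set()
    return [
        simulate_study(
            config,
            rng,
            float(log_ors[i]),
            study_id=f"sim {i + 1}",
            violate_hwe=i in violators,
        )
        for i in range(config.k)
    ]
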