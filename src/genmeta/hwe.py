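"""Pearson chi-square test of Hardy-Weinberg equilibrium.

Applied to control-group genotype counts as an inclusion screen: under HWE
the genotype proportions are p^2, 2pq, q^2 at the observed allele
frequencies, and the goodness-of-fit statistic has one degree of freedom
(three genotype classes, one estimated allele frequency).  No continuity
correction and no exact test — the plain Pearson statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .study_table import GenotypeCounts, allele_frequency

__all__ = ["HweResult", "hwe_test"]


@dataclass(frozen=True)
class HweResult:
    """Chi-square statistic, its df=1 p-value, and the mutant allele frequency."""

    chi2: float
    p_value: float
    maf: float


def hwe_test(counts: GenotypeCounts) -> HweResult:
    """Test genotype counts for departure from Hardy-Weinberg proportions.

    Raises ``ValueError`` for monomorphic counts (one allele absent), where
    the test is undefined.
    """
    n = counts.total
    p = allele_frequency(counts)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        raise ValueError("HWE undefined for monomorphic genotype counts")
    expected = (n * p * p, 2 * n * p * q, n * q * q)
    observed = counts.as_tuple()
    chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    return HweResult(chi2=chi2, p_value=float(stats.chi2.sf(chi2, df=1)), maf=p)
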