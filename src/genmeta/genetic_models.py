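"""The five genetic-model contrasts of a biallelic case-control study.

Each model reduces genotype counts (CC/CT/TT with C the mutant allele) to a
2x2 exposure-by-status table:

=============  ======================  =========================
model          exposed                 unexposed
=============  ======================  =========================
allele         C alleles (2*CC + CT)   T alleles (2*TT + CT)
heterozygote   CT                      TT        (CC excluded)
dominant       CC + CT                 TT
homozygote     CC                      TT        (CT excluded)
recessive      CC                      CT + TT
=============  ======================  =========================

The heterozygote and homozygote contrasts are conditional 2x2 tables: the
excluded genotype is dropped entirely, so their margins are smaller than the
study.  Exposure is always the mutant-bearing category, so OR < 1 reads as a
protective mutant allele/genotype throughout.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .study_table import StudyRecord

__all__ = ["GeneticModel", "ContrastTable", "build_contrast"]


class GeneticModel(enum.Enum):
    """The five standard contrasts, with their conventional display labels."""

    ALLELE = "C-allele vs. T-allele"
    HETEROZYGOTE = "CT vs. TT"
    DOMINANT = "CC+CT vs. TT"
    HOMOZYGOTE = "CC vs. TT"
    RECESSIVE = "CC vs. CT+TT"

    @property
    def label(self) -> str:
        return self.value


@dataclass(frozen=True)
class ContrastTable:
    """2x2 count table: a/b exposed/unexposed cases, c/d likewise controls."""

    a: int
    b: int
    c: int
    d: int
    study_id: str
    model: GeneticModel

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contrast table cells must be non-negative")
        if self.n < 1:
            raise ValueError("contrast table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


def build_contrast(study: StudyRecord, model: GeneticModel) -> ContrastTable:
    """Build the 2x2 table for one study under one genetic model.

    Zero cells are permitted here; continuity handling is the effect
    estimator's concern.
    """
    cc, ct, tt = study.case_counts.as_tuple()
    CC, CT, TT = study.control_counts.as_tuple()
    if model is GeneticModel.ALLELE:
        a, b, c, d = 2 * cc + ct, 2 * tt + ct, 2 * CC + CT, 2 * TT + CT
    elif model is GeneticModel.HETEROZYGOTE:
        a, b, c, d = ct, tt, CT, TT
    elif model is GeneticModel.DOMINANT:
        a, b, c, d = cc + ct, tt, CC + CT, TT
    elif model is GeneticModel.HOMOZYGOTE:
        a, b, c, d = cc, tt, CC, TT
    elif model is GeneticModel.RECESSIVE:
        a, b, c, d = cc, ct + tt, CC, CT + TT
    else:  # pragma: no cover - enum is closed
        raise ValueError(f"unknown genetic model {model!r}")
    return ContrastTable(a=a, b=b, c=c, d=d, study_id=study.study_id, model=model)
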