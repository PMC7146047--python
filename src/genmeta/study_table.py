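"""Study-level genotype-count tables for case-control association meta-analysis.

The unit of analysis is one case-control study genotyped at a biallelic SNP,
recorded as genotype counts (mutant homozygote, heterozygote, wild-type
homozygote) in cases and controls plus design metadata used for subgroup
stratification.  Three embedded fixture tables carry the published
CFI/age-related-macular-degeneration study collection: 12 rs10033900 studies
of total AMD, 11 disease-subtype strata of the same studies, and 3 rs2285714
studies.  For both SNPs the wild-type allele is T and the mutant allele is C;
genotype columns are ordered CC, CT, TT (mutant homozygote first), which
fixes the orientation of every downstream odds ratio: OR < 1 means the C
allele (or C-bearing genotype) is protective.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

__all__ = [
    "GenotypeCounts",
    "StudyRecord",
    "Ethnicity",
    "AmdType",
    "SourceOfControl",
    "Genotyping",
    "ParseError",
    "parse_studies",
    "write_studies",
    "total_sample_sizes",
    "allele_frequency",
    "load_fixture",
    "FIXTURES",
]

CSV_COLUMNS = [
    "study_id", "snp", "year", "country", "ethnicity", "amd_type",
    "source_of_control", "genotyping",
    "case_cc", "case_ct", "case_tt", "ctrl_cc", "ctrl_ct", "ctrl_tt",
]

#: Embedded study tables (name -> packaged CSV).
FIXTURES = {
    "rs10033900_total": "rs10033900_total.csv",
    "rs10033900_by_type": "rs10033900_by_type.csv",
    "rs2285714": "rs2285714.csv",
}


class ParseError(ValueError):
    """Raised when a study CSV row cannot be parsed or validated."""


class Ethnicity(str, enum.Enum):
    ASIAN = "Asian"
    CAUCASIAN = "Caucasian"


class AmdType(str, enum.Enum):
    AMD = "AMD"
    ADVANCED_AMD = "advanced_AMD"
    NEOVASCULAR = "neovascular"
    GEOGRAPHIC_ATROPHY = "geographic_atrophy"


class SourceOfControl(str, enum.Enum):
    POPULATION_BASED = "PB"
    HOSPITAL_BASED = "HB"


class Genotyping(str, enum.Enum):
    MALDI_TOF_MS = "MALDI-TOF MS"
    MIXED_METHODS = "Mixed methods"
    PCR_RFLP = "PCR-RFLP"
    SEQUENCING = "Sequencing"
    TAQMAN = "TaqMan"


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts for one group, mutant-homozygote first.

    ``hom_mut`` counts CC, ``het`` CT, ``hom_wt`` TT individuals.
    """

    hom_mut: int
    het: int
    hom_wt: int

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, int) or isinstance(v, bool):
                raise ParseError(f"genotype count {f.name} must be an integer, got {v!r}")
            if v < 0:
                raise ParseError(f"genotype count {f.name} must be non-negative, got {v}")
        if self.total < 1:
            raise ParseError("genotype counts must total at least 1")

    @property
    def total(self) -> int:
        return self.hom_mut + self.het + self.hom_wt

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.hom_mut, self.het, self.hom_wt)


@dataclass(frozen=True)
class StudyRecord:
    """One case-control study at one SNP, possibly a disease-subtype stratum.

    ``study_id`` must be unique within an analysis set; where a study
    contributes several strata (e.g. neovascular and geographic-atrophy case
    subsets against a shared control group) the id carries the stratum.
    """

    study_id: str
    snp: str
    year: int
    country: str
    ethnicity: Ethnicity
    amd_type: AmdType
    source_of_control: SourceOfControl
    genotyping: Genotyping
    case_counts: GenotypeCounts
    control_counts: GenotypeCounts

    @property
    def n_case(self) -> int:
        return self.case_counts.total

    @property
    def n_control(self) -> int:
        return self.control_counts.total


def _coerce_enum(cls, value, row: int, col: str):
    try:
        return cls(value)
    except ValueError:
        allowed = ", ".join(m.value for m in cls)
        raise ParseError(
            f"row {row}: field {col!r} has invalid value {value!r} (allowed: {allowed})"
        ) from None


def _coerce_int(value, row: int, col: str, nonneg: bool = False) -> int:
    try:
        iv = int(value)
    except (TypeError, ValueError):
        raise ParseError(f"row {row}: field {col!r} is not an integer: {value!r}") from None
    if float(value) != iv:
        raise ParseError(f"row {row}: field {col!r} is not an integer: {value!r}")
    if nonneg and iv < 0:
        raise ParseError(f"row {row}: field {col!r} must be non-negative, got {iv}")
    return iv


def parse_studies(
    path: Union[str, Path], snp_filter: Optional[str] = None
) -> list[StudyRecord]:
    """Read and validate a study table CSV.

    Parameters
    ----------
    path
        CSV with the columns in :data:`CSV_COLUMNS`.
    snp_filter
        If given, keep only records for this SNP id.

    Returns
    -------
    list of StudyRecord in file order.

    Raises
    ------
    ParseError
        On a missing column, malformed cell, or negative count; the message
        names the offending row and field.
    """
    try:
        df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise ParseError(f"cannot read study table {path}: {exc}") from exc
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"study table {path} is missing columns: {missing}")

    records: list[StudyRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rec = StudyRecord(
            study_id=str(row.study_id),
            snp=str(row.snp),
            year=_coerce_int(row.year, i, "year"),
            country=str(row.country),
            ethnicity=_coerce_enum(Ethnicity, row.ethnicity, i, "ethnicity"),
            amd_type=_coerce_enum(AmdType, row.amd_type, i, "amd_type"),
            source_of_control=_coerce_enum(
                SourceOfControl, row.source_of_control, i, "source_of_control"
            ),
            genotyping=_coerce_enum(Genotyping, row.genotyping, i, "genotyping"),
            case_counts=GenotypeCounts(
                _coerce_int(row.case_cc, i, "case_cc", nonneg=True),
                _coerce_int(row.case_ct, i, "case_ct", nonneg=True),
                _coerce_int(row.case_tt, i, "case_tt", nonneg=True),
            ),
            control_counts=GenotypeCounts(
                _coerce_int(row.ctrl_cc, i, "ctrl_cc", nonneg=True),
                _coerce_int(row.ctrl_ct, i, "ctrl_ct", nonneg=True),
                _coerce_int(row.ctrl_tt, i, "ctrl_tt", nonneg=True),
            ),
        )
        key = (rec.study_id, rec.snp)
        if key in seen:
            raise ParseError(f"row {i}: duplicate study_id {rec.study_id!r} for {rec.snp}")
        seen.add(key)
        records.append(rec)
    if snp_filter is not None:
        records = [r for r in records if r.snp == snp_filter]
    return records


def write_studies(records: Iterable[StudyRecord], path: Union[str, Path]) -> None:
    """Serialize records to the same CSV dialect :func:`parse_studies` reads."""
    rows = []
    for r in records:
        rows.append(
            {
                "study_id": r.study_id,
                "snp": r.snp,
                "year": r.year,
                "country": r.country,
                "ethnicity": r.ethnicity.value,
                "amd_type": r.amd_type.value,
                "source_of_control": r.source_of_control.value,
                "genotyping": r.genotyping.value,
                "case_cc": r.case_counts.hom_mut,
                "case_ct": r.case_counts.het,
                "case_tt": r.case_counts.hom_wt,
                "ctrl_cc": r.control_counts.hom_mut,
                "ctrl_ct": r.control_counts.het,
                "ctrl_tt": r.control_counts.hom_wt,
            }
        )
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


def total_sample_sizes(studies: Sequence[StudyRecord]) -> tuple[int, int]:
    """Total cases and controls over an analysis set.

    Returns ``(n_cases, n_controls)``; raises ``ValueError`` on an empty list.
    """
    if not studies:
        raise ValueError("cannot total sample sizes of an empty study list")
    return (sum(s.n_case for s in studies), sum(s.n_control for s in studies))


def allele_frequency(counts: GenotypeCounts) -> float:
    """Frequency of the mutant (C) allele: (2*CC + CT) / (2*N)."""
    n = counts.total
    if n < 1:
        raise ValueError("allele frequency undefined for empty genotype counts")
    return (2 * counts.hom_mut + counts.het) / (2 * n)


def load_fixture(name: str) -> list[StudyRecord]:
    """Load one of the embedded published study tables.

    ``name`` is a key of :data:`FIXTURES`: ``rs10033900_total`` (12 total-AMD
    studies), ``rs10033900_by_type`` (11 neovascular / geographic-atrophy
    strata), or ``rs2285714`` (3 studies).
    """
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(FIXTURES)}")
    ref = resources.files("genmeta.data") / FIXTURES[name]
    with resources.as_file(ref) as p:
        return parse_studies(p)
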