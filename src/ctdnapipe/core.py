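"""Shared data model for the ctDNA analysis pipeline.

Variant identity throughout the package is the left-normalized tuple
(chrom, pos, ref, alt), 1-based VCF-style coordinates with indels anchored on
a preceding base.  VAFs are stored as fractions in [0, 1]; every percentage
threshold quoted in configuration is converted once at the config boundary.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import pandas as pd

_BASES = frozenset("ACGT")


class ValidationError(ValueError):
    """Raised when an input object violates a model invariant."""


class ClinvarClass(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    BENIGN = "benign"
    LIKELY_BENIGN = "likely_benign"
    VUS = "vus"
    CONFLICTING = "conflicting"
    UNREPORTED = "unreported"


#: ClinVar classes counted as pathogenic/likely pathogenic for driver calls.
PLP = frozenset({ClinvarClass.PATHOGENIC, ClinvarClass.LIKELY_PATHOGENIC})
#: ClinVar classes counted as benign/likely benign in the tumour-agnostic cascade.
BLB = frozenset({ClinvarClass.BENIGN, ClinvarClass.LIKELY_BENIGN})


class Material(str, enum.Enum):
    TISSUE = "tissue"
    PLASMA = "plasma"
    WBC = "wbc"


class Timepoint(str, enum.Enum):
    """Sampling timepoint; follow-up samples carry an ordinal suffix."""

    DIAGNOSTIC = "diagnostic"
    POST_SURGERY = "post_surgery"
    FOLLOW_UP = "follow_up"


@dataclass(frozen=True, order=True)
class GenomicLocus:
    """One variant site: chromosome, 1-based position, ref and alt alleles."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or not set(allele) <= _BASES:
                raise ValidationError(
                    f"{name} allele must be a non-empty string over ACGT, got {allele!r}"
                )


def normalize_variant(locus: GenomicLocus) -> GenomicLocus:
    """Reduce a variant to its minimal left-aligned representation.

    Shared trailing bases are trimmed first, then shared leading bases
    (advancing the position), always leaving at least one base per allele.
    Idempotent; an SNV is always already minimal.
    """
    ref, alt, pos = locus.ref, locus.alt, locus.pos
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if (ref, alt, pos) == (locus.ref, locus.alt, locus.pos):
        return locus
    return GenomicLocus(locus.chrom, pos, ref, alt)


@dataclass(frozen=True)
class AnnotationBundle:
    """Externally computed annotations consumed (never produced) by the filters.

    clinvar_source_counts carries the number of submitting sources per ClinVar
    class, which the tumour-agnostic cascade uses to distinguish "benign by one
    source" from "benign by multiple sources".
    """

    clinvar_class: ClinvarClass = ClinvarClass.UNREPORTED
    clinvar_source_counts: Mapping[ClinvarClass, int] = field(default_factory=dict)
    is_synonymous: bool = False
    gnomad_max_pop_af: float = 0.0
    gnomad_overall_af: float = 0.0
    cosmic_same_position_count: int = 0
    local_cohort_germline_count: int = 0
    exon_distance: int = 0

    def __post_init__(self) -> None:
        for name in ("gnomad_max_pop_af", "gnomad_overall_af"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0,1], got {v}")
        for name in ("cosmic_same_position_count", "local_cohort_germline_count"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    def benign_source_count(self) -> int:
        counts = dict(self.clinvar_source_counts)
        if not counts and self.clinvar_class in BLB:
            counts = {self.clinvar_class: 1}
        return sum(n for cls, n in counts.items() if ClinvarClass(cls) in BLB)


@dataclass(frozen=True)
class UmiSupport:
    """Consensus UMI families supporting the alt allele, per strand orientation."""

    families_top_strand: int
    families_bottom_strand: int

    def __post_init__(self) -> None:
        if self.families_top_strand < 0 or self.families_bottom_strand < 0:
            raise ValidationError("UMI family counts must be >= 0")

    @property
    def total(self) -> int:
        return self.families_top_strand + self.families_bottom_strand


class Caller(str, enum.Enum):
    UMI_CONSENSUS = "umi_consensus"
    NON_UMI = "non_umi"


@dataclass(frozen=True)
class VariantCall:
    """One observed variant in one sample."""

    locus: GenomicLocus
    gene: str
    vaf: float
    alt_reads: int
    total_reads: int
    quality_lod: float
    caller: Caller = Caller.UMI_CONSENSUS
    umi_support: Optional[UmiSupport] = None
    annotations: AnnotationBundle = field(default_factory=AnnotationBundle)

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ValidationError(f"vaf must be in [0,1], got {self.vaf}")
        if self.alt_reads > self.total_reads:
            raise ValidationError("alt_reads must not exceed total_reads")
        if self.total_reads > 0:
            if abs(self.vaf - self.alt_reads / self.total_reads) > 1.0 / self.total_reads:
                raise ValidationError(
                    "vaf inconsistent with alt_reads/total_reads beyond 1/total_reads"
                )

    def normalized(self) -> "VariantCall":
        norm = normalize_variant(self.locus)
        return self if norm is self.locus else replace(self, locus=norm)


def match_variants(
    query: Sequence[VariantCall], reference: Sequence[GenomicLocus]
) -> list[VariantCall]:
    """Subset of ``query`` whose normalized locus occurs in ``reference``.

    Order of ``query`` is preserved; this is how tissue driver variants are
    sought in the plasma panel call set.
    """
    ref_set = {normalize_variant(loc) for loc in reference}
    return [call for call in query if normalize_variant(call.locus) in ref_set]


@dataclass
class SampleRecord:
    """A sequenced specimen and its variant calls."""

    participant_id: str
    material: Material
    timepoint: Optional[Timepoint] = None
    timepoint_index: int = 0
    plasma_volume_ml: Optional[float] = None
    cfdna_mass_ng: Optional[float] = None
    calls: list[VariantCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        is_plasma = self.material == Material.PLASMA
        for name in ("plasma_volume_ml", "cfdna_mass_ng"):
            v = getattr(self, name)
            if v is not None:
                if not is_plasma:
                    raise ValidationError(f"{name} only valid for plasma samples")
                if v <= 0:
                    raise ValidationError(f"{name} must be > 0, got {v}")


@dataclass
class Participant:
    """Clinical unit: staging, samples, survival outcomes, optional truth labels."""

    id: str
    stage: str
    samples: list[SampleRecord] = field(default_factory=list)
    os_years: float = 0.0
    os_event: bool = False
    pfs_years: Optional[float] = None
    pfs_event: Optional[bool] = None
    #: synthetic cohorts only: planted label per locus,
    #: one of {"tumour", "ch", "germline", "artefact"}
    truth: Optional[dict[GenomicLocus, str]] = None

    def sample(
        self, material: Material, timepoint: Optional[Timepoint] = None
    ) -> Optional[SampleRecord]:
        for s in self.samples:
            if s.material == material and (timepoint is None or s.timepoint == timepoint):
                return s
        return None


APPROACHES = ("A", "B", "C", "D")
TIMEPOINT_COLS = ("diagnostic", "post")

DETECTION_COLUMNS = [
    "participant_id",
    "expected_variants",
    "a_diagnostic",
    "b_diagnostic",
    "c_diagnostic",
    "d_diagnostic",
    "a_post",
    "b_post",
    "c_post",
    "d_post",
    "plasma_diagnostic_ng",
    "plasma_diagnostic_ml",
    "plasma_post_ng",
    "plasma_post_ml",
]


class DetectionTable:
    """Per-participant, per-approach retained-variant counts (the Table 2 shape).

    Count columns are pandas nullable integers; NA means the prerequisite
    input (tissue drivers, a sequenced sample, CH-filterable data) is missing,
    never "zero variants".
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in DETECTION_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"DetectionTable missing columns: {missing}")
        df = df.copy()
        for col in DETECTION_COLUMNS[2:10]:
            df[col] = df[col].astype("Int64")
        self.df = df.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.df
        if df["participant_id"].duplicated().any():
            raise ValidationError("duplicate participant ids")
        bad = df["expected_variants"].dropna().isin(["Y", "N"])
        if not bad.all():
            raise ValidationError("expected_variants must be Y/N/NA")
        for tp in TIMEPOINT_COLS:
            c, d = df[f"c_{tp}"], df[f"d_{tp}"]
            both = c.notna() & d.notna()
            if (d[both] > c[both]).any():
                raise ValidationError(f"approach D count exceeds C count at {tp}")

    def __len__(self) -> int:
        return len(self.df)

    def row(self, participant_id: str) -> pd.Series:
        hit = self.df[self.df["participant_id"] == participant_id]
        if hit.empty:
            raise KeyError(participant_id)
        return hit.iloc[0]
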