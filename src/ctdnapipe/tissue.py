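"""Tissue variant filtering: the tumour-informed reference set.

Filters tissue calls to the potentially cancer-associated set, classifies
somatic vs germline origin, and designates driver variants.  Participants
with at least one driver variant form the tumour-informed cohort.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .config import DEFAULT_CONFIG, RunConfig
from .core import (
    PLP,
    GenomicLocus,
    ValidationError,
    VariantCall,
    normalize_variant,
)


class Origin(str, enum.Enum):
    SOMATIC = "somatic"
    GERMLINE = "germline"
    UNDETERMINED = "undetermined"


class ExclusionReason(str, enum.Enum):
    """First failing rule, in cascade order."""

    EXON_DISTANCE = "exon_distance"
    VAF_FLOOR = "vaf_floor"
    CLINVAR_GNOMAD = "clinvar_gnomad"
    LOCAL_COHORT = "local_cohort"
    COHORT_RECURRENT = "cohort_recurrent"


@dataclass
class TissueVerdict:
    variant: VariantCall
    retained: bool
    origin: Origin = Origin.SOMATIC
    driver: bool = False
    exclusion_reason: Optional[ExclusionReason] = None

    def __post_init__(self) -> None:
        if self.driver and not self.retained:
            raise ValidationError("driver implies retained")
        if self.origin == Origin.GERMLINE and self.driver:
            raise ValidationError("germline variants cannot be drivers")


def _first_failure(
    call: VariantCall,
    cohort_sample_count: int,
    occurrence: int,
    cfg: RunConfig,
) -> Optional[ExclusionReason]:
    ann = call.annotations
    if ann.exon_distance > cfg.exon_distance_max:
        return ExclusionReason.EXON_DISTANCE
    if not call.vaf > cfg.tissue_vaf_floor:
        return ExclusionReason.VAF_FLOOR
    plp = ann.clinvar_class in PLP
    gnomad_branch = (
        cfg.tissue_vaf_floor < call.vaf <= cfg.tissue_vaf_ceiling
        and ann.gnomad_max_pop_af < cfg.gnomad_tissue_max
    )
    if not (plp or gnomad_branch):
        return ExclusionReason.CLINVAR_GNOMAD
    if ann.local_cohort_germline_count > cfg.local_cohort_max:
        return ExclusionReason.LOCAL_COHORT
    if (
        occurrence > cohort_sample_count / 2
        and ann.cosmic_same_position_count < cfg.cosmic_hotspot_min
    ):
        return ExclusionReason.COHORT_RECURRENT
    return None


def filter_tissue_variants(
    calls: Sequence[VariantCall],
    cohort_sample_count: int,
    cohort_occurrence: Mapping[GenomicLocus, int],
    cfg: RunConfig = DEFAULT_CONFIG,
) -> list[TissueVerdict]:
    """Apply the tissue retention rules; each exclusion records its first
    failing rule.

    Retained requires, in order: within the exon/splice window; VAF strictly
    above the floor; ClinVar P/LP or (VAF within (floor, ceiling] and gnomAD
    max population frequency below the germline cutoff); not a recurrent
    local-cohort germline call; not cohort-recurrent without COSMIC support.
    """
    verdicts = []
    for call in calls:
        locus = normalize_variant(call.locus)
        occurrence = cohort_occurrence.get(locus, 0)
        reason = _first_failure(call, cohort_sample_count, occurrence, cfg)
        verdicts.append(
            TissueVerdict(call, retained=reason is None, exclusion_reason=reason)
        )
    return verdicts


def classify_origin(
    verdicts: Sequence[TissueVerdict],
    cfg: RunConfig = DEFAULT_CONFIG,
    somatic_overrides: Optional[set[GenomicLocus]] = None,
) -> list[TissueVerdict]:
    """Label somatic vs germline-candidate origin within one tissue sample.

    A retained P/LP variant in the heterozygous VAF window is somatic when
    another retained variant in the sample sits within the similarity window
    (co-occurring clonal variants); otherwise it is a germline candidate
    (undetermined) pending WBC confirmation.  Variants outside the window are
    somatic by default.  ``somatic_overrides`` is the manual
    phenotype-consistency escape hatch: listed loci are forced somatic.
    """
    lo, hi = cfg.origin_vaf_window
    overrides = somatic_overrides or set()
    retained_vafs = [v.variant.vaf for v in verdicts if v.retained]
    out = []
    for v in verdicts:
        if not v.retained:
            out.append(v)
            continue
        origin = Origin.SOMATIC
        plp = v.variant.annotations.clinvar_class in PLP
        if plp and lo <= v.variant.vaf <= hi:
            if normalize_variant(v.variant.locus) in overrides:
                origin = Origin.SOMATIC
            else:
                companions = [
                    w
                    for w in retained_vafs
                    if abs(w - v.variant.vaf) <= cfg.origin_similarity_window
                ]
                # the variant's own VAF is always a companion of itself
                origin = Origin.SOMATIC if len(companions) > 1 else Origin.UNDETERMINED
        out.append(replace_origin(v, origin))
    return out


def replace_origin(verdict: TissueVerdict, origin: Origin) -> TissueVerdict:
    return TissueVerdict(
        verdict.variant,
        retained=verdict.retained,
        origin=origin,
        driver=verdict.driver and origin != Origin.GERMLINE,
        exclusion_reason=verdict.exclusion_reason,
    )


def resolve_origin_with_wbc(
    verdicts: Sequence[TissueVerdict],
    wbc_calls: Sequence[VariantCall],
    cfg: RunConfig = DEFAULT_CONFIG,
) -> list[TissueVerdict]:
    """Resolve origins using a matched WBC sample.

    A WBC VAF near 50% confirms germline; an undetermined candidate absent
    from WBC (or outside the band) resolves to somatic.  WBC evidence also
    overrides the companion-VAF heuristic: a P/LP variant in the heterozygous
    window that the heuristic called somatic is reclassified germline when its
    WBC VAF sits in the band, since direct germline DNA evidence trumps
    co-occurrence circumstantials.
    """
    lo, hi = cfg.wbc_germline_band
    wlo, whi = cfg.origin_vaf_window
    wbc_vaf = {normalize_variant(c.locus): c.vaf for c in wbc_calls}
    out = []
    for v in verdicts:
        in_window = (
            v.retained
            and v.variant.annotations.clinvar_class in PLP
            and wlo <= v.variant.vaf <= whi
        )
        if v.retained and (v.origin == Origin.UNDETERMINED or in_window):
            vaf = wbc_vaf.get(normalize_variant(v.variant.locus))
            if vaf is not None and lo <= vaf <= hi:
                v = replace_origin(v, Origin.GERMLINE)
            elif v.origin == Origin.UNDETERMINED:
                v = replace_origin(v, Origin.SOMATIC)
        out.append(v)
    return out


def classify_driver(
    verdict: TissueVerdict, cfg: RunConfig = DEFAULT_CONFIG
) -> TissueVerdict:
    """Driver = retained, non-germline, and ClinVar P/LP or COSMIC
    same-position recurrence at or above the hotspot count."""
    ann = verdict.variant.annotations
    driver = (
        verdict.retained
        and verdict.origin != Origin.GERMLINE
        and (
            ann.clinvar_class in PLP
            or ann.cosmic_same_position_count >= cfg.cosmic_hotspot_min
        )
    )
    return TissueVerdict(
        verdict.variant,
        retained=verdict.retained,
        origin=verdict.origin,
        driver=driver,
        exclusion_reason=verdict.exclusion_reason,
    )


def run_tissue_pipeline(
    calls: Sequence[VariantCall],
    cohort_sample_count: int,
    cohort_occurrence: Mapping[GenomicLocus, int],
    wbc_calls: Optional[Sequence[VariantCall]] = None,
    cfg: RunConfig = DEFAULT_CONFIG,
    somatic_overrides: Optional[set[GenomicLocus]] = None,
) -> list[TissueVerdict]:
    """Filter, classify origin (using WBC when provided) and designate drivers."""
    verdicts = filter_tissue_variants(calls, cohort_sample_count, cohort_occurrence, cfg)
    verdicts = classify_origin(verdicts, cfg, somatic_overrides)
    if wbc_calls is not None:
        verdicts = resolve_origin_with_wbc(verdicts, wbc_calls, cfg)
    return [classify_driver(v, cfg) for v in verdicts]


def driver_loci(verdicts: Iterable[TissueVerdict]) -> list[GenomicLocus]:
    return [normalize_variant(v.variant.locus) for v in verdicts if v.driver]
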