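"""Plasma variant filtering: caller pass thresholds, blacklist construction,
tumour-informed approaches A/B and the tumour-agnostic cascade (approach C).

Approach A restricts UMI-consensus plasma calls to the participant's tissue
driver loci; approach B does the same on non-UMI calls; approach C keeps all
plasma calls surviving a fixed cascade of artefact, region, depth, ClinVar,
local-cohort and germline filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .config import DEFAULT_CONFIG, RunConfig
from .core import (
    Caller,
    GenomicLocus,
    VariantCall,
    match_variants,
    normalize_variant,
)
from .umi import passes_umi_support


@dataclass
class Blacklist:
    """Loci recurring across more samples than the recurrence threshold and
    lacking COSMIC hotspot support; treated as technical artefacts."""

    loci: set[GenomicLocus]
    provenance: dict[GenomicLocus, int] = field(default_factory=dict)

    def __contains__(self, locus: GenomicLocus) -> bool:
        return normalize_variant(locus) in self.loci


@dataclass
class PlasmaCallSet:
    participant_id: str
    timepoint: str
    approach: str
    retained: list[VariantCall] = field(default_factory=list)
    #: (normalized locus, filter step that removed it); retained calls absent
    audit: list[tuple[GenomicLocus, str]] = field(default_factory=list)
    na: bool = False
    na_reason: Optional[str] = None

    @property
    def count(self) -> Optional[int]:
        return None if self.na else len(self.retained)

    @property
    def detected(self) -> Optional[bool]:
        return None if self.na else len(self.retained) >= 1


def apply_caller_pass_filters(
    calls: Sequence[VariantCall], cfg: RunConfig = DEFAULT_CONFIG
) -> list[VariantCall]:
    """Post-hoc caller pass thresholds: allele-fraction floor, log-odds floor,
    population-frequency ceiling; UMI-consensus calls additionally need duplex
    family support."""
    kept = []
    for c in calls:
        if c.vaf < cfg.caller_vaf_floor:
            continue
        if c.quality_lod < cfg.caller_lod_floor:
            continue
        if c.annotations.gnomad_max_pop_af > cfg.gnomad_plasma_max:
            continue
        if c.caller == Caller.UMI_CONSENSUS:
            if c.umi_support is None or not passes_umi_support(
                c.umi_support, cfg.umi_min_total, cfg.umi_min_per_strand
            ):
                continue
        kept.append(c)
    return kept


def _tumour_informed(
    approach: str,
    tissue_drivers: Optional[Sequence[GenomicLocus]],
    plasma_calls: Sequence[VariantCall],
    participant_id: str,
    timepoint: str,
) -> PlasmaCallSet:
    if not tissue_drivers:
        return PlasmaCallSet(
            participant_id, timepoint, approach, na=True, na_reason="no_tissue_drivers"
        )
    retained = match_variants(plasma_calls, tissue_drivers)
    return PlasmaCallSet(participant_id, timepoint, approach, retained=retained)


def approach_A(
    tissue_drivers: Optional[Sequence[GenomicLocus]],
    plasma_calls_umi: Sequence[VariantCall],
    participant_id: str = "",
    timepoint: str = "diagnostic",
) -> PlasmaCallSet:
    """Tumour-informed, UMI-consensus calls restricted to tissue driver loci.
    NA (never zero) for participants without tissue drivers."""
    return _tumour_informed("A", tissue_drivers, plasma_calls_umi, participant_id, timepoint)


def approach_B(
    tissue_drivers: Optional[Sequence[GenomicLocus]],
    plasma_calls_non_umi: Sequence[VariantCall],
    participant_id: str = "",
    timepoint: str = "diagnostic",
) -> PlasmaCallSet:
    """Tumour-informed on non-UMI calls (no duplex family gate)."""
    return _tumour_informed("B", tissue_drivers, plasma_calls_non_umi, participant_id, timepoint)


def build_blacklist(
    all_cohort_plasma_calls: Mapping[str, Sequence[VariantCall]],
    recurrence_threshold: int = 10,
    cosmic_hotspot_min: int = 5,
    manual_overrides: Optional[Mapping[GenomicLocus, bool]] = None,
) -> Blacklist:
    """List loci occurring in strictly more than ``recurrence_threshold``
    distinct samples without COSMIC same-position support.

    ``manual_overrides`` (locus -> keep-on-blacklist) replaces the study's
    manual IGV review: True forces a locus onto the list, False exempts it.
    """
    sample_hits: dict[GenomicLocus, set[str]] = {}
    cosmic: dict[GenomicLocus, int] = {}
    for sample_id, calls in all_cohort_plasma_calls.items():
        for c in calls:
            locus = normalize_variant(c.locus)
            sample_hits.setdefault(locus, set()).add(sample_id)
            cosmic[locus] = max(
                cosmic.get(locus, 0), c.annotations.cosmic_same_position_count
            )
    overrides = {normalize_variant(k): v for k, v in (manual_overrides or {}).items()}
    loci, provenance = set(), {}
    for locus, hits in sample_hits.items():
        recurrent = len(hits) > recurrence_threshold
        listed = recurrent and cosmic[locus] < cosmic_hotspot_min
        if locus in overrides:
            listed = overrides[locus] and recurrent
        if listed:
            loci.add(locus)
            provenance[locus] = len(hits)
    return Blacklist(loci, provenance)


CASCADE_STEPS = (
    "blacklist",
    "exon_distance",
    "depth",
    "clinvar_benign",
    "local_cohort",
    "post_only",
    "verified_germline",
)


def _benign_excluded(call: VariantCall, cfg: RunConfig) -> bool:
    ann = call.annotations
    n_benign = ann.benign_source_count()
    return (n_benign >= 1 and ann.is_synonymous) or n_benign >= cfg.clinvar_multi_source_min


def approach_C(
    plasma_calls_umi: Sequence[VariantCall],
    blacklist: Blacklist,
    participant_id: str = "",
    timepoint: str = "diagnostic",
    paired_calls: Optional[Sequence[VariantCall]] = None,
    tissue_loci: Optional[Sequence[GenomicLocus]] = None,
    cfg: RunConfig = DEFAULT_CONFIG,
) -> PlasmaCallSet:
    """Tumour-agnostic cascade over caller-passing UMI calls.

    In order: (1) drop blacklisted loci; (2) keep only exon/splice-window
    variants; (3) drop low-depth sites; (4) drop ClinVar-benign calls
    (benign by one source and synonymous, or benign by multiple sources);
    (5) drop recurrent local-cohort germline calls; (6) post-treatment samples
    only: drop variants absent from the paired diagnostic sample unless they
    are COSMIC hotspots or seen in tissue; (7) drop verified germline variants
    sitting in the heterozygous plasma band in both paired samples.  Steps 6/7
    are silently skipped (and audited) when the paired sample is absent.
    """
    is_post = timepoint != "diagnostic"
    paired_loci = (
        {normalize_variant(c.locus): c.vaf for c in paired_calls}
        if paired_calls is not None
        else None
    )
    tissue_set = {normalize_variant(l) for l in (tissue_loci or [])}
    lo, hi = cfg.germline_plasma_band

    retained: list[VariantCall] = []
    audit: list[tuple[GenomicLocus, str]] = []
    if paired_calls is None:
        audit.append((None, "paired_sample_absent:steps_6_7_skipped"))

    for call in plasma_calls_umi:
        locus = normalize_variant(call.locus)
        ann = call.annotations
        step = None
        if locus in blacklist:
            step = "blacklist"
        elif ann.exon_distance > cfg.exon_distance_max:
            step = "exon_distance"
        elif call.total_reads < cfg.plasma_depth_floor:
            step = "depth"
        elif _benign_excluded(call, cfg):
            step = "clinvar_benign"
        elif ann.local_cohort_germline_count > cfg.local_cohort_max:
            step = "local_cohort"
        elif is_post and paired_loci is not None and locus not in paired_loci:
            if not (
                ann.cosmic_same_position_count >= cfg.cosmic_hotspot_min
                or locus in tissue_set
            ):
                step = "post_only"
        if (
            step is None
            and paired_loci is not None
            and locus in paired_loci
            and lo <= call.vaf <= hi
            and lo <= paired_loci[locus] <= hi
        ):
            step = "verified_germline"
        if step is None:
            retained.append(call)
        else:
            audit.append((locus, step))
    return PlasmaCallSet(participant_id, timepoint, "C", retained=retained, audit=audit)


def retained_loci(callset: PlasmaCallSet) -> set[GenomicLocus]:
    return {normalize_variant(c.locus) for c in callset.retained}
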