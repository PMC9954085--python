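"""End-to-end orchestration: tissue filtering, blacklist construction,
plasma approaches A–D and the cohort detection table, over a list of
participants (synthetic or loaded from disk)."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .ch import ChVerdict, approach_D
from .config import DEFAULT_CONFIG, RunConfig
from .core import (
    Caller,
    DetectionTable,
    GenomicLocus,
    Material,
    Participant,
    Timepoint,
    normalize_variant,
)
from .plasma import (
    Blacklist,
    PlasmaCallSet,
    apply_caller_pass_filters,
    approach_A,
    approach_B,
    approach_C,
    build_blacklist,
)
from .summary import build_detection_table
from .tissue import TissueVerdict, driver_loci, run_tissue_pipeline


@dataclass
class CohortResults:
    tissue_verdicts: dict[str, list[TissueVerdict]]
    tissue_drivers: dict[str, list[GenomicLocus]]
    blacklist: Blacklist
    callsets: list[PlasmaCallSet]
    ch_verdicts: dict[str, list[ChVerdict]] = field(default_factory=dict)
    detection_table: Optional[DetectionTable] = None

    def callset(self, participant_id: str, approach: str, timepoint: str) -> PlasmaCallSet:
        for cs in self.callsets:
            if (
                cs.participant_id == participant_id
                and cs.approach == approach
                and cs.timepoint == timepoint
            ):
                return cs
        raise KeyError((participant_id, approach, timepoint))


def _split_callers(sample):
    umi = [c for c in sample.calls if c.caller == Caller.UMI_CONSENSUS]
    non_umi = [c for c in sample.calls if c.caller == Caller.NON_UMI]
    return umi, non_umi


def run_cohort(
    participants: Sequence[Participant], cfg: RunConfig = DEFAULT_CONFIG
) -> CohortResults:
    """Run the full variant-filtering workflow over a cohort."""
    # ---- tissue: cohort occurrence then per-participant filtering --------
    occurrence: dict[GenomicLocus, int] = {}
    tissue_samples = {}
    for p in participants:
        t = p.sample(Material.TISSUE)
        if t is not None:
            tissue_samples[p.id] = t
            for call in {normalize_variant(c.locus) for c in t.calls}:
                occurrence[call] = occurrence.get(call, 0) + 1

    tissue_verdicts: dict[str, list[TissueVerdict]] = {}
    tissue_drivers: dict[str, list[GenomicLocus]] = {}
    for p in participants:
        t = tissue_samples.get(p.id)
        if t is None:
            continue
        wbc = p.sample(Material.WBC)
        verdicts = run_tissue_pipeline(
            t.calls, len(tissue_samples), occurrence,
            wbc_calls=wbc.calls if wbc else None, cfg=cfg,
        )
        tissue_verdicts[p.id] = verdicts
        tissue_drivers[p.id] = driver_loci(verdicts)

    # ---- blacklist over the whole set of called plasma variants ----------
    cohort_calls = {}
    for p in participants:
        for tp in (Timepoint.DIAGNOSTIC, Timepoint.POST_SURGERY):
            s = p.sample(Material.PLASMA, tp)
            if s is not None:
                cohort_calls[f"{p.id}:{tp.value}"] = [
                    c for c in s.calls if c.caller == Caller.UMI_CONSENSUS
                ]
    blacklist = build_blacklist(
        cohort_calls, cfg.blacklist_recurrence_threshold, cfg.cosmic_hotspot_min
    )

    # ---- per-participant plasma approaches ------------------------------
    callsets: list[PlasmaCallSet] = []
    ch_verdicts: dict[str, list[ChVerdict]] = {}
    expected: dict[str, Optional[bool]] = {}
    metadata: dict[str, dict[str, float]] = {}

    for p in participants:
        drivers = tissue_drivers.get(p.id) or None
        expected[p.id] = (
            None if p.id not in tissue_verdicts else bool(tissue_drivers.get(p.id))
        )
        diag = p.sample(Material.PLASMA, Timepoint.DIAGNOSTIC)
        post = p.sample(Material.PLASMA, Timepoint.POST_SURGERY)
        wbc = p.sample(Material.WBC)
        tissue_loci = [
            normalize_variant(v.variant.locus)
            for v in tissue_verdicts.get(p.id, [])
            if v.retained
        ]
        meta: dict[str, float] = {}
        if diag is not None:
            meta["plasma_diagnostic_ng"] = diag.cfdna_mass_ng
            meta["plasma_diagnostic_ml"] = diag.plasma_volume_ml
        if post is not None:
            meta["plasma_post_ng"] = post.cfdna_mass_ng
            meta["plasma_post_ml"] = post.plasma_volume_ml
        metadata[p.id] = meta

        passing = {}
        for tp_key, sample in (("diagnostic", diag), ("post", post)):
            if sample is None:
                for app in "ABCD":
                    callsets.append(
                        PlasmaCallSet(p.id, tp_key, app, na=True, na_reason="no_sample")
                    )
                continue
            umi_raw, non_umi_raw = _split_callers(sample)
            umi = apply_caller_pass_filters(umi_raw, cfg)
            non_umi = apply_caller_pass_filters(non_umi_raw, cfg)
            passing[tp_key] = umi

            callsets.append(approach_A(drivers, umi, p.id, tp_key))
            callsets.append(approach_B(drivers, non_umi, p.id, tp_key))

            paired = None
            if tp_key == "diagnostic" and post is not None:
                paired = apply_caller_pass_filters(
                    [c for c in post.calls if c.caller == Caller.UMI_CONSENSUS], cfg
                )
            elif tp_key == "post" and diag is not None:
                paired = apply_caller_pass_filters(
                    [c for c in diag.calls if c.caller == Caller.UMI_CONSENSUS], cfg
                )
            c_set = approach_C(
                umi, blacklist, p.id, tp_key,
                paired_calls=paired, tissue_loci=tissue_loci, cfg=cfg,
            )
            callsets.append(c_set)

            d_set, verdicts = approach_D(
                c_set,
                wbc_calls=wbc.calls if wbc is not None else None,
                paired_calls=paired,
                cfg=cfg,
            )
            callsets.append(d_set)
            if tp_key == "diagnostic":
                ch_verdicts[p.id] = verdicts

    table = build_detection_table(callsets, expected, metadata)
    return CohortResults(
        tissue_verdicts, tissue_drivers, blacklist, callsets, ch_verdicts, table
    )
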