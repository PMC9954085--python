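"""Clonal haematopoiesis (CH) and germline exclusion — approach D.

CH variants expand in blood stem cells and appear in both plasma and WBC DNA
but are not tumour-derived.  The primary filter looks the plasma variant up in
matched WBC calls; the fallback compares diagnostic and post-surgical plasma
VAFs: tumour-derived signal is diluted by the post-operative rise in total
cfDNA, blood-derived CH signal is not, so a post VAF above a quarter of the
diagnostic VAF points to CH.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

from .config import DEFAULT_CONFIG, RunConfig
from .core import ValidationError, VariantCall, normalize_variant
from .plasma import PlasmaCallSet


class ChSource(str, enum.Enum):
    WBC = "wbc"
    PAIRED_PLASMA = "paired_plasma"
    NONE = "none"


@dataclass
class ChVerdict:
    variant: VariantCall
    source: ChSource
    is_ch: bool = False
    is_germline: bool = False
    evidence: Optional[tuple] = None  # (wbc_alt_reads, wbc_vaf) or (diag_vaf, post_vaf)

    def __post_init__(self) -> None:
        if self.is_ch and self.is_germline:
            raise ValidationError("is_ch and is_germline are mutually exclusive")
        if self.source == ChSource.NONE and (self.is_ch or self.is_germline):
            raise ValidationError("source=none implies neither CH nor germline")


class ApproachENotSupported(NotImplementedError):
    """Non-UMI calls with WBC CH filtering (approach E) have no robust
    read-count or VAF threshold separating CH from tumour signal; the
    combination is deliberately unsupported."""


def ch_filter_wbc(
    variant: VariantCall,
    wbc_calls: Sequence[VariantCall],
    read_threshold: int = 4,
    vaf_threshold: float = 0.0005,
    germline_band: tuple[float, float] = (0.40, 0.60),
) -> ChVerdict:
    """Classify a plasma variant against matched WBC calls.

    Presence in WBC in strictly more than ``read_threshold`` alt reads or
    above ``vaf_threshold`` VAF is proof of CH (below the germline band) or
    of a germline variant (WBC VAF around 50%).  Absent from WBC: neither.
    """
    locus = normalize_variant(variant.locus)
    hit = next((c for c in wbc_calls if normalize_variant(c.locus) == locus), None)
    if hit is None:
        return ChVerdict(variant, ChSource.WBC)
    lo, hi = germline_band
    is_germline = lo <= hit.vaf <= hi
    is_ch = (
        not is_germline
        and hit.vaf < lo
        and (hit.alt_reads > read_threshold or hit.vaf > vaf_threshold)
    )
    return ChVerdict(
        variant, ChSource.WBC, is_ch=is_ch, is_germline=is_germline,
        evidence=(hit.alt_reads, hit.vaf),
    )


def ch_filter_paired(
    variant: VariantCall,
    diagnostic_vaf: float,
    post_vaf: Optional[float],
    ratio: float = 4.0,
) -> ChVerdict:
    """Quarter-VAF fallback on paired plasma samples.

    CH iff the variant persists post-surgery with a VAF above a
    ``1/ratio`` fraction of the diagnostic VAF; absence post-surgery argues
    against CH (blood-derived signal would not vanish).
    """
    if post_vaf is None:
        return ChVerdict(variant, ChSource.PAIRED_PLASMA, evidence=(diagnostic_vaf, None))
    is_ch = post_vaf > diagnostic_vaf / ratio
    return ChVerdict(
        variant, ChSource.PAIRED_PLASMA, is_ch=is_ch, evidence=(diagnostic_vaf, post_vaf)
    )


def approach_D(
    c_results: PlasmaCallSet,
    wbc_calls: Optional[Sequence[VariantCall]] = None,
    paired_calls: Optional[Sequence[VariantCall]] = None,
    cfg: RunConfig = DEFAULT_CONFIG,
) -> tuple[PlasmaCallSet, list[ChVerdict]]:
    """Remove CH/germline variants from the tumour-agnostic retained set.

    WBC data takes precedence; paired post-surgical plasma is the fallback.
    With neither, the participant is unfilterable and the result is NA.
    Removal-only: D retained is always a subset of C retained.
    """
    if c_results.na:
        return (
            PlasmaCallSet(
                c_results.participant_id, c_results.timepoint, "D",
                na=True, na_reason=c_results.na_reason,
            ),
            [],
        )
    if wbc_calls is None and paired_calls is None:
        return (
            PlasmaCallSet(
                c_results.participant_id, c_results.timepoint, "D",
                na=True, na_reason="no_wbc_no_paired_sample",
            ),
            [],
        )

    paired_vafs = (
        {normalize_variant(c.locus): c.vaf for c in paired_calls}
        if paired_calls is not None
        else {}
    )
    is_diagnostic = c_results.timepoint == "diagnostic"
    verdicts, retained, audit = [], [], []
    source = "wbc" if wbc_calls is not None else "paired_plasma"
    for call in c_results.retained:
        if wbc_calls is not None:
            verdict = ch_filter_wbc(
                call, wbc_calls, cfg.wbc_read_threshold, cfg.wbc_vaf_threshold,
                cfg.wbc_germline_band,
            )
        else:
            paired_vaf = paired_vafs.get(normalize_variant(call.locus))
            if is_diagnostic:
                diag_vaf, post_vaf = call.vaf, paired_vaf
            else:
                # post-surgical call set: the paired sample is the diagnostic
                # one; a variant absent from it cannot be assessed and the
                # quarter rule is oriented the same way
                if paired_vaf is None:
                    verdict = ChVerdict(
                        call, ChSource.PAIRED_PLASMA, evidence=(None, call.vaf)
                    )
                    verdicts.append(verdict)
                    retained.append(call)
                    continue
                diag_vaf, post_vaf = paired_vaf, call.vaf
            verdict = ch_filter_paired(
                call, diag_vaf, post_vaf, cfg.paired_plasma_ratio
            )
        verdicts.append(verdict)
        if verdict.is_ch:
            audit.append((normalize_variant(call.locus), f"ch:{source}"))
        elif verdict.is_germline:
            audit.append((normalize_variant(call.locus), f"germline:{source}"))
        else:
            retained.append(call)
    result = PlasmaCallSet(
        c_results.participant_id, c_results.timepoint, "D",
        retained=retained, audit=audit,
    )
    return result, verdicts


def approach_E(*_args, **_kwargs):
    raise ApproachENotSupported(
        "approach E (non-UMI calls + WBC CH filtering) is unsupported: no robust "
        "read or VAF threshold separates CH from tumour-derived variants without "
        "UMI error suppression"
    )
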