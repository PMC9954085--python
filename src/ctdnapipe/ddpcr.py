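"""Droplet digital PCR quantification and positivity calling.

Each ~0.85 nL droplet either contains template molecules or not; the fraction
of positive droplets p estimates the per-droplet Poisson occupancy λ·v through
p = 1 − e^{−λv}, inverted as λ = −ln(1 − p)/v.  Replicate wells are merged by
pooling droplet counts before inversion (one Poisson estimate on the pooled
partition count, the documented analyser behaviour).  Confidence intervals are
Wilson score intervals on p, propagated through the (monotone) inversion.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from statsmodels.stats.proportion import proportion_confint

from .core import ValidationError


class WellRole(str, enum.Enum):
    SAMPLE = "sample"
    WILDTYPE_CONTROL = "wildtype_control"
    POSITIVE_CONTROL = "positive_control"
    NO_TEMPLATE_CONTROL = "no_template_control"


class SaturatedWellError(ValueError):
    """All droplets positive: the Poisson inversion diverges; dilute and rerun."""


@dataclass(frozen=True)
class DdpcrWell:
    well_id: str
    role: WellRole
    #: positive droplet count per channel/assay target (FAM targets, HEX wildtype)
    channel_counts: Mapping[str, int]
    total_droplets: int
    droplet_volume_nl: float = 0.85

    def __post_init__(self) -> None:
        if self.total_droplets <= 0:
            raise ValidationError("total_droplets must be > 0")
        for ch, n in self.channel_counts.items():
            if not 0 <= n <= self.total_droplets:
                raise ValidationError(
                    f"channel {ch}: positive count {n} outside [0, {self.total_droplets}]"
                )


@dataclass(frozen=True)
class Concentration:
    """Copies per microlitre of reaction with a confidence interval."""

    value: float
    ci_low: float
    ci_high: float

    def overlaps(self, other: "Concentration") -> bool:
        return self.ci_low <= other.ci_high and other.ci_low <= self.ci_high


@dataclass
class DdpcrAssayResult:
    target: str
    merged_concentration: Concentration
    vaf_percent: float
    false_positive_rate_percent: float = 0.0
    copies_per_ml_plasma: Optional[float] = None
    positive: Optional[bool] = None
    no_template: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf_percent <= 100.0:
            raise ValidationError("vaf_percent must be in [0, 100]")
        c = self.merged_concentration
        if not c.ci_low <= c.value <= c.ci_high:
            raise ValidationError("concentration CI must bracket the point estimate")


def concentration_from_counts(
    n_positive: int,
    n_total: int,
    droplet_volume_nl: float = 0.85,
    ci_level: float = 0.95,
) -> Concentration:
    """Poisson-invert a positive-droplet count into copies/µL with a CI.

    Strictly increasing in ``n_positive`` at fixed ``n_total``.  A fully
    positive plate is flagged saturated rather than returning infinity.
    """
    if n_total <= 0:
        raise ValidationError("n_total must be > 0")
    if not 0 <= n_positive <= n_total:
        raise ValidationError("n_positive outside [0, n_total]")
    if n_positive == n_total:
        raise SaturatedWellError(
            f"{n_positive}/{n_total} droplets positive: dilute the sample and rerun"
        )
    v_ul = droplet_volume_nl * 1e-3  # nL -> µL

    def invert(p: float) -> float:
        return -math.log1p(-p) / v_ul

    p = n_positive / n_total
    lo, hi = proportion_confint(n_positive, n_total, alpha=1 - ci_level, method="wilson")
    hi = min(hi, 1.0 - 1.0 / (2 * n_total))  # keep the upper bound invertible
    return Concentration(invert(p), invert(max(lo, 0.0)), invert(hi))


def merge_replicates(
    wells: Sequence[DdpcrWell], target: str
) -> tuple[int, int, float]:
    """Pool droplet counts for one target across replicate wells.

    Returns (positive, total, droplet volume); counts are summed before the
    Poisson inversion, which makes merging exact rather than an average of
    per-well estimates.
    """
    if not wells:
        raise ValidationError("no wells to merge")
    volumes = {w.droplet_volume_nl for w in wells}
    if len(volumes) > 1:
        raise ValidationError("cannot merge wells with different droplet volumes")
    n_pos = sum(w.channel_counts.get(target, 0) for w in wells)
    n_tot = sum(w.total_droplets for w in wells)
    return n_pos, n_tot, volumes.pop()


def merged_concentration(
    wells: Sequence[DdpcrWell], target: str, ci_level: float = 0.95
) -> Concentration:
    n_pos, n_tot, vol = merge_replicates(wells, target)
    return concentration_from_counts(n_pos, n_tot, vol, ci_level)


def vaf_singleplex(conc_target: float, conc_wildtype: float) -> float:
    """Percent VAF from target (FAM) and wildtype (HEX) concentrations."""
    if conc_target < 0 or conc_wildtype < 0:
        raise ValidationError("concentrations must be >= 0")
    denom = conc_target + conc_wildtype
    if denom == 0:
        return 0.0  # no template; callers should flag
    return 100.0 * conc_target / denom


def vaf_multiplex(
    conc_target1: float, conc_target2: float, conc_wildtype_of_target1: float
) -> tuple[float, float]:
    """Percent VAFs in an amplitude-multiplex assay with a wildtype assay for
    target 1 only: both targets share the target1 + wildtype denominator."""
    denom = conc_target1 + conc_wildtype_of_target1
    if denom == 0:
        return 0.0, 0.0
    return 100.0 * conc_target1 / denom, 100.0 * conc_target2 / denom


def copies_per_ml(
    concentration: float,
    elution_volume_ul: float,
    input_volume_ul: float,
    plasma_volume_ml: float,
) -> float:
    """Scale a reaction concentration (copies/µL) to copies per mL plasma."""
    for name, v in (
        ("elution_volume_ul", elution_volume_ul),
        ("input_volume_ul", input_volume_ul),
        ("plasma_volume_ml", plasma_volume_ml),
    ):
        if v <= 0:
            raise ValidationError(f"{name} must be > 0")
    return concentration * elution_volume_ul / (input_volume_ul * plasma_volume_ml)


def false_positive_rate(
    wt_wells: Sequence[DdpcrWell], target: str, wildtype_channel: str = "WT"
) -> float:
    """Apparent target VAF (%) in merged wildtype-control wells."""
    wells = [w for w in wt_wells if w.role == WellRole.WILDTYPE_CONTROL]
    if not wells:
        raise ValidationError("at least one wildtype-control well required")
    t_pos, t_tot, vol = merge_replicates(wells, target)
    w_pos, _, _ = merge_replicates(wells, wildtype_channel)
    conc = lambda n: 0.0 if n == 0 else -math.log1p(-n / t_tot) / (vol * 1e-3)
    return vaf_singleplex(conc(t_pos), conc(w_pos))


def call_positive(sample: DdpcrAssayResult, control: DdpcrAssayResult) -> bool:
    """Positivity rule for one target: sample VAF above the assay's
    false-positive rate AND sample/control concentration CIs disjoint."""
    if not sample.vaf_percent > sample.false_positive_rate_percent:
        return False
    return not sample.merged_concentration.overlaps(control.merged_concentration)


def call_positive_from_summary(
    vaf_percent: float, false_positive_rate_percent: float, ci_overlap: bool
) -> bool:
    """Positivity rule applied to summarised results (printed VAF, assay FPR
    and a CI-overlap flag) rather than raw droplet counts."""
    return vaf_percent > false_positive_rate_percent and not ci_overlap


def theoretical_lod(hge_input: float, min_molecules: int = 3) -> float:
    """Input-limited detection floor, in percent: the VAF at which
    ``min_molecules`` mutant copies are expected among the available haploid
    genome equivalents, regardless of assay false-positive rate."""
    if hge_input <= 0:
        raise ValidationError("hge_input must be > 0")
    return 100.0 * min_molecules / hge_input
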