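"""Synthetic cohort generation with known ground truth.

Every pipeline stage is testable without access to the study's raw data: the
generator emulates the study's stated conditions — tissue variants at VAF
5–90% (median ~20%), plasma ctDNA at a median VAF of 0.6% (range 0.07–17%)
sampled binomially at a UMI-collapsed depth with median ~1300×, germline
variants near VAF 50%, CH variants present in both WBC and plasma and NOT
diluted after surgery (they derive from blood), recurrent cross-sample
artefact loci, a ~3.6× post-surgical rise in total cfDNA that dilutes
tumour-derived VAFs, and survival times with an elevated hazard for
ctDNA-shedding participants.

Truth labels ride on ``Participant.truth`` out-of-band; the pipeline under
test never sees them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import (
    AnnotationBundle,
    Caller,
    ClinvarClass,
    GenomicLocus,
    Material,
    Participant,
    SampleRecord,
    Timepoint,
    UmiSupport,
    ValidationError,
    VariantCall,
)
from .ddpcr import DdpcrWell, WellRole

# toy gene panel: (gene, chrom, window start) for locus placement
_PANEL = [
    ("TP53", "chr17", 7_570_000),
    ("KMT2D", "chr12", 49_410_000),
    ("ARID1A", "chr1", 27_020_000),
    ("KRAS", "chr12", 25_360_000),
    ("PIK3CA", "chr3", 178_860_000),
    ("APC", "chr5", 112_040_000),
    ("ERBB2", "chr17", 37_840_000),
    ("RB1", "chr13", 48_870_000),
    ("NF1", "chr17", 29_420_000),
    ("POLE", "chr12", 133_200_000),
    ("MYC", "chr8", 128_740_000),
    ("SMAD4", "chr18", 48_550_000),
    ("CDH1", "chr16", 68_770_000),
    ("PTEN", "chr10", 89_620_000),
]

_STAGES = ["IA", "IB", "IIA", "IIB", "IIIA", "IIIB", "IIIC", "IV"]
_STAGE_P = [0.11, 0.15, 0.11, 0.11, 0.08, 0.04, 0.32, 0.08]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters; defaults encode the published cohort."""

    n_participants: int = 47
    fraction_tissue_positive: float = 31 / 47
    drivers_per_positive_mean: float = 2.2  # drivers = 1 + Poisson(mean)

    tissue_vaf_range: tuple[float, float] = (0.05, 0.90)  # log-uniform, median ~0.21

    plasma_vaf_median: float = 0.006
    plasma_vaf_sigma: float = 1.2  # log-scale sd, truncated to plasma_vaf_range
    plasma_vaf_range: tuple[float, float] = (0.0007, 0.17)
    shedding_rate: float = 0.55  # fraction of tissue-positive participants with ctDNA

    depth_median: float = 1309.0
    depth_sigma: float = 0.55
    depth_range: tuple[float, float] = (143.0, 4533.0)

    dilution_factor: float = 3.6  # median post/diag total-cfDNA concentration ratio
    dilution_sigma: float = 0.30  # per-participant log-normal spread around it
    residual_disease_rate: float = 0.18
    residual_margin: float = 10.0  # residual tumour post VAF = diagnostic / margin

    ch_mean_per_participant: float = 0.4
    ch_vaf_range: tuple[float, float] = (0.005, 0.05)  # log-uniform clone sizes

    germline_mean_per_participant: float = 0.5
    germline_vaf_sd: float = 0.03

    n_artefact_loci: int = 25
    artefact_sample_range: tuple[int, int] = (11, 30)  # distinct plasma samples hit
    artefact_vaf_range: tuple[float, float] = (0.003, 0.01)

    wbc_available_rate: float = 21 / 47
    diagnostic_failure_rate: float = 3 / 47
    post_missing_rate: float = 2 / 47

    survival_hr_detectable: float = 2.5
    baseline_median_os_years: float = 4.5
    censoring_years: float = 5.5
    pfs_hazard_multiplier: float = 1.5

    tissue_depth: int = 800
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "fraction_tissue_positive",
            "shedding_rate",
            "residual_disease_rate",
            "wbc_available_rate",
            "diagnostic_failure_rate",
            "post_missing_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be a probability, got {v}")
        if self.artefact_sample_range[0] <= 10:
            # artefacts are meant to recur above the blacklist threshold
            raise ValidationError("artefact_sample_range must start above 10 samples")
        if self.residual_margin < self.dilution_factor:
            raise ValidationError(
                "residual_margin below the dilution factor would place residual "
                "tumour VAFs on the wrong side of the quarter rule"
            )


@dataclass
class SyntheticCohort:
    participants: list[Participant]
    artefact_loci: list[GenomicLocus]
    config: GeneratorConfig
    #: participant id -> ground-truth ctDNA shedding flag (drives survival)
    shedding: dict[str, bool] = field(default_factory=dict)
    #: participant id -> planted tumour-variant VAF in the diagnostic plasma
    tumour_plasma_vaf: dict[str, dict[GenomicLocus, float]] = field(default_factory=dict)
    #: participant id -> UMI-collapsed depth of the diagnostic plasma sample
    diagnostic_depth: dict[str, int] = field(default_factory=dict)


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(math.log(lo), math.log(hi))))


def _trunc_lognormal(
    rng: np.random.Generator, median: float, sigma: float, lo: float, hi: float
) -> float:
    for _ in range(100):
        v = float(np.exp(rng.normal(math.log(median), sigma)))
        if lo <= v <= hi:
            return v
    return float(min(max(median, lo), hi))


def _random_locus(rng: np.random.Generator, used: set[GenomicLocus]) -> tuple[str, GenomicLocus]:
    bases = "ACGT"
    while True:
        gene, chrom, start = _PANEL[rng.integers(len(_PANEL))]
        pos = int(start + rng.integers(50_000))
        ref = bases[rng.integers(4)]
        alt = bases[rng.integers(4)]
        if ref == alt:
            continue
        locus = GenomicLocus(chrom, pos, ref, alt)
        if locus not in used:
            used.add(locus)
            return gene, locus


def _driver_annotations(rng: np.random.Generator) -> AnnotationBundle:
    if rng.random() < 0.6:
        return AnnotationBundle(
            clinvar_class=ClinvarClass.PATHOGENIC,
            clinvar_source_counts={ClinvarClass.PATHOGENIC: int(1 + rng.integers(4))},
            gnomad_max_pop_af=0.0,
            cosmic_same_position_count=int(rng.integers(0, 30)),
        )
    return AnnotationBundle(
        clinvar_class=ClinvarClass.UNREPORTED,
        gnomad_max_pop_af=float(rng.uniform(0, 1e-4)),
        cosmic_same_position_count=int(5 + rng.poisson(10)),
    )


def _germline_annotations(rng: np.random.Generator, has_wbc: bool) -> AnnotationBundle:
    # most rare germline variants are VUS-class; a minority are known P/LP
    # (the case the origin-classification rules exist for).  P/LP germline is
    # only planted for participants with WBC data, emulating confirmatory
    # blood testing of suspected pathogenic germline findings — without it the
    # companion-VAF heuristic has no germline evidence to override it.
    if has_wbc and rng.random() < 0.3:
        return AnnotationBundle(
            clinvar_class=ClinvarClass.PATHOGENIC,
            clinvar_source_counts={ClinvarClass.PATHOGENIC: 1},
            gnomad_max_pop_af=float(rng.uniform(0, 0.004)),
            cosmic_same_position_count=0,
        )
    return AnnotationBundle(
        clinvar_class=ClinvarClass.VUS,
        gnomad_max_pop_af=float(rng.uniform(0, 0.004)),
        cosmic_same_position_count=0,
    )


def _ch_annotations(rng: np.random.Generator) -> AnnotationBundle:
    # a fair share of CH hits known cancer hotspots, which is exactly why
    # WBC/paired filtering is needed on top of database annotation
    if rng.random() < 0.5:
        return AnnotationBundle(
            clinvar_class=ClinvarClass.PATHOGENIC,
            clinvar_source_counts={ClinvarClass.PATHOGENIC: 2},
            cosmic_same_position_count=int(5 + rng.poisson(8)),
        )
    return AnnotationBundle(
        clinvar_class=ClinvarClass.UNREPORTED,
        gnomad_max_pop_af=float(rng.uniform(0, 1e-4)),
        cosmic_same_position_count=0,
    )


_ARTEFACT_ANN = AnnotationBundle(
    clinvar_class=ClinvarClass.UNREPORTED, cosmic_same_position_count=0
)


def _sampled_call(
    rng: np.random.Generator,
    gene: str,
    locus: GenomicLocus,
    true_vaf: float,
    depth: int,
    ann: AnnotationBundle,
    min_alt: int = 0,
) -> Optional[tuple[VariantCall, VariantCall]]:
    """Binomially sample one plasma variant; returns the (UMI, non-UMI) call
    pair or None when no alt molecule was drawn."""
    alt = int(rng.binomial(depth, min(true_vaf, 1.0)))
    alt = max(alt, min_alt)
    if alt == 0:
        return None
    top = int(rng.binomial(alt, 0.5))
    support = UmiSupport(top, alt - top)
    vaf = alt / depth
    umi = VariantCall(
        locus, gene, vaf, alt, depth, quality_lod=10.0,
        caller=Caller.UMI_CONSENSUS, umi_support=support, annotations=ann,
    )
    non_umi = VariantCall(
        locus, gene, vaf, alt, depth, quality_lod=10.0,
        caller=Caller.NON_UMI, annotations=ann,
    )
    return umi, non_umi


def _deterministic_call(
    gene: str, locus: GenomicLocus, vaf: float, depth: int, ann: AnnotationBundle
) -> VariantCall:
    """Expected-count representation used for WBC consensus calls."""
    alt = max(1, round(vaf * depth))
    top = (alt + 1) // 2
    return VariantCall(
        locus, gene, alt / depth, alt, depth, quality_lod=10.0,
        caller=Caller.UMI_CONSENSUS, umi_support=UmiSupport(top, alt - top),
        annotations=ann,
    )


def generate_cohort(config: GeneratorConfig = GeneratorConfig()) -> SyntheticCohort:
    """Generate a full labelled cohort; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    used_loci: set[GenomicLocus] = set()

    # cohort-level recurrent artefact loci and their target samples
    artefacts = []
    for _ in range(config.n_artefact_loci):
        gene, locus = _random_locus(rng, used_loci)
        n_hit = int(rng.integers(config.artefact_sample_range[0],
                                 config.artefact_sample_range[1] + 1))
        vaf = _log_uniform(rng, *config.artefact_vaf_range)
        artefacts.append((gene, locus, n_hit, vaf))

    participants: list[Participant] = []
    shedding_map: dict[str, bool] = {}
    tumour_vaf_map: dict[str, dict[GenomicLocus, float]] = {}
    depth_map: dict[str, int] = {}
    plasma_slots: list[tuple[int, str]] = []  # (participant index, timepoint key)

    base_hazard = math.log(2) / config.baseline_median_os_years

    for i in range(config.n_participants):
        pid = f"S{i + 1:02d}"
        stage = str(rng.choice(_STAGES, p=_STAGE_P))
        truth: dict[GenomicLocus, str] = {}

        tissue_positive = rng.random() < config.fraction_tissue_positive
        has_diag = rng.random() >= config.diagnostic_failure_rate
        has_post = rng.random() >= config.post_missing_rate
        has_wbc = rng.random() < config.wbc_available_rate

        depth_diag = int(_trunc_lognormal(rng, config.depth_median, config.depth_sigma,
                                          *config.depth_range))
        depth_post = int(_trunc_lognormal(rng, config.depth_median, config.depth_sigma,
                                          *config.depth_range))
        depth_wbc = int(_trunc_lognormal(rng, config.depth_median, config.depth_sigma,
                                         *config.depth_range))

        # planted variants -----------------------------------------------
        drivers: list[tuple[str, GenomicLocus, float, AnnotationBundle]] = []
        if tissue_positive:
            n_drivers = 1 + int(rng.poisson(config.drivers_per_positive_mean))
            for _ in range(n_drivers):
                gene, locus = _random_locus(rng, used_loci)
                tvaf = _log_uniform(rng, *config.tissue_vaf_range)
                drivers.append((gene, locus, tvaf, _driver_annotations(rng)))
                truth[locus] = "tumour"

        germlines: list[tuple[str, GenomicLocus, float, AnnotationBundle]] = []
        for _ in range(int(rng.poisson(config.germline_mean_per_participant))):
            gene, locus = _random_locus(rng, used_loci)
            gvaf = float(np.clip(rng.normal(0.5, config.germline_vaf_sd), 0.30, 0.70))
            germlines.append((gene, locus, gvaf, _germline_annotations(rng, has_wbc)))
            truth[locus] = "germline"

        ch_variants: list[tuple[str, GenomicLocus, float, AnnotationBundle]] = []
        for _ in range(int(rng.poisson(config.ch_mean_per_participant))):
            gene, locus = _random_locus(rng, used_loci)
            cvaf = _log_uniform(rng, *config.ch_vaf_range)
            ch_variants.append((gene, locus, cvaf, _ch_annotations(rng)))
            truth[locus] = "ch"

        sheds = tissue_positive and rng.random() < config.shedding_rate
        shedding_map[pid] = sheds
        ctdna_anchor = (
            _trunc_lognormal(rng, config.plasma_vaf_median, config.plasma_vaf_sigma,
                             *config.plasma_vaf_range)
            if sheds
            else 0.0
        )
        residual = sheds and rng.random() < config.residual_disease_rate
        median_tissue_vaf = math.sqrt(
            config.tissue_vaf_range[0] * config.tissue_vaf_range[1]
        )

        samples: list[SampleRecord] = []

        # tissue sample ---------------------------------------------------
        if tissue_positive or germlines:
            tissue_calls = []
            for gene, locus, tvaf, ann in drivers + germlines:
                depth = config.tissue_depth
                alt = max(1, round(tvaf * depth))
                tissue_calls.append(
                    VariantCall(locus, gene, alt / depth, alt, depth, quality_lod=20.0,
                                caller=Caller.NON_UMI, annotations=ann)
                )
            samples.append(SampleRecord(pid, Material.TISSUE, calls=tissue_calls))

        # plasma samples ---------------------------------------------------
        diag_mass = _log_uniform(rng, 15.0, 240.0)
        diag_vol = float(rng.choice([3.0, 4.0, 5.0]))
        dilution = float(
            np.exp(rng.normal(math.log(config.dilution_factor), config.dilution_sigma))
        )
        post_vol = float(rng.choice([3.0, 4.0, 5.0]))
        post_mass = diag_mass / diag_vol * dilution * post_vol

        plasma_vaf_diag: dict[GenomicLocus, tuple[str, float, AnnotationBundle]] = {}
        plasma_vaf_post: dict[GenomicLocus, tuple[str, float, AnnotationBundle]] = {}
        for gene, locus, tvaf, ann in drivers:
            if not sheds:
                continue
            pvaf = float(
                np.clip(ctdna_anchor * tvaf / median_tissue_vaf,
                        config.plasma_vaf_range[0] / 2, config.plasma_vaf_range[1])
            )
            plasma_vaf_diag[locus] = (gene, pvaf, ann)
            tumour_vaf_map.setdefault(pid, {})[locus] = pvaf
            if residual:
                plasma_vaf_post[locus] = (gene, pvaf / config.residual_margin, ann)
        for gene, locus, gvaf, ann in germlines:
            plasma_vaf_diag[locus] = (gene, gvaf, ann)
            plasma_vaf_post[locus] = (gene, gvaf, ann)
        for gene, locus, cvaf, ann in ch_variants:
            plasma_vaf_diag[locus] = (gene, cvaf, ann)
            plasma_vaf_post[locus] = (gene, cvaf, ann)  # CH is not diluted by surgery

        if has_diag:
            calls = []
            for locus, (gene, vaf, ann) in plasma_vaf_diag.items():
                pair = _sampled_call(rng, gene, locus, vaf, depth_diag, ann)
                if pair:
                    calls.extend(pair)
            samples.append(
                SampleRecord(pid, Material.PLASMA, Timepoint.DIAGNOSTIC,
                             plasma_volume_ml=diag_vol, cfdna_mass_ng=diag_mass,
                             calls=calls)
            )
            plasma_slots.append((i, "diagnostic"))
            depth_map[pid] = depth_diag
        if has_post:
            calls = []
            for locus, (gene, vaf, ann) in plasma_vaf_post.items():
                pair = _sampled_call(rng, gene, locus, vaf, depth_post, ann)
                if pair:
                    calls.extend(pair)
            samples.append(
                SampleRecord(pid, Material.PLASMA, Timepoint.POST_SURGERY,
                             plasma_volume_ml=post_vol, cfdna_mass_ng=post_mass,
                             calls=calls)
            )
            plasma_slots.append((i, "post"))

        # WBC sample: CH and germline, never tumour-only variants ----------
        if has_wbc:
            wbc_calls = [
                _deterministic_call(gene, locus, vaf, depth_wbc, ann)
                for gene, locus, vaf, ann in ch_variants
            ] + [
                _deterministic_call(gene, locus, vaf, depth_wbc, ann)
                for gene, locus, vaf, ann in germlines
            ]
            samples.append(SampleRecord(pid, Material.WBC, calls=wbc_calls))

        # survival ---------------------------------------------------------
        hazard = base_hazard * (config.survival_hr_detectable if sheds else 1.0)
        event_t = float(rng.exponential(1.0 / hazard))
        censor_t = float(rng.uniform(0.05, config.censoring_years))
        os_years = max(min(event_t, censor_t), 1e-3)
        os_event = event_t <= censor_t
        pfs_hazard = hazard * config.pfs_hazard_multiplier
        pfs_t = float(rng.exponential(1.0 / pfs_hazard))
        pfs_years = max(min(pfs_t, censor_t), 1e-3)
        pfs_event = pfs_t <= censor_t

        participants.append(
            Participant(pid, stage, samples, os_years, os_event,
                        pfs_years, pfs_event, truth=truth)
        )

    # plant artefacts across plasma samples ------------------------------
    for gene, locus, n_hit, vaf in artefacts:
        if not plasma_slots:
            break
        chosen = rng.choice(len(plasma_slots), size=min(n_hit, len(plasma_slots)),
                            replace=False)
        for slot in chosen:
            idx, tp_key = plasma_slots[slot]
            participant = participants[idx]
            tp = Timepoint.DIAGNOSTIC if tp_key == "diagnostic" else Timepoint.POST_SURGERY
            sample = participant.sample(Material.PLASMA, tp)
            pair = _sampled_call(
                rng, gene, locus, vaf, sample.calls[0].total_reads if sample.calls else 1000,
                _ARTEFACT_ANN, min_alt=4,
            )
            if pair:
                sample.calls.extend(pair)
            if participant.truth is not None:
                participant.truth[locus] = "artefact"

    return SyntheticCohort(
        participants, [a[1] for a in artefacts], config, shedding_map,
        tumour_vaf_map, depth_map,
    )


def generate_ddpcr_wells(
    true_target_lambda: float,
    true_wt_lambda: float,
    n_droplets: int = 20_000,
    n_replicates: int = 3,
    seed: int = 0,
    droplet_volume_nl: float = 0.85,
    role: WellRole = WellRole.SAMPLE,
    target: str = "target",
    wildtype_channel: str = "WT",
) -> list[DdpcrWell]:
    """Simulate droplet partitioning for one assay.

    Per-droplet template occupancy is Poisson(λ·v) per channel, so a droplet
    is positive with probability 1 − e^{−λv}; positives are drawn binomially.
    λ is in copies/µL, v the droplet volume.  Deterministic given ``seed``.
    """
    if true_target_lambda < 0 or true_wt_lambda < 0:
        raise ValidationError("concentrations must be >= 0")
    if n_droplets <= 0:
        raise ValidationError("n_droplets must be > 0")
    rng = np.random.default_rng(seed)
    v_ul = droplet_volume_nl * 1e-3
    p_t = 1.0 - math.exp(-true_target_lambda * v_ul)
    p_w = 1.0 - math.exp(-true_wt_lambda * v_ul)
    wells = []
    for k in range(n_replicates):
        wells.append(
            DdpcrWell(
                well_id=f"{role.value}_{k + 1}",
                role=role,
                channel_counts={
                    target: int(rng.binomial(n_droplets, p_t)),
                    wildtype_channel: int(rng.binomial(n_droplets, p_w)),
                },
                total_droplets=n_droplets,
                droplet_volume_nl=droplet_volume_nl,
            )
        )
    return wells
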