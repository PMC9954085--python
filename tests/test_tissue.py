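"""Tissue filtering, origin classification and driver designation."""

import numpy as np
import pytest

from ctdnapipe.config import DEFAULT_CONFIG
from ctdnapipe.core import ClinvarClass
from ctdnapipe.pipeline import run_cohort
from ctdnapipe.simulate import GeneratorConfig, generate_cohort
from ctdnapipe.tissue import (
    ExclusionReason,
    Origin,
    classify_driver,
    classify_origin,
    filter_tissue_variants,
    resolve_origin_with_wbc,
)

from .conftest import PATHOGENIC, make_call


def tissue_call(vaf, **ann):
    return make_call(vaf=vaf, depth=800, caller="non_umi", umi=None, **ann)


class TestRetentionRules:
    def test_vaf_floor_excludes_pathogenic(self):
        v = filter_tissue_variants([tissue_call(0.04, **PATHOGENIC)], 40, {})
        assert not v[0].retained
        assert v[0].exclusion_reason == ExclusionReason.VAF_FLOOR

    def test_pathogenic_exonic_retained(self):
        v = filter_tissue_variants([tissue_call(0.50, **PATHOGENIC)], 40, {})
        assert v[0].retained

    def test_gnomad_gate(self):
        v = filter_tissue_variants([tissue_call(0.30, gnomad_max_pop_af=0.02)], 40, {})
        assert not v[0].retained
        assert v[0].exclusion_reason == ExclusionReason.CLINVAR_GNOMAD

    def test_exon_distance_gate(self):
        v = filter_tissue_variants([tissue_call(0.50, exon_distance=6, **PATHOGENIC)], 40, {})
        assert v[0].exclusion_reason == ExclusionReason.EXON_DISTANCE

    def test_local_cohort_gate(self):
        v = filter_tissue_variants(
            [tissue_call(0.50, local_cohort_germline_count=6, **PATHOGENIC)], 40, {}
        )
        assert v[0].exclusion_reason == ExclusionReason.LOCAL_COHORT

    def test_cohort_recurrence_needs_cosmic_support(self):
        call = tissue_call(0.50, **PATHOGENIC)
        occ = {call.locus: 25}
        assert not filter_tissue_variants([call], 40, occ)[0].retained
        hot = tissue_call(0.50, clinvar_class=ClinvarClass.PATHOGENIC,
                          cosmic_same_position_count=9)
        assert filter_tissue_variants([hot], 40, {hot.locus: 25})[0].retained

    def test_missing_annotations_default_benignly(self):
        # an unannotated non-pathogenic variant passes only via the gnomAD branch
        v = filter_tissue_variants([tissue_call(0.30)], 40, {})
        assert v[0].retained

    def test_retained_set_matches_rule_by_rule_oracle(self):
        """Random variants against a plain re-statement of the conjunction."""
        rng = np.random.default_rng(21)
        cfg = DEFAULT_CONFIG
        calls = []
        for i in range(1000):
            calls.append(
                make_call(
                    pos=1000 + i,
                    vaf=float(rng.uniform(0, 1)),
                    depth=800,
                    umi=None,
                    caller="non_umi",
                    clinvar_class=rng.choice(
                        [ClinvarClass.PATHOGENIC, ClinvarClass.UNREPORTED,
                         ClinvarClass.BENIGN, ClinvarClass.VUS]
                    ),
                    gnomad_max_pop_af=float(rng.choice([0.0, 0.001, 0.02, 0.3])),
                    cosmic_same_position_count=int(rng.choice([0, 3, 7])),
                    local_cohort_germline_count=int(rng.choice([0, 4, 6, 10])),
                    exon_distance=int(rng.choice([0, 2, 5, 6, 40])),
                )
            )
        occurrence = {c.locus: int(rng.choice([1, 5, 25])) for c in calls}
        verdicts = filter_tissue_variants(calls, 40, occurrence, cfg)
        for call, verdict in zip(calls, verdicts):
            a = call.annotations
            expected = (
                a.exon_distance <= 5
                and call.vaf > 0.05
                and (
                    a.clinvar_class in (ClinvarClass.PATHOGENIC, ClinvarClass.LIKELY_PATHOGENIC)
                    or (0.05 < call.vaf <= 0.98 and a.gnomad_max_pop_af < 0.01)
                )
                and a.local_cohort_germline_count <= 5
                and not (occurrence[call.locus] > 20 and a.cosmic_same_position_count < 5)
            )
            assert verdict.retained == expected, call

    def test_retention_monotone_in_vaf(self):
        """Within the working VAF band, raising VAF never loses retention."""
        for vaf in np.linspace(0.06, 0.98, 20):
            assert filter_tissue_variants([tissue_call(float(vaf), **PATHOGENIC)], 40, {})[0].retained


class TestOriginAndDriver:
    def test_lone_heterozygous_plp_is_undetermined(self):
        v = classify_origin(filter_tissue_variants([tissue_call(0.45, **PATHOGENIC)], 40, {}))
        assert v[0].origin == Origin.UNDETERMINED

    def test_companion_vaf_marks_somatic(self):
        calls = [tissue_call(0.45, **PATHOGENIC), tissue_call(0.40, pos=999, **PATHOGENIC)]
        v = classify_origin(filter_tissue_variants(calls, 40, {}))
        assert all(x.origin == Origin.SOMATIC for x in v)

    def test_low_vaf_is_somatic_by_default(self):
        v = classify_origin(filter_tissue_variants([tissue_call(0.20, **PATHOGENIC)], 40, {}))
        assert v[0].origin == Origin.SOMATIC

    def test_wbc_resolves_undetermined(self):
        verdicts = classify_origin(
            filter_tissue_variants([tissue_call(0.45, **PATHOGENIC)], 40, {})
        )
        wbc_het = [make_call(vaf=0.5, depth=1000, umi=(250, 250))]
        assert resolve_origin_with_wbc(verdicts, wbc_het)[0].origin == Origin.GERMLINE
        assert resolve_origin_with_wbc(verdicts, [])[0].origin == Origin.SOMATIC

    def test_wbc_overrides_companion_heuristic(self):
        calls = [tissue_call(0.45, **PATHOGENIC), tissue_call(0.40, pos=999, **PATHOGENIC)]
        verdicts = classify_origin(filter_tissue_variants(calls, 40, {}))
        wbc = [make_call(vaf=0.5, depth=1000, umi=(250, 250))]  # locus of the first call
        resolved = resolve_origin_with_wbc(verdicts, wbc)
        assert resolved[0].origin == Origin.GERMLINE
        assert resolved[1].origin == Origin.SOMATIC

    @pytest.mark.parametrize(
        "clinvar, cosmic, expected",
        [
            (ClinvarClass.PATHOGENIC, 0, True),
            (ClinvarClass.UNREPORTED, 5, True),
            (ClinvarClass.UNREPORTED, 4, False),
        ],
    )
    def test_driver_rule(self, clinvar, cosmic, expected):
        v = classify_origin(
            filter_tissue_variants(
                [tissue_call(0.30, clinvar_class=clinvar, cosmic_same_position_count=cosmic)],
                40, {},
            )
        )
        assert classify_driver(v[0]).driver is expected

    def test_germline_never_driver(self):
        verdicts = classify_origin(
            filter_tissue_variants([tissue_call(0.48, **PATHOGENIC)], 40, {})
        )
        wbc = [make_call(vaf=0.5, depth=1000, umi=(250, 250))]
        resolved = resolve_origin_with_wbc(verdicts, wbc)
        assert classify_driver(resolved[0]).driver is False


def test_planted_germline_with_wbc_is_recovered():
    """On a cohort where every participant has matched WBC, each planted
    germline variant is classified germline and none becomes a driver."""
    cohort = generate_cohort(
        GeneratorConfig(seed=13, wbc_available_rate=1.0, germline_mean_per_participant=1.5)
    )
    results = run_cohort(cohort.participants)
    germline_seen = 0
    for p in cohort.participants:
        germline_loci = {l for l, lab in (p.truth or {}).items() if lab == "germline"}
        drivers = set(results.tissue_drivers.get(p.id, []))
        assert not (germline_loci & drivers)
        for v in results.tissue_verdicts.get(p.id, []):
            if v.variant.locus in germline_loci and v.retained:
                germline_seen += 1
                if v.variant.annotations.clinvar_class == ClinvarClass.PATHOGENIC:
                    assert v.origin == Origin.GERMLINE
    assert germline_seen > 0
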