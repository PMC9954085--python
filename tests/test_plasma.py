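"""Plasma caller filters, tumour-informed approaches, blacklist, cascade."""

import itertools

import numpy as np

from ctdnapipe.config import DEFAULT_CONFIG
from ctdnapipe.core import ClinvarClass, GenomicLocus, Material, Timepoint, normalize_variant
from ctdnapipe.plasma import (
    Blacklist,
    apply_caller_pass_filters,
    approach_A,
    approach_B,
    approach_C,
    build_blacklist,
    retained_loci,
)

from .conftest import make_call

EMPTY_BLACKLIST = Blacklist(set())


class TestCallerPassFilters:
    def test_vaf_floor(self):
        assert apply_caller_pass_filters([make_call(vaf=0.0004, depth=10_000)]) == []

    def test_all_gates_pass(self):
        call = make_call(vaf=0.006, lod=5, umi=(2, 1), gnomad_max_pop_af=0.004)
        assert apply_caller_pass_filters([call]) == [call]

    def test_gnomad_ceiling(self):
        assert apply_caller_pass_filters([make_call(gnomad_max_pop_af=0.006)]) == []

    def test_lod_floor(self):
        assert apply_caller_pass_filters([make_call(lod=3.9)]) == []

    def test_umi_gate_only_for_umi_caller(self):
        weak = dict(vaf=0.006, umi=(3, 0))
        assert apply_caller_pass_filters([make_call(**weak)]) == []
        non_umi = make_call(vaf=0.006, caller="non_umi", umi=None)
        assert apply_caller_pass_filters([non_umi]) == [non_umi]


class TestTumourInformed:
    def test_intersection(self):
        drivers = [GenomicLocus("chr17", 7_577_120, "C", "T"),
                   GenomicLocus("chr12", 25_398_284, "C", "T")]
        calls = [make_call(), make_call(chrom="chr3", pos=500, ref="A", alt="G")]
        res = approach_A(drivers, calls, "P1")
        assert res.count == 1 and not res.na

    def test_no_drivers_is_na_never_zero(self):
        res = approach_A([], [make_call()], "P1")
        assert res.na and res.count is None and res.detected is None

    def test_b_equals_a_when_umi_gate_vacuous(self):
        drivers = [GenomicLocus("chr17", 7_577_120, "C", "T")]
        umi_calls = [make_call(umi=(3, 2))]
        non_umi = [make_call(caller="non_umi", umi=None)]
        a = approach_A(drivers, apply_caller_pass_filters(umi_calls), "P1")
        b = approach_B(drivers, apply_caller_pass_filters(non_umi), "P1")
        assert a.count == b.count == 1

    def test_b_empty_calls(self):
        assert approach_B([GenomicLocus("chr1", 5, "A", "T")], [], "P1").count == 0

    def test_binomial_sampling_detects_planted_driver(self):
        """VAF 0.6% at ~1300x leaves ~8 expected alt molecules, comfortably
        above the duplex support minimum in most draws."""
        rng = np.random.default_rng(3)
        locus = GenomicLocus("chr17", 7_577_120, "C", "T")
        hits = 0
        for _ in range(200):
            alt = rng.binomial(1300, 0.006)
            top = rng.binomial(alt, 0.5) if alt else 0
            call = make_call(vaf=alt / 1300, depth=1300, umi=(top, alt - top))
            passing = apply_caller_pass_filters([call])
            hits += bool(approach_A([locus], passing, "P1").count)
        assert hits / 200 > 0.8


class TestBlacklist:
    def _cohort(self, n_samples, cosmic):
        call = make_call(cosmic_same_position_count=cosmic)
        return {f"s{i}": [call] for i in range(n_samples)}

    def test_recurrent_artefact_listed(self):
        bl = build_blacklist(self._cohort(11, cosmic=0))
        assert len(bl.loci) == 1 and bl.provenance[next(iter(bl.loci))] == 11

    def test_cosmic_recurrent_exempt(self):
        assert build_blacklist(self._cohort(11, cosmic=7)).loci == set()

    def test_threshold_is_strict(self):
        assert build_blacklist(self._cohort(10, cosmic=0)).loci == set()

    def test_manual_override(self):
        locus = make_call().locus
        keep = build_blacklist(self._cohort(11, cosmic=7), manual_overrides={locus: True})
        assert locus in keep
        drop = build_blacklist(self._cohort(11, cosmic=0), manual_overrides={locus: False})
        assert locus not in drop


def _rand_call(rng, i, timept_vaf=None):
    return make_call(
        pos=10_000 + i,
        vaf=timept_vaf if timept_vaf is not None else float(rng.uniform(0.001, 0.6)),
        depth=int(rng.choice([80, 99, 100, 400, 1300])),
        umi=(5, 5),
        clinvar_class=rng.choice(
            [ClinvarClass.PATHOGENIC, ClinvarClass.UNREPORTED, ClinvarClass.BENIGN,
             ClinvarClass.LIKELY_BENIGN, ClinvarClass.VUS]
        ),
        clinvar_source_counts={},
        is_synonymous=bool(rng.random() < 0.3),
        cosmic_same_position_count=int(rng.choice([0, 6])),
        local_cohort_germline_count=int(rng.choice([0, 6])),
        exon_distance=int(rng.choice([0, 5, 6])),
    )


class TestCascade:
    def test_depth_floor(self):
        call = make_call(vaf=0.05, depth=99, umi=(3, 2))
        res = approach_C([call], EMPTY_BLACKLIST)
        assert res.count == 0 and res.audit[-1][1] == "depth"

    def test_verified_germline_band_both_samples(self):
        diag = make_call(vaf=0.47, depth=1000, umi=(200, 270))
        post = make_call(vaf=0.52, depth=1000, umi=(260, 260))
        res = approach_C([diag], EMPTY_BLACKLIST, paired_calls=[post])
        assert res.count == 0 and res.audit[-1][1] == "verified_germline"
        # one side outside the band -> kept
        post_out = make_call(vaf=0.60, depth=1000, umi=(300, 300))
        assert approach_C([diag], EMPTY_BLACKLIST, paired_calls=[post_out]).count == 1

    def test_post_only_variant_kept_if_hotspot_or_in_tissue(self):
        hot = make_call(vaf=0.01, depth=1000, umi=(5, 5), cosmic_same_position_count=9)
        res = approach_C([hot], EMPTY_BLACKLIST, timepoint="post", paired_calls=[])
        assert res.count == 1
        cold = make_call(vaf=0.01, depth=1000, umi=(5, 5))
        assert approach_C([cold], EMPTY_BLACKLIST, timepoint="post", paired_calls=[]).count == 0
        assert approach_C(
            [cold], EMPTY_BLACKLIST, timepoint="post", paired_calls=[],
            tissue_loci=[cold.locus],
        ).count == 1

    def test_benign_logic(self):
        syn_one_src = make_call(
            vaf=0.01, depth=1000, umi=(5, 5),
            clinvar_class=ClinvarClass.BENIGN, is_synonymous=True,
        )
        assert approach_C([syn_one_src], EMPTY_BLACKLIST).count == 0
        nonsyn_one_src = make_call(
            vaf=0.01, depth=1000, umi=(5, 5), clinvar_class=ClinvarClass.BENIGN
        )
        assert approach_C([nonsyn_one_src], EMPTY_BLACKLIST).count == 1
        multi_src = make_call(
            vaf=0.01, depth=1000, umi=(5, 5),
            clinvar_class=ClinvarClass.BENIGN,
            clinvar_source_counts={ClinvarClass.BENIGN: 1, ClinvarClass.LIKELY_BENIGN: 1},
        )
        assert approach_C([multi_src], EMPTY_BLACKLIST).count == 0

    def test_steps_skipped_without_paired_sample_and_audited(self):
        diag = make_call(vaf=0.47, depth=1000, umi=(200, 270))
        res = approach_C([diag], EMPTY_BLACKLIST, paired_calls=None)
        assert res.count == 1
        assert any("skipped" in step for _, step in res.audit)

    def test_final_membership_order_invariant(self):
        """Steps 1-5 are pure conjunctions: applying them in any order leaves
        the same final membership (checked by permuting single-step runs)."""
        rng = np.random.default_rng(2)
        calls = [_rand_call(rng, i) for i in range(120)]
        bl_locus = normalize_variant(calls[0].locus)
        blacklist = Blacklist({bl_locus})
        baseline = retained_loci(approach_C(calls, blacklist))
        cfg = DEFAULT_CONFIG

        def step_blacklist(cs):
            return [c for c in cs if normalize_variant(c.locus) not in blacklist.loci]

        def step_exon(cs):
            return [c for c in cs if c.annotations.exon_distance <= cfg.exon_distance_max]

        def step_depth(cs):
            return [c for c in cs if c.total_reads >= cfg.plasma_depth_floor]

        def step_benign(cs):
            out = []
            for c in cs:
                n = c.annotations.benign_source_count()
                if (n >= 1 and c.annotations.is_synonymous) or n >= 2:
                    continue
                out.append(c)
            return out

        def step_local(cs):
            return [c for c in cs if c.annotations.local_cohort_germline_count <= 5]

        steps = [step_blacklist, step_exon, step_depth, step_benign, step_local]
        for perm in itertools.islice(itertools.permutations(steps), 0, None, 17):
            cs = list(calls)
            for step in perm:
                cs = step(cs)
            assert {normalize_variant(c.locus) for c in cs} == baseline


def test_approach_a_subset_of_c_on_synthetic_cohort(default_cohort, default_results):
    """Tumour-informed hits are a subset of the tumour-agnostic retained set
    whenever no driver locus is blacklisted or below the depth floor."""
    res = default_results
    checked = 0
    for p in default_cohort.participants:
        try:
            a = res.callset(p.id, "A", "diagnostic")
            c = res.callset(p.id, "C", "diagnostic")
        except KeyError:
            continue
        if a.na or c.na:
            continue
        drivers = set(res.tissue_drivers.get(p.id, []))
        if any(loc in res.blacklist for loc in drivers):
            continue
        a_loci, c_loci = retained_loci(a), retained_loci(c)
        diag = p.sample(Material.PLASMA, Timepoint.DIAGNOSTIC)
        post = p.sample(Material.PLASMA, Timepoint.POST_SURGERY)
        post_vaf = {normalize_variant(x.locus): x.vaf for x in (post.calls if post else [])}
        for loc in a_loci:
            call = next(
                x for x in diag.calls if normalize_variant(x.locus) == loc
            )
            if call.total_reads < 100:
                continue
            # the verified-germline step may legitimately remove a driver
            # sitting at heterozygous VAF in both samples
            if 0.40 <= call.vaf <= 0.55 and 0.40 <= post_vaf.get(loc, -1) <= 0.55:
                continue
            assert loc in c_loci
            checked += 1
    assert checked > 0


def test_blacklist_plus_cascade_remove_planted_artefacts(default_cohort, default_results):
    """Artefact loci planted in more than the threshold number of samples are
    overwhelmingly removed by blacklist + cascade."""
    artefacts = set(default_cohort.artefact_loci)
    surviving = set()
    for cs in default_results.callsets:
        if cs.approach == "C" and not cs.na:
            surviving |= artefacts & retained_loci(cs)
    removed_fraction = 1 - len(surviving) / len(artefacts)
    assert removed_fraction >= 0.8
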