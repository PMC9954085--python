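# Methods

## Scope and data model

The package implements a post-calling analysis layer: it consumes annotated
variant calls (VCF or in-memory `VariantCall` lists) for tissue, plasma and
WBC specimens and produces filtered call sets, per-participant detection
calls, cohort detection rates, ddPCR quantifications and survival
comparisons. It does not align reads, call variants, or compute annotations;
ClinVar class and source counts, gnomAD frequencies, COSMIC same-position
counts, local-cohort germline counts and exon distances are inputs.

Variant identity is the left-normalized `(chrom, pos, ref, alt)` tuple,
1-based and VCF-anchored. Normalization trims shared trailing bases, then
shared leading bases (advancing the position), leaving at least one base per
allele — the standard parsimony convention, and the only unambiguous way to
match tissue variants in plasma when the two call sets render an indel
differently. Gene symbols are annotation only and never part of identity.
VAFs are fractions in [0, 1] everywhere inside the package; percent
thresholds are converted once at the `RunConfig` boundary.

## Filtering rules and their thresholds

All thresholds live in `RunConfig` with the study defaults; any override is
echoed in run logs.

| parameter | default | meaning |
|---|---|---|
| `tissue_vaf_floor` | 0.05 (strict >) | tissue retention floor |
| `tissue_vaf_ceiling` | 0.98 | gnomAD branch only |
| `exon_distance_max` | 5 bp | exon/splice window |
| `gnomad_tissue_max` / `gnomad_plasma_max` | 0.01 / 0.005 | population-frequency gates |
| `local_cohort_max` | 5 | local germline occurrence cap |
| `cosmic_hotspot_min` | 5 | same-position cases for driver/hotspot status |
| `caller_vaf_floor` / `caller_lod_floor` | 0.0005 / 4 | caller pass thresholds |
| `umi_min_total`, `umi_min_per_strand` | 3, 1 | duplex family gate (min_reads 3,1,1) |
| `blacklist_recurrence_threshold` | 10 (strict >) | artefact recurrence |
| `plasma_depth_floor` | 100 reads | tumour-agnostic depth gate |
| `germline_plasma_band` | [0.40, 0.55] | verified-germline band in paired plasma |
| `wbc_read_threshold` / `wbc_vaf_threshold` | 4 (strict >) / 0.0005 | WBC CH evidence |
| `wbc_germline_band` | [0.40, 0.60] | WBC heterozygous band |
| `paired_plasma_ratio` | 4 | quarter rule for paired-plasma CH |
| `droplet_volume_nl` | 0.85 | QX200 nominal droplet volume |

Decisions taken where the published description leaves latitude:

- **Tissue VAF floor is strict** (> 5%), with the 98% ceiling applying only
  to the gnomAD branch, mirroring the sentence structure of the source
  protocol; both are configurable.
- **"Similar VAF"** for the somatic-companion heuristic is ±10 percentage
  points. The heuristic is deliberately weak evidence: matched WBC data
  overrides it in both directions (a heterozygous-band WBC VAF reclassifies
  a companion-called "somatic" P/LP variant as germline), because direct
  germline DNA evidence trumps co-occurrence circumstantials. The
  phenotype-consistency escape hatch is a per-locus manual override, not
  automated.
- **"COSMIC-recurrent"** reuses the ≥ 5 same-position threshold wherever a
  hotspot exemption is needed (blacklist, post-only rescue, cohort
  recurrence), avoiding a second invented constant.
- **ClinVar "multiple sources"** means a summed benign/likely-benign
  submitter count ≥ 2.
- **Blacklist review**: the manual IGV inspection step is replaced by the
  automatic COSMIC exemption plus an optional per-locus override mapping.
- **WBC VAF threshold**: 0.05% is the operative default; the alternative
  published reading of 0.5% ships as `wbc_vaf_threshold_alt` rather than
  being silently chosen.
- **WBC precedence**: when both WBC and a paired plasma sample exist, WBC is
  used; the paired-plasma quarter rule is strictly a fallback.
- **Approach E** (non-UMI calls + WBC filtering) raises a documented
  not-supported error: without UMI error suppression no robust read/VAF
  threshold separates CH from tumour signal.
- The cascade's final membership for the pure-conjunction steps is
  order-invariant (property-tested under permutation); only the audit trail
  depends on order.

## ddPCR quantification

Replicate wells are merged by **pooling droplet counts before** the Poisson
inversion λ = −ln(1 − p)/v — the exact treatment, not a mean of per-well
estimates. Confidence intervals are Wilson score intervals on the
positive-droplet fraction pushed through the (monotone) inversion; Wilson is
stable at zero counts, where the interval collapses to [0, upper). A fully
positive plate raises a saturation error advising dilution instead of
returning an unbounded estimate. Positivity uses concentration CIs (not VAF
CIs), matching how the overlapping-error-bar footnotes in the bundled ddPCR
table are expressed. For summarised inputs (printed VAF, assay FPR,
CI-overlap flag) the same rule is exposed as `call_positive_from_summary`.

## Bundled cohort tables

Three TSV fixtures ship with the package (checksummed at load): the
47-participant clinical table (stage, overall survival, censoring), the
per-participant detection table for approaches A–D at the diagnostic and
post-surgical timepoints with plasma volumes and cfDNA masses, and the
longitudinal per-target ddPCR table. Values are verbatim, including the
250 ng cfDNA-mass cap imposed by the library-prep input limit — because of
that cap, post/diagnostic concentration ratios computed from the detection
table are lower bounds, and the cohort median ratio from it understates the
true post-surgical rise; ratio statistics on capped data are therefore not
used as reference quantities. One further known quirk: one post-surgical
ddPCR row prints a VAF above a zero FPR yet a negative per-variant call with
no footnote; the positivity rule disagrees with that single per-variant
entry but reproduces all per-participant calls.

Detection-rate denominators are generated by prerequisite logic, not
hard-coded: tumour-informed rates count participants with tissue drivers and
a sequenced sample at the timepoint; tumour-agnostic rates count sequenced
samples, with an unfilterable approach-D row (no WBC, no paired sample)
counted in the denominator as not-detected — this reproduces the published
23/44 convention. The CH-filterable count (43 at diagnosis) is exposed
separately.

## Synthetic cohort generator

The generator emulates the study conditions so that every filter has
something real to act on:

- 47 participants, 31/47 tissue-positive, 1 + Poisson(2.2) driver variants
  each, tissue VAFs log-uniform on [0.05, 0.90] (median ≈ 0.21);
- plasma UMI-collapsed depth log-normal, median 1309×, truncated to
  [143, 4533];
- 55% of tissue-positive participants shed ctDNA; the participant-level
  plasma VAF anchor is log-normal with median 0.006 truncated to
  [0.0007, 0.17]. (A log-uniform law over that range would put the median at
  ≈ 0.011; the truncated log-normal honours both the observed range and the
  observed median, so it is used instead.) Per-variant plasma VAF scales
  with tissue clonality; alt reads are binomial in depth × VAF with a
  fair-coin strand split;
- total cfDNA concentration rises post-surgery by a per-participant
  log-normal factor around 3.6; tumour-derived VAFs are divided accordingly
  while CH VAFs are left untouched — the asymmetry the quarter rule exploits.
  Residual disease (18% of shedders) is planted at one tenth of the
  diagnostic VAF: the boundary analysis (dilution 3.6 vs quarter-rule 4)
  shows the published cutoff is intentionally permissive, so residual
  fixtures are placed clearly below it, and the generator refuses margins
  below the dilution factor;
- CH variants (Poisson(0.4) per participant, clone VAFs log-uniform on
  [0.005, 0.05]) appear in plasma at both timepoints and in WBC; germline
  variants sit at N(0.5, 0.03) everywhere; WBC calls never contain
  tumour-only variants;
- WBC calls carry **expected** (rounded) consensus counts rather than a
  binomial draw: the WBC sample is the deep, high-input reference material,
  and representing it deterministically is what makes WBC-based CH recovery
  exact at the planted clone sizes. Plasma remains fully stochastic.
  P/LP-class germline variants are only planted for participants with WBC
  data, emulating confirmatory blood testing of suspected pathogenic
  germline findings;
- 25 artefact loci each recur in 11–30 plasma samples (systematically, with
  a minimum alt-read floor) so the blacklist has true targets;
- sample dropout follows the study: diagnostic failure 3/47, missing
  post-surgical sample 2/47, WBC available 21/47;
- survival is exponential with hazard ratio 2.5 for shedders over a
  4.5-year baseline median, censored uniformly over 5.5 years; progression
  events use a 1.5× hazard multiplier.

What the generator does **not** model: sequencing error as a per-base
process (errors enter only as recurrent artefact loci and as the toy
tagged-read simulation used for consensus tests), UMI family-size
distributions in plasma (calls arrive at family-count granularity),
tumour-fraction dynamics over multiple follow-ups, age-dependent CH
incidence, and real panel footprints (loci are placed in a toy 14-gene
panel). Passing tests on synthetic cohorts therefore demonstrate the
correctness and calibration of the *rules*, not the clinical performance of
the assay on real cfDNA.

## Numerical and statistical choices

- Survival estimation is delegated to lifelines: Kaplan–Meier product-limit
  (deaths before censorings at ties), Mantel–Haenszel log-rank with
  two-sided chi-square p, Cox partial likelihood with Efron tie handling and
  Wald intervals. A group with no events yields a flagged "unbounded" hazard
  ratio rather than a number. No multiple-testing correction is applied.
- Consensus-family ties vote for the reference allele, so noise can never
  manufacture alt support; families are keyed by (UMI tag, start, strand),
  duplex pairing by shared tag.
- Degenerate ddPCR inputs: zero template in both channels reports VAF 0 with
  a no-template flag; the Wilson upper bound is clipped below 1 to keep the
  inversion finite.

## Problem sizes

The test suite and the acceptance script run the cohort aggregation on the
bundled 47-participant tables, rule oracles on 1000 random variants, CH and
detection recovery pooled over 20 seeded 47-participant cohorts, log-rank
calibration on 1000 two-group replicates of n = 30 + 30, Cox recovery on
n = 500 (averaged over 20 fits in the acceptance report), and ddPCR
Monte-Carlo recovery on 100 × 20 000 droplets. The full suite completes in
well under a minute of compute on a single CPU, the acceptance script in
about fifteen seconds.

## Known limitations

- Exact reproduction of the published survival p-values is out of reach from
  printed data (borderline group membership is not fully determinable), so
  the survival machinery is validated by hand-computed oracles and
  simulation instead; the CLI `survival` command runs the comparison on the
  bundled tables for inspection.
- Multi-allelic VCF records are split on read, but complex/overlapping
  representations beyond parsimony trimming (true left-alignment against a
  reference genome) are not resolved.
- The per-stage detection breakdown is implemented but its published
  stage-group denominators cannot be reconciled with the bundled staging
  labels, so it is reported without reference values.
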