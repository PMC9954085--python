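import pytest

from ctdnapipe.core import (
    AnnotationBundle,
    Caller,
    ClinvarClass,
    GenomicLocus,
    UmiSupport,
    VariantCall,
)
from ctdnapipe.pipeline import run_cohort
from ctdnapipe.simulate import GeneratorConfig, generate_cohort


def make_call(
    chrom="chr17",
    pos=7_577_120,
    ref="C",
    alt="T",
    gene="TP53",
    vaf=0.01,
    depth=1300,
    lod=10.0,
    caller=Caller.UMI_CONSENSUS,
    umi=(3, 2),
    **ann_kwargs,
):
    """Small builder for a plausible plasma/tissue call."""
    alt_reads = max(0, round(vaf * depth))
    caller = Caller(caller)
    return VariantCall(
        GenomicLocus(chrom, pos, ref, alt),
        gene=gene,
        vaf=alt_reads / depth if depth else 0.0,
        alt_reads=alt_reads,
        total_reads=depth,
        quality_lod=lod,
        caller=caller,
        umi_support=UmiSupport(*umi) if umi is not None else None,
        annotations=AnnotationBundle(**ann_kwargs),
    )


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def default_results(default_cohort):
    return run_cohort(default_cohort.participants)


@pytest.fixture(scope="session")
def multi_seed_runs():
    """Twenty generated cohorts with full pipeline results, shared across the
    property tests that pool over seeds."""
    runs = []
    for seed in range(20):
        cohort = generate_cohort(GeneratorConfig(seed=seed))
        runs.append((cohort, run_cohort(cohort.participants)))
    return runs


PATHOGENIC = dict(
    clinvar_class=ClinvarClass.PATHOGENIC,
    clinvar_source_counts={ClinvarClass.PATHOGENIC: 2},
)
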