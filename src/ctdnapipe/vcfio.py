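"""VCF 4.2 reading and writing for variant call lists (pysam-backed).

The annotation bundle rides in INFO fields: CLNSIG, CLNSIG_SRC, SYN,
GNOMAD_MAX_AF, GNOMAD_AF, COSMIC_CNT, LOCAL_GERMLINE_CNT, EXON_DIST, plus
call-level VAF, ALT_READS, DP, LOD, CALLER, UMI_TOP, UMI_BOT and GENE.
Multi-allelic records are split into biallelic calls on read; writing always
emits biallelic records.  INFO floats travel at float32 precision (an htslib
constraint), so the reader shortens them to their decimal representation and
reconstructs the VAF exactly from ALT_READS/DP when consistent, which makes a
write-read round trip lossless for all modelled fields.
"""

from __future__ import annotations

from typing import Optional, Sequence

import pysam

from .core import (
    AnnotationBundle,
    Caller,
    ClinvarClass,
    GenomicLocus,
    UmiSupport,
    ValidationError,
    VariantCall,
)

_PER_ALLELE = [
    ("VAF", "Float", "Variant allele fraction"),
    ("ALT_READS", "Integer", "Reads supporting the alt allele"),
    ("UMI_TOP", "Integer", "Alt consensus UMI families, top strand"),
    ("UMI_BOT", "Integer", "Alt consensus UMI families, bottom strand"),
]
_SHARED = [
    ("DP", "Integer", "Total read depth"),
    ("LOD", "Float", "Caller log-odds score"),
    ("CALLER", "String", "umi_consensus or non_umi"),
    ("GENE", "String", "Gene symbol"),
    ("CLNSIG", "String", "ClinVar class"),
    ("CLNSIG_SRC", "String", "Per-class ClinVar source counts, class:n comma-joined"),
    ("SYN", "Integer", "1 if synonymous"),
    ("GNOMAD_MAX_AF", "Float", "Max gnomAD population allele frequency"),
    ("GNOMAD_AF", "Float", "Overall gnomAD allele frequency"),
    ("COSMIC_CNT", "Integer", "COSMIC same-position case count"),
    ("LOCAL_GERMLINE_CNT", "Integer", "Local cohort germline occurrence count"),
    ("EXON_DIST", "Integer", "Distance from nearest exon boundary (bp)"),
]
_MANDATORY = ("VAF", "ALT_READS", "DP", "LOD")


def _build_header(calls: Sequence[VariantCall]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, typ, desc in _PER_ALLELE:
        header.info.add(name, "A", typ, desc)
    for name, typ, desc in _SHARED:
        header.info.add(name, 1, typ, desc)
    for chrom in dict.fromkeys(c.locus.chrom for c in calls):
        header.contigs.add(chrom)
    return header


def write_vcf(calls: Sequence[VariantCall], path: str) -> None:
    """Write calls as an uncompressed biallelic VCF 4.2."""
    header = _build_header(calls)
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for call in sorted(calls, key=lambda c: (c.locus.chrom, c.locus.pos)):
            ann = call.annotations
            rec = vcf.new_record(
                contig=call.locus.chrom,
                start=call.locus.pos - 1,
                alleles=(call.locus.ref, call.locus.alt),
            )
            rec.info["VAF"] = (call.vaf,)
            rec.info["ALT_READS"] = (call.alt_reads,)
            rec.info["DP"] = call.total_reads
            rec.info["LOD"] = call.quality_lod
            rec.info["CALLER"] = call.caller.value
            rec.info["GENE"] = call.gene or "."
            rec.info["CLNSIG"] = ann.clinvar_class.value
            if ann.clinvar_source_counts:
                rec.info["CLNSIG_SRC"] = ",".join(
                    f"{ClinvarClass(cls).value}:{n}"
                    for cls, n in sorted(
                        ann.clinvar_source_counts.items(), key=lambda kv: ClinvarClass(kv[0]).value
                    )
                )
            rec.info["SYN"] = int(ann.is_synonymous)
            rec.info["GNOMAD_MAX_AF"] = ann.gnomad_max_pop_af
            rec.info["GNOMAD_AF"] = ann.gnomad_overall_af
            rec.info["COSMIC_CNT"] = ann.cosmic_same_position_count
            rec.info["LOCAL_GERMLINE_CNT"] = ann.local_cohort_germline_count
            rec.info["EXON_DIST"] = ann.exon_distance
            if call.umi_support is not None:
                rec.info["UMI_TOP"] = (call.umi_support.families_top_strand,)
                rec.info["UMI_BOT"] = (call.umi_support.families_bottom_strand,)
            vcf.write(rec)


def _f32(x: float) -> float:
    """Shortest decimal value consistent with the float32 INFO encoding."""
    return float(f"{x:.6g}")


def _parse_src_counts(raw: Optional[str]) -> dict[ClinvarClass, int]:
    if not raw:
        return {}
    out = {}
    for item in raw.split(","):
        cls, n = item.rsplit(":", 1)
        out[ClinvarClass(cls)] = int(n)
    return out


def read_vcf(path: str) -> list[VariantCall]:
    """Read a VCF with the package INFO contract; multi-allelic records are
    split into one biallelic call per alt allele."""
    calls = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            info = dict(rec.info)
            missing = [k for k in _MANDATORY if k not in info]
            if missing:
                raise ValidationError(
                    f"{path}: record {rec.contig}:{rec.pos} missing INFO keys {missing}"
                )
            ann = AnnotationBundle(
                clinvar_class=ClinvarClass(info.get("CLNSIG", "unreported")),
                clinvar_source_counts=_parse_src_counts(info.get("CLNSIG_SRC")),
                is_synonymous=bool(info.get("SYN", 0)),
                gnomad_max_pop_af=_f32(info.get("GNOMAD_MAX_AF", 0.0)),
                gnomad_overall_af=_f32(info.get("GNOMAD_AF", 0.0)),
                cosmic_same_position_count=int(info.get("COSMIC_CNT", 0)),
                local_cohort_germline_count=int(info.get("LOCAL_GERMLINE_CNT", 0)),
                exon_distance=int(info.get("EXON_DIST", 0)),
            )
            caller = Caller(info.get("CALLER", "umi_consensus"))
            gene = info.get("GENE", ".")
            vafs = info["VAF"]
            alt_reads = info["ALT_READS"]
            umi_top = info.get("UMI_TOP")
            umi_bot = info.get("UMI_BOT")
            depth = int(info["DP"])
            for i, alt in enumerate(rec.alts or ()):
                support = None
                if umi_top is not None and umi_bot is not None:
                    support = UmiSupport(int(umi_top[i]), int(umi_bot[i]))
                vaf = _f32(vafs[i])
                exact = int(alt_reads[i]) / depth if depth else 0.0
                if abs(vaf - exact) < 1e-6:
                    vaf = exact
                calls.append(
                    VariantCall(
                        GenomicLocus(rec.contig, rec.pos, rec.ref, alt),
                        gene="" if gene == "." else gene,
                        vaf=vaf,
                        alt_reads=int(alt_reads[i]),
                        total_reads=depth,
                        quality_lod=_f32(info["LOD"]),
                        caller=caller,
                        umi_support=support,
                        annotations=ann,
                    )
                )
    return calls
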