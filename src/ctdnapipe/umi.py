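"""Duplex-UMI family support: the min_reads 3,1,1 gate and toy-scale consensus.

A consensus family is the set of reads sharing (UMI tag, alignment start,
strand orientation) — a single-strand consensus read.  The duplex pair is the
two families sharing a tag across strands.  The default support gate requires
at least 3 families in total with at least 1 on each strand, which suppresses
PCR/sequencing errors confined to single reads or single strands.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping

from .core import UmiSupport, ValidationError

TOP = "top"
BOTTOM = "bottom"


def passes_umi_support(
    support: UmiSupport, min_total: int = 3, min_per_strand: int = 1
) -> bool:
    """True iff family counts satisfy the (min_total, per-strand) rule.

    Monotone: adding a family to either strand never turns a pass into a fail.
    """
    top, bottom = support.families_top_strand, support.families_bottom_strand
    if top < 0 or bottom < 0:
        raise ValidationError("negative UMI family counts")
    return (
        top + bottom >= min_total
        and top >= min_per_strand
        and bottom >= min_per_strand
    )


@dataclass(frozen=True)
class TaggedRead:
    """A raw read at consensus-calling granularity."""

    umi_tag: str
    strand: str  # "top" | "bottom"
    start: int
    allele: str


def collapse_families(
    tagged_reads: Iterable[TaggedRead | tuple], ref_allele: str
) -> Mapping[str, UmiSupport]:
    """Group reads into consensus families and count per-allele strand support.

    Each family (umi_tag, start, strand) votes one consensus allele by
    majority; ties resolve to the reference allele so that noise can never
    manufacture alt support.  Returns per-allele UmiSupport (the reference
    allele itself is included in the map when families vote for it).
    """
    families: dict[tuple[str, int, str], list[str]] = defaultdict(list)
    for read in tagged_reads:
        if not isinstance(read, TaggedRead):
            read = TaggedRead(*read)
        if read.strand not in (TOP, BOTTOM):
            raise ValidationError(f"strand must be 'top' or 'bottom', got {read.strand!r}")
        families[(read.umi_tag, read.start, read.strand)].append(read.allele)

    strand_counts: dict[str, Counter] = defaultdict(Counter)
    for (_, _, strand), alleles in families.items():
        counts = Counter(alleles)
        best = max(counts.values())
        winners = {a for a, n in counts.items() if n == best}
        consensus = ref_allele if ref_allele in winners or len(winners) > 1 else winners.pop()
        strand_counts[consensus][strand] += 1

    return {
        allele: UmiSupport(by_strand[TOP], by_strand[BOTTOM])
        for allele, by_strand in strand_counts.items()
    }
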