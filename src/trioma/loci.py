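"""Orientation classification of lncRNA loci relative to coding genes.

Each lncRNA locus falls into one of four classes with respect to its nearest
qualifying coding gene:

* ``antisense_overlap`` / ``sense_overlap`` — the locus shares >=1 base with
  the gene's transcript span (or its promoter) on the opposite / same strand;
* ``bidirectional`` — no overlap, but head-to-head divergent with a coding
  gene on the opposite strand whose TSS lies within a window (default
  1000 bp) of the lncRNA's TSS;
* ``intergenic`` — everything else.

Overlap classes additionally carry a sub-region label (promoter, exon,
intron, first_intron, intron_exon, three_prime_UTR) describing which part of
the gene the locus touches.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .data import GeneModel, LncLocus

__all__ = ["LocusRelation", "classify_locus", "associate_lnc_genes"]

CATEGORIES = ("antisense_overlap", "sense_overlap", "bidirectional", "intergenic")


@dataclass(frozen=True)
class LocusRelation:
    lnc_id: str
    gene_id: str  # empty for intergenic
    category: str
    subregion: str  # none for bidirectional/intergenic
    distance_bp: int  # 0 for overlaps; TSS gap for bidirectional

    def __post_init__(self) -> None:
        if self.category == "intergenic" and (self.gene_id or self.subregion != "none"):
            raise ValueError("intergenic relation cannot carry a gene or subregion")


def _span_overlap(a0: int, a1: int, b0: int, b1: int) -> bool:
    return a0 < b1 and b0 < a1


def _subregion(lnc: LncLocus, gene: GeneModel, promoter_bp: int) -> str:
    prom = gene.promoter(promoter_bp)
    in_prom = _span_overlap(lnc.start, lnc.end, *prom)
    in_tx = _span_overlap(lnc.start, lnc.end, gene.start, gene.end)
    if in_prom and not in_tx:
        return "promoter"
    if gene.utr3 is not None and _span_overlap(lnc.start, lnc.end, *gene.utr3):
        # confined to the 3'UTR?
        if lnc.start >= gene.utr3[0] and lnc.end <= gene.utr3[1]:
            return "three_prime_UTR"
    introns = gene.introns
    hit_exon = any(_span_overlap(lnc.start, lnc.end, s, e) for s, e in gene.exons)
    hit_introns = [i for i, (s, e) in enumerate(introns)
                   if _span_overlap(lnc.start, lnc.end, s, e)]
    if hit_exon and hit_introns:
        return "intron_exon"
    if hit_exon:
        return "exon"
    if hit_introns:
        return "first_intron" if hit_introns == [0] else "intron"
    return "exon" if not gene.exons else "intron"


def _tss_gap(a: int, b: int) -> int:
    """Bases strictly between two TSS positions."""
    return max(0, abs(a - b) - 1)


def classify_locus(
    lnc: LncLocus,
    genes: list[GeneModel],
    window: int = 1000,
    promoter_bp: int = 1000,
) -> LocusRelation:
    """Assign one lncRNA locus its orientation class and sub-region.

    The nearest qualifying gene wins; ties break on the smaller gene id.
    Rule order: transcript overlap, then head-to-head bidirectional, then
    promoter-only overlap, else intergenic — so a divergent lncRNA sitting
    upstream of a gene is bidirectional, not a promoter overlap.
    """
    # 1) overlap with the transcript span
    overlap_hits = [
        g
        for g in genes
        if g.chrom == lnc.chrom
        and _span_overlap(lnc.start, lnc.end, g.start, g.end)
    ]
    if overlap_hits:
        gene = min(overlap_hits, key=lambda g: (_tss_gap(lnc.tss, g.tss), g.gene_id))
        category = "sense_overlap" if gene.strand == lnc.strand else "antisense_overlap"
        return LocusRelation(
            lnc_id=lnc.lnc_id,
            gene_id=gene.gene_id,
            category=category,
            subregion=_subregion(lnc, gene, promoter_bp),
            distance_bp=0,
        )
    # 2) head-to-head divergent within the window, opposite strands, no overlap
    bidir_hits = []
    for g in genes:
        if g.chrom != lnc.chrom or g.strand == lnc.strand:
            continue
        divergent = (
            (lnc.strand == "-" and g.strand == "+" and lnc.tss < g.tss)
            or (lnc.strand == "+" and g.strand == "-" and g.tss < lnc.tss)
        )
        gap = _tss_gap(lnc.tss, g.tss)
        if divergent and gap <= window:
            bidir_hits.append((gap, g))
    if bidir_hits:
        gap, gene = min(bidir_hits, key=lambda t: (t[0], t[1].gene_id))
        return LocusRelation(
            lnc_id=lnc.lnc_id,
            gene_id=gene.gene_id,
            category="bidirectional",
            subregion="none",
            distance_bp=gap,
        )
    # 3) promoter-only overlap (no transcript overlap, not divergent-qualifying)
    prom_hits = [
        g
        for g in genes
        if g.chrom == lnc.chrom
        and _span_overlap(lnc.start, lnc.end, *g.promoter(promoter_bp))
    ]
    if prom_hits:
        gene = min(prom_hits, key=lambda g: (_tss_gap(lnc.tss, g.tss), g.gene_id))
        category = "sense_overlap" if gene.strand == lnc.strand else "antisense_overlap"
        return LocusRelation(
            lnc_id=lnc.lnc_id,
            gene_id=gene.gene_id,
            category=category,
            subregion="promoter",
            distance_bp=0,
        )
    return LocusRelation(lnc.lnc_id, "", "intergenic", "none", 0)


def associate_lnc_genes(
    relations: list[LocusRelation],
    subset: set[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Gene<->lncRNA association table plus a category census.

    The census reports the percentage of each orientation class over
    ``subset`` (lnc ids; default all), rounded to 1 dp.
    """
    assoc = pd.DataFrame(
        [
            {
                "gene": r.gene_id,
                "lnc_id": r.lnc_id,
                "category": r.category,
                "subregion": r.subregion,
                "distance_bp": r.distance_bp,
            }
            for r in relations
            if r.category != "intergenic"
        ],
        columns=["gene", "lnc_id", "category", "subregion", "distance_bp"],
    )
    pool = [r for r in relations if subset is None or r.lnc_id in subset]
    census: dict[str, float] = {}
    if pool:
        counts = Counter(r.category for r in pool)
        census = {
            cat: round(100.0 * counts.get(cat, 0) / len(pool), 1) for cat in CATEGORIES
        }
    return assoc, census
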