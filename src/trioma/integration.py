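"""The gene-shortlisting cascade and the integrated regulatory network.

Stages, each a pure set operation on the outputs of the upstream modules:

1. genes whose mRNA is differentially expressed AND which carry >=1
   differentially expressed associated lncRNA (dual-DE shortlist);
2. hypergeometric / EASE pathway enrichment of the shortlist;
3. intersection with the predicted targets of the differentially expressed
   miRNAs;
4. the mature-phenotype filter (|SLR| above the cut on both late days);
5. miRNAs targeting >= k of the eligible genes;
6. assembly of the typed mRNA-lncRNA-miRNA network.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import networkx as nx
from scipy.stats import hypergeom

from .data import GeneSetCollection, SLRMatrix, TargetTable
from .differential import DifferentialCall
from .loci import LocusRelation
from .relationship import INCONCLUSIVE, PairRelationship

__all__ = [
    "EnrichmentResult",
    "shortlist_dual_de",
    "enrich_pathways",
    "intersect_mirna_targets",
    "mature_phenotype_filter",
    "map_mirnas_min_genes",
    "build_network",
    "network_to_json",
    "summary_report",
]


def shortlist_dual_de(
    mrna_calls: list[DifferentialCall],
    lnc_calls: list[DifferentialCall],
    mrna_gene_of: dict[str, str],
    lnc_associations: list[LocusRelation],
) -> list[str]:
    """Genes with a DE mRNA probe and >=1 associated DE lncRNA.

    ``mrna_gene_of`` maps mRNA probe id -> gene symbol;
    ``lnc_associations`` link lncRNA ids (probe ids) to genes.
    """
    de_genes = {
        mrna_gene_of[c.probe_id]
        for c in mrna_calls
        if c.is_de and c.probe_id in mrna_gene_of
    }
    de_lnc = {c.probe_id for c in lnc_calls if c.is_de}
    genes_with_de_lnc = {
        rel.gene_id
        for rel in lnc_associations
        if rel.gene_id and rel.lnc_id in de_lnc
    }
    return sorted(de_genes & genes_with_de_lnc)


@dataclass(frozen=True)
class EnrichmentResult:
    name: str
    overlap: int
    list_size: int
    set_size: int
    universe_size: int
    p: float

    def __post_init__(self) -> None:
        if self.overlap > min(self.list_size, self.set_size):
            raise ValueError("overlap exceeds list or set size")
        if not 0 < self.p <= 1:
            raise ValueError("p must be in (0, 1]")


def enrich_pathways(
    gene_list: list[str] | set[str],
    sets: GeneSetCollection,
    method: str = "ease",
) -> list[EnrichmentResult]:
    """One-sided hypergeometric upper-tail enrichment of ``gene_list``.

    ``method="fisher"`` is the plain tail P(X >= overlap); ``"ease"`` is the
    conservative variant that removes one success from the overlap first
    (floored at 0, so an empty overlap scores p = 1).  Results sorted by p.
    """
    if not sets.universe:
        raise ValueError("empty universe")
    genes = set(gene_list) & sets.universe
    if set(gene_list) - sets.universe:
        raise ValueError("gene list contains genes outside the universe: "
                         f"{sorted(set(gene_list) - sets.universe)}")
    N = len(sets.universe)
    n = len(genes)
    results = []
    for name, members in sets.sets.items():
        K = len(members)
        k = len(genes & members)
        if method == "fisher":
            k_eff = k
        elif method == "ease":
            k_eff = max(0, k - 1)
        else:
            raise ValueError("method must be 'fisher' or 'ease'")
        # P(X >= k_eff) for X ~ Hypergeom(N, K, n)
        p = float(hypergeom.sf(k_eff - 1, N, K, n))
        p = min(1.0, max(p, 5e-324))
        results.append(EnrichmentResult(name, k, n, K, N, p))
    return sorted(results, key=lambda r: (r.p, r.name))


def intersect_mirna_targets(
    gene_list: list[str] | set[str],
    targets: TargetTable,
    de_mirnas: set[str],
) -> list[str]:
    """Genes from ``gene_list`` targeted by >=1 differentially expressed miRNA."""
    hit = {
        row.gene
        for row in targets.rows.itertuples()
        if row.mirna in de_mirnas
    }
    return sorted(set(gene_list) & hit)


def mature_phenotype_filter(
    gene_subset: list[str] | set[str],
    mrna_slr: SLRMatrix,
    gene_of: dict[str, str],
    days: tuple[float, float] = (6.0, 8.0),
    cut: float = 1.0,
    mode: str = "both",
) -> list[str]:
    """Keep genes differentially expressed on the late maturation days.

    ``mode="both"`` requires |SLR| > cut on every listed day (default: days
    6 and 8); ``"either"`` requires it on at least one.
    """
    sample_of_day = {t: s for s, t in mrna_slr.design.timepoints.items()}
    try:
        cols = [sample_of_day[d] for d in days]
    except KeyError as exc:
        raise ValueError(f"day {exc.args[0]} missing from SLR matrix") from exc
    kept = set()
    for probe_id, row in mrna_slr.data.iterrows():
        gene = gene_of.get(str(probe_id))
        if gene not in set(gene_subset):
            continue
        hits = [abs(float(row[c])) > cut for c in cols]
        ok = all(hits) if mode == "both" else any(hits)
        if ok:
            kept.add(gene)
    return sorted(kept)


def map_mirnas_min_genes(
    eligible: list[str] | set[str],
    targets: TargetTable,
    k: int = 2,
) -> list[str]:
    """miRNAs whose target rows cover >= k distinct eligible genes."""
    eligible = set(eligible)
    return sorted(
        m for m in targets.mirnas if len(targets.genes_of(m) & eligible) >= k
    )


def build_network(
    eligible: list[str],
    pair_labels: list[PairRelationship],
    relations: list[LocusRelation],
    targets: TargetTable,
    mirnas: list[str],
    directions: dict[str, str] | None = None,
) -> nx.MultiDiGraph:
    """Assemble the typed mRNA-lncRNA-miRNA regulatory network.

    Nodes are typed mRNA / lncRNA / miRNA; edges are association
    (sense|antisense|bidirectional, lncRNA->gene), relationship
    (synergistic|inverse, lncRNA->gene) and targeting (predicted|validated,
    miRNA->gene).  ``directions`` optionally annotates nodes with an
    expression direction (up/down) per the profiling.
    """
    directions = directions or {}
    g = nx.MultiDiGraph()
    eligible = list(eligible)
    orientation_of = {r.lnc_id: r for r in relations if r.gene_id}
    for gene in eligible:
        g.add_node(gene, kind="mRNA", direction=directions.get(gene))
    for p in pair_labels:
        if p.gene not in eligible or p.label == INCONCLUSIVE:
            continue
        if p.gene not in g:
            raise ValueError(f"relationship edge references unknown gene {p.gene!r}")
        g.add_node(p.lnc, kind="lncRNA", direction=directions.get(p.lnc))
        rel = orientation_of.get(p.lnc)
        g.add_edge(
            p.lnc, p.gene, kind="relationship", label=p.label,
            orientation=rel.category if rel else None,
        )
        if rel is not None:
            g.add_edge(p.lnc, p.gene, kind="association",
                       orientation=rel.category, subregion=rel.subregion)
    for mirna in mirnas:
        for row in targets.rows.itertuples():
            if row.mirna != mirna or row.gene not in g:
                continue
            g.add_node(mirna, kind="miRNA", direction=directions.get(mirna))
            g.add_edge(mirna, row.gene, kind="targeting", evidence=row.evidence)
    return g


def network_to_json(g: nx.MultiDiGraph) -> str:
    """Edge-list JSON export of the regulatory network."""
    payload = {
        "nodes": [
            {"id": n, **{k: v for k, v in d.items() if v is not None}}
            for n, d in sorted(g.nodes(data=True))
        ],
        "edges": [
            {"source": u, "target": v,
             **{k: val for k, val in d.items() if val is not None}}
            for u, v, d in sorted(g.edges(data=True), key=lambda e: (e[0], e[1]))
        ],
    }
    return json.dumps(payload, indent=1)


def _pct(part: int, whole: int) -> float:
    return round(100.0 * part / whole, 1) if whole else 0.0


def summary_report(
    detection_counts: dict[str, tuple[int, int]] | None = None,
    census: dict[str, float] | None = None,
    funnel: dict[str, list[str]] | None = None,
) -> dict:
    """Stage-by-stage report: detection/DE percentages (1 dp), the lncRNA
    orientation census, and the shortlisting funnel counts.

    ``detection_counts`` maps a label to (count, total); the report adds the
    percentage.  ``funnel`` maps stage name -> gene/miRNA list in cascade
    order.
    """
    report: dict = {}
    if detection_counts:
        report["fractions"] = {
            label: {"count": c, "total": t, "percent": _pct(c, t)}
            for label, (c, t) in detection_counts.items()
        }
    if census is not None:
        report["orientation_census"] = dict(census)
    if funnel is not None:
        report["funnel"] = {
            stage: {"n": len(items), "members": list(items)}
            for stage, items in funnel.items()
        }
    return report
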