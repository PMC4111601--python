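"""Self-consistent synthetic inputs with planted ground truth.

Emulates the structure of the deposited study (GEO GSE44834): three array
channels over a maturation timecourse (Days 2/4/6/8, baseline Day 2) and an
OGD injury timecourse (0/2/4 hr, baseline 0 hr); lncRNA loci planted in all
four orientation classes with their sub-regions; monotone log2 trajectories
with sign reversal under OGD; a miRNA target table and gene sets with one
planted enriched set; and qPCR C_T tables consistent with the planted
expression (C_T = a - log2(expression)).

Intensities follow ``I = baseline * 2**(s(t) + eps)`` with ``s`` a linear
log2 trajectory anchored at 0 on the baseline sample and
``eps ~ Normal(0, noise_sd^2)`` per cell, so the Signal Log Ratio recovers
``s(t)`` exactly at zero noise.  Differentially expressed probes draw their
endpoint amplitude well above the calling cut and flat probes well below it,
which keeps planted-truth recovery near-perfect at the default noise level.

All generators take an explicit seed and draw from a single
``numpy.random.default_rng`` stream; no global state.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import (
    Channel,
    Condition,
    ExpressionMatrix,
    GeneModel,
    GeneSetCollection,
    LncLocus,
    QpcrRecord,
    SampleDesign,
    TargetTable,
)

__all__ = [
    "DEFAULT_CLASS_MIX",
    "SyntheticTruth",
    "default_designs",
    "generate_annotation",
    "generate_expression",
    "generate_ancillary",
]

DEFAULT_CLASS_MIX = {
    "intergenic": 0.60,
    "antisense_overlap": 0.20,
    "sense_overlap": 0.13,
    "bidirectional": 0.07,
}

#: gene slot spacing on the toy chromosome (bp)
_SLOT = 100_000
_CHROM = "chrS"

# subregion cycles; promoter-embedded loci are planted on the sense strand
# only (an opposite-strand locus upstream of a TSS is head-to-head divergent
# and would legitimately classify as bidirectional)
_SENSE_SUBREGIONS = ("intron", "exon", "intron_exon", "three_prime_UTR",
                     "first_intron", "promoter")
_ANTISENSE_SUBREGIONS = ("intron", "exon", "intron_exon", "three_prime_UTR",
                         "first_intron")


def default_designs() -> tuple[SampleDesign, SampleDesign]:
    """The study layout: Days 2/4/6/8 (baseline Day 2); 0/2/4 hr OGD (baseline 0 hr)."""
    maturation = SampleDesign(
        condition=Condition.MATURATION,
        timepoints={"Day2": 2.0, "Day4": 4.0, "Day6": 6.0, "Day8": 8.0},
        baseline="Day2",
    )
    ogd = SampleDesign(
        condition=Condition.OGD,
        timepoints={"0hr": 0.0, "2hr": 2.0, "4hr": 4.0},
        baseline="0hr",
    )
    return maturation, ogd


@dataclass
class SyntheticTruth:
    """Planted ground truth for every pipeline stage; JSON-serializable."""

    seed: int
    #: lnc id -> (category, subregion, gene id or "")
    lnc_class: dict[str, tuple[str, str, str]]
    #: channel value -> probe id -> {"gene", "maturation", "injury"} where the
    #: last two are trajectory families "up" | "down" | "flat"
    probe_truth: dict[str, dict[str, dict[str, str]]]
    #: planted mRNA-lncRNA pairs with their realizable final label
    pairs: list[dict]
    #: planted miRNA -> target gene symbols (>= min-genes coverage)
    mirna_targets: dict[str, list[str]]
    #: miRNA probe id -> planted detected flag
    mirna_detected: dict[str, bool]
    #: endogenous control probe ids on the miRNA channel
    control_probes: list[str]
    #: gene symbols in the planted enriched set
    enriched_genes: list[str] = field(default_factory=list)

    def de_flags(self, channel: Channel | str, condition: Condition | str) -> dict[str, bool]:
        key = "maturation" if Condition(condition) == Condition.MATURATION else "injury"
        return {
            probe: info[key] != "flat"
            for probe, info in self.probe_truth[Channel(channel).value].items()
        }

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        raw = json.loads(text)
        raw["lnc_class"] = {k: tuple(v) for k, v in raw["lnc_class"].items()}
        return cls(**raw)


def _class_counts(n_lnc: int, class_mix: dict[str, float]) -> dict[str, int]:
    if abs(sum(class_mix.values()) - 1.0) > 1e-9:
        raise ValueError("class_mix must sum to 1")
    raw = {k: v * n_lnc for k, v in class_mix.items()}
    counts = {k: int(v) for k, v in raw.items()}
    # largest remainder
    rest = n_lnc - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:rest]:
        counts[k] += 1
    return counts


def _make_gene(i: int, strand: str) -> GeneModel:
    r = _SLOT * (i + 1)
    exons = ((r, r + 500), (r + 2500, r + 3000), (r + 5500, r + 6000))
    utr3 = (r + 5700, r + 6000) if strand == "+" else (r, r + 300)
    return GeneModel(
        gene_id=f"G{i:03d}", symbol=f"G{i:03d}", chrom=_CHROM, strand=strand,
        start=r, end=r + 6000, exons=exons, utr3=utr3,
    )


def _overlap_interval(gene: GeneModel, subregion: str) -> tuple[int, int]:
    r = gene.start
    plus = gene.strand == "+"
    table_plus = {
        "exon": (r + 2600, r + 2900),
        "intron": (r + 3500, r + 4000),
        "first_intron": (r + 1000, r + 1500),
        "intron_exon": (r + 2600, r + 3300),
        "three_prime_UTR": (r + 5750, r + 5950),
        "promoter": (r - 800, r - 300),
    }
    table_minus = {
        "exon": (r + 2600, r + 2900),
        "intron": (r + 1000, r + 1500),
        "first_intron": (r + 3500, r + 4000),
        "intron_exon": (r + 2600, r + 3300),
        "three_prime_UTR": (r + 50, r + 250),
        "promoter": (r + 6300, r + 6800),
    }
    return (table_plus if plus else table_minus)[subregion]


def generate_annotation(
    n_genes: int = 50,
    n_lnc: int = 500,
    class_mix: dict[str, float] | None = None,
    seed: int = 0,
    n_mirna: int = 200,
    n_mrna_probes: int = 2000,
    detected_fraction: float = 0.38,
    n_network_mirnas: int = 10,
) -> tuple[list[GeneModel], list[LncLocus], SyntheticTruth]:
    """Build a toy genome and the full planted truth.

    Genes sit on well-separated slots of a synthetic chromosome; each
    lncRNA locus is constructed so the locus classifier provably recovers
    its planted class and sub-region.  Expression trajectory families,
    mRNA-lncRNA pair labels and the miRNA target map are planted here so
    the expression and ancillary generators can emit consistent data.
    """
    class_mix = dict(class_mix or DEFAULT_CLASS_MIX)
    unknown = set(class_mix) - set(DEFAULT_CLASS_MIX)
    if unknown:
        raise ValueError(f"unknown orientation class(es): {sorted(unknown)}")
    counts = _class_counts(n_lnc, class_mix)
    if counts.get("bidirectional", 0) > n_genes:
        raise ValueError(
            f"infeasible class mix: {counts['bidirectional']} bidirectional loci "
            f"but only {n_genes} genes (one divergent slot per gene)"
        )
    rng = np.random.default_rng(seed)
    genes = [_make_gene(i, "+" if i % 2 == 0 else "-") for i in range(n_genes)]

    loci: list[LncLocus] = []
    lnc_class: dict[str, tuple[str, str, str]] = {}
    idx = 0

    def add(lnc: LncLocus, cat: str, sub: str, gene_id: str) -> None:
        loci.append(lnc)
        lnc_class[lnc.lnc_id] = (cat, sub, gene_id)

    for cat in ("antisense_overlap", "sense_overlap"):
        subs = _ANTISENSE_SUBREGIONS if cat == "antisense_overlap" else _SENSE_SUBREGIONS
        for j in range(counts.get(cat, 0)):
            sub = subs[j % len(subs)]
            gene = genes[j % n_genes]
            start, end = _overlap_interval(gene, sub)
            strand = (
                gene.strand
                if cat == "sense_overlap"
                else ("-" if gene.strand == "+" else "+")
            )
            add(
                LncLocus(f"lnc{idx:04d}", _CHROM, strand, start, end),
                cat, sub, gene.gene_id,
            )
            idx += 1
    bidir_genes = rng.permutation(n_genes)[: counts.get("bidirectional", 0)]
    for j, gi in enumerate(bidir_genes):
        gene = genes[int(gi)]
        gap = int(rng.integers(50, 950))
        if gene.strand == "+":
            end = gene.start - gap
            lnc = LncLocus(f"lnc{idx:04d}", _CHROM, "-", end - 500, end)
        else:
            start = gene.end + gap
            lnc = LncLocus(f"lnc{idx:04d}", _CHROM, "+", start, start + 500)
        add(lnc, "bidirectional", "none", gene.gene_id)
        idx += 1
    far = _SLOT * (n_genes + 2)
    for j in range(counts.get("intergenic", 0)):
        start = far + 10_000 * j
        strand = "+" if j % 2 == 0 else "-"
        add(LncLocus(f"lnc{idx:04d}", _CHROM, strand, start, start + 400),
            "intergenic", "none", "")
        idx += 1

    # --- expression trajectory families -----------------------------------
    probe_truth: dict[str, dict[str, dict[str, str]]] = {
        Channel.MRNA.value: {}, Channel.LNCRNA.value: {}, Channel.MIRNA.value: {},
    }

    def random_family() -> str:
        return str(rng.choice(["up", "down", "flat"], p=[0.35, 0.35, 0.30]))

    def negate(fam: str) -> str:
        return {"up": "down", "down": "up", "flat": "flat"}[fam]

    # pair plan: the first associated lncRNA of each gene forms a pair whose
    # label cycles synergistic / inverse / inconclusive
    first_lnc_of: dict[str, str] = {}
    for lid, (cat, _sub, gid) in lnc_class.items():
        if gid and gid not in first_lnc_of:
            first_lnc_of[gid] = lid
    pair_labels = ["synergistic", "inverse", "inconclusive"]
    pairs: list[dict] = []
    mrna_fams: dict[str, tuple[str, str]] = {}
    lnc_fams: dict[str, tuple[str, str]] = {}
    for k, (gid, lid) in enumerate(sorted(first_lnc_of.items())):
        label = pair_labels[k % 3]
        m_mat = "up" if rng.random() < 0.5 else "down"
        m_inj = negate(m_mat)  # sign reversal under OGD
        if label == "synergistic":
            l_mat, l_inj = m_mat, m_inj
        elif label == "inverse":
            l_mat, l_inj = negate(m_mat), negate(m_inj)
        else:  # inconclusive: concordant in maturation, discordant in injury
            l_mat, l_inj = m_mat, negate(m_inj)
        mrna_fams[gid] = (m_mat, m_inj)
        lnc_fams[lid] = (l_mat, l_inj)
        pairs.append(
            {"gene": gid, "mrna": f"m-{gid}", "lnc": lid, "label": label}
        )

    for gene in genes:
        pid = f"m-{gene.gene_id}"
        if gene.gene_id in mrna_fams:
            mat, inj = mrna_fams[gene.gene_id]
        else:
            mat = random_family()
            inj = negate(mat) if (mat != "flat" and rng.random() < 0.7) else random_family()
        probe_truth[Channel.MRNA.value][pid] = {
            "gene": gene.gene_id, "maturation": mat, "injury": inj,
        }
    # filler probes not tied to annotated genes, to array-like probe counts
    for j in range(max(0, n_mrna_probes - n_genes)):
        mat = random_family()
        inj = negate(mat) if (mat != "flat" and rng.random() < 0.7) else random_family()
        probe_truth[Channel.MRNA.value][f"p{j:04d}"] = {
            "gene": "", "maturation": mat, "injury": inj,
        }
    for lnc in loci:
        cat, _sub, gid = lnc_class[lnc.lnc_id]
        if lnc.lnc_id in lnc_fams:
            mat, inj = lnc_fams[lnc.lnc_id]
        else:
            mat = random_family()
            inj = negate(mat) if (mat != "flat" and rng.random() < 0.7) else random_family()
        probe_truth[Channel.LNCRNA.value][lnc.lnc_id] = {
            "gene": gid, "maturation": mat, "injury": inj,
        }

    # --- miRNA channel and target map -------------------------------------
    eligible = [p["gene"] for p in pairs if p["label"] != "inconclusive"]
    control_probes = [f"ctrl-{i}" for i in range(1, 5)]
    mirna_detected: dict[str, bool] = {}
    mirna_targets: dict[str, list[str]] = {}
    decoy_pool = [g.gene_id for g in genes if g.gene_id not in eligible]
    n_detected = int(round(detected_fraction * n_mirna))
    for i in range(n_mirna):
        pid = f"miR-s{i:03d}"
        detected = i < n_detected
        mirna_detected[pid] = detected
        if detected and i < n_network_mirnas and len(eligible) >= 2:
            fam_mat = "up" if i % 2 == 0 else "down"
            take = 2 + int(rng.random() < 0.5)
            picks = list(rng.choice(eligible, size=min(take, len(eligible)),
                                    replace=False))
            mirna_targets[pid] = sorted(str(g) for g in picks)
        elif detected:
            fam_mat = random_family()
            if decoy_pool and rng.random() < 0.5:
                mirna_targets[pid] = [str(rng.choice(decoy_pool))]
        else:
            fam_mat = "flat"
        fam_inj = negate(fam_mat) if fam_mat != "flat" else "flat"
        probe_truth[Channel.MIRNA.value][pid] = {
            "gene": "", "maturation": fam_mat, "injury": fam_inj,
        }
    for pid in control_probes:
        probe_truth[Channel.MIRNA.value][pid] = {
            "gene": "", "maturation": "flat", "injury": "flat",
        }

    truth = SyntheticTruth(
        seed=int(seed),
        lnc_class=lnc_class,
        probe_truth=probe_truth,
        pairs=pairs,
        mirna_targets=mirna_targets,
        mirna_detected=mirna_detected,
        control_probes=control_probes,
        enriched_genes=sorted(set(p["gene"] for p in pairs)),
    )
    return genes, loci, truth


# amplitude bands (log2 units) keyed by DE cut: DE endpoints land well above
# the cut, flat ones well below, so calls are separable at the default noise
_DE_BAND = {1.0: (1.5, 3.0), 0.6: (1.1, 2.0)}
_FLAT_BAND = {1.0: (0.0, 0.5), 0.6: (0.0, 0.3)}


def _trajectory(family: str, amplitude: float, times: np.ndarray) -> np.ndarray:
    t0, tmax = times[0], times[-1]
    ramp = (times - t0) / (tmax - t0)
    sign = {"up": 1.0, "down": -1.0, "flat": 1.0}[family]
    return sign * amplitude * ramp


def generate_expression(
    design: SampleDesign,
    truth: SyntheticTruth,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> dict[Channel, ExpressionMatrix]:
    """Raw intensity matrices for all three channels under one design."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    cond_key = "maturation" if design.condition == Condition.MATURATION else "injury"
    times = design.times
    out: dict[Channel, ExpressionMatrix] = {}
    for channel in (Channel.MRNA, Channel.LNCRNA, Channel.MIRNA):
        probes = truth.probe_truth[channel.value]
        cut = 0.6 if channel == Channel.MIRNA else 1.0
        rows = np.empty((len(probes), len(times)))
        ids = list(probes)
        for i, pid in enumerate(ids):
            fam = probes[pid][cond_key]
            if channel == Channel.MIRNA:
                if pid in truth.control_probes:
                    base = rng.uniform(800, 1200)
                elif truth.mirna_detected.get(pid, True):
                    base = rng.uniform(600, 3000)
                else:
                    base = rng.uniform(50, 200)
            else:
                base = rng.uniform(200, 1000)
            band = _FLAT_BAND[cut] if fam == "flat" else _DE_BAND[cut]
            amp = rng.uniform(*band)
            s = _trajectory(fam, amp, times)
            eps = rng.normal(0.0, noise_sd, size=len(times)) if noise_sd else 0.0
            rows[i] = base * 2.0 ** (s + eps)
        df = pd.DataFrame(rows, index=ids, columns=design.sample_ids)
        out[channel] = ExpressionMatrix(channel=channel, data=df)
    return out


def generate_ancillary(
    truth: SyntheticTruth,
    seed: int = 0,
    n_background_sets: int = 8,
    ct_noise_sd: float = 0.0,
) -> tuple[TargetTable, GeneSetCollection, dict[str, list[QpcrRecord]]]:
    """Target table, gene sets and qPCR C_T tables consistent with the truth.

    The target table is the planted miRNA->gene map plus decoy rows already
    planted in the truth; evidence alternates predicted/validated.  One
    enriched gene set contains exactly the planted pair genes; background
    sets are random draws from the gene universe.  qPCR tables encode each
    planted fold change via ``C_T = a - log2(expression)`` with a constant
    reference assay.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for j, (mirna, gs) in enumerate(sorted(truth.mirna_targets.items())):
        for g in gs:
            rows.append(
                {
                    "mirna": mirna,
                    "gene": g,
                    "evidence": "validated" if j % 2 == 0 else "predicted",
                    "source": "synthetic",
                }
            )
    targets = TargetTable(pd.DataFrame(rows) if rows else None)

    universe = {
        info["gene"]
        for info in truth.probe_truth[Channel.MRNA.value].values()
        if info["gene"]
    }
    sets: dict[str, set[str]] = {}
    if truth.enriched_genes:
        sets["planted_pathway"] = set(truth.enriched_genes) & universe
    pool = sorted(universe)
    for b in range(n_background_sets):
        size = min(int(rng.integers(8, 15)), len(pool))
        if size == 0:
            break
        sets[f"background_{b}"] = set(rng.choice(pool, size=size, replace=False))
    gene_sets = GeneSetCollection(sets, universe=universe)

    # qPCR: one assay per planted pair gene, calibrator = baseline condition
    qpcr: dict[str, list[QpcrRecord]] = {}
    a = 30.0  # Ct intercept: Ct = a - log2(expression)
    for pair in truth.pairs:
        gene = pair["gene"]
        fam = truth.probe_truth[Channel.MRNA.value][f"m-{gene}"]["maturation"]
        fold = 4.0 if fam == "up" else (0.25 if fam == "down" else 1.0)
        recs = []
        for sample, expr in (("Day2", 1.0), ("Day8", fold)):
            ct = a - np.log2(expr)
            reps = tuple(
                float(ct + rng.normal(0.0, ct_noise_sd)) if ct_noise_sd else float(ct)
                for _ in range(3)
            )
            recs.append(QpcrRecord(assay=gene, sample=sample, ct=reps))
            recs.append(
                QpcrRecord(assay="REF", sample=sample,
                           ct=(18.0, 18.0, 18.0))
            )
        recs.append(QpcrRecord(assay=gene, sample="NTC",
                               ct=(39.0, 39.2, 38.8), is_ntc=True))
        qpcr[gene] = recs
    return targets, gene_sets, qpcr
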