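"""Published reference measurements from the maturing-neuron / OGD study
(GEO series GSE44834) used as inputs to the downstream analyses.

These are the printed summary values for the 11 shortlisted genes and their
associated lncRNAs: per-timepoint Signal Log Ratios (mean +/- SD over 2
replicates) under oxygen-glucose deprivation, the Pearson trend coefficients
for both conditions with their significance marks, the genomic orientation
of each lncRNA, the pathway membership table, and the qPCR purity panel
(mean C_T +/- SD over 3 biological replicates, 40-cycle runs).
"""

from __future__ import annotations

# Each row: (gene, accession, kind, orientation, subregion,
#            (slr_2h, sd_2h), (slr_4h, sd_4h), mark_4h,
#            r_maturation, mark_mat, r_injury, mark_inj, label)
# kind: "mRNA" | "lncRNA"; label (final mRNA-lncRNA relationship) only on
# lncRNA rows.
INJURY_ROWS = [
    # proliferation and differentiation related pathway
    ("Axin2", "NM_015732", "mRNA", None, None,
     (0.03, 0.03), (1.54, 0.33), "##", -0.83, "**", 0.88, "", None),
    ("Axin2", "ENSMUST00000143435", "lncRNA", "antisense_overlap", "intron_exon",
     (-0.46, 0.06), (-0.26, 0.03), "#", 0.28, "", -0.55, "*", "inverse"),
    ("Igf1r", "NM_010513", "mRNA", None, None,
     (0.07, 0.01), (0.25, 0.03), "##", 0.54, "*", 0.97, "", None),
    ("Igf1r", "AK040698", "lncRNA", "antisense_overlap", "intron",
     (1.34, 0.31), (1.31, 0.26), "", -0.97, "*", 0.86, "**", "inconclusive"),
    ("Ikbkb", "NM_010546", "mRNA", None, None,
     (-0.49, 0.09), (0.10, 0.01), "##", 0.87, "**", 0.16, "", None),
    ("Ikbkb", "uc009ldv.1", "lncRNA", "sense_overlap", "promoter",
     (-2.05, 2.06), (-1.22, 0.38), "", -0.04, "", -0.59, "*", "inconclusive"),
    ("Prkcb", "NM_008855", "mRNA", None, None,
     (-0.89, 0.13), (-0.23, 0.03), "##", 0.95, "**", -0.25, "", None),
    ("Prkcb", "ENSMUST00000118119", "lncRNA", "sense_overlap", "intron",
     (-0.82, 0.09), (-0.49, 0.05), "##", 0.94, "*", -0.59, "*", "synergistic"),
    ("Ralgds", "NM_009058", "mRNA", None, None,
     (0.12, 0.02), (-0.25, 0.05), "##", -0.64, "**", -0.65, "", None),
    ("Ralgds", "uc008iyq.1", "lncRNA", "sense_overlap", "intron_exon",
     (1.23, 0.15), (0.41, 0.06), "##", -0.73, "**", 0.32, "", "inconclusive"),
    # cell adhesion molecules
    ("Cntn1", "NM_001159648", "mRNA", None, None,
     (0.34, 0.06), (0.39, 0.06), "", -0.78, "*", 0.91, "**", None),
    ("Cntn1", "AK004399", "lncRNA", "sense_overlap", "three_prime_UTR",
     (-0.33, 0.03), (-0.59, 0.06), "##", 0.99, "*", -1.00, "*", "inverse"),
    ("Cntn1", "AK140484", "lncRNA", "antisense_overlap", "intron",
     (0.09, 0.01), (-0.33, 0.04), "##", 0.47, "*", -0.75, "", "inverse"),
    ("Ncam1", "NM_010875", "mRNA", None, None,
     (-1.38, 0.21), (-0.35, 0.04), "##", 0.89, "*", -0.25, "", None),
    ("Ncam1", "uc009pjm.1", "lncRNA", "sense_overlap", "promoter",
     (-0.23, 0.02), (0.00, 0.10), "##", -0.92, "*", -0.01, "", "inconclusive"),
    ("Ncam1", "AK156022", "lncRNA", "antisense_overlap", "intron",
     (1.34, 0.13), (0.69, 0.07), "##", -0.41, "", 0.52, "*", "inverse"),
    ("Negr1", "NM_001039094", "mRNA", None, None,
     (-0.39, 0.04), (-0.60, 0.06), "#", 0.96, "**", -0.99, "*", None),
    ("Negr1", "uc008ruz.1", "lncRNA", "bidirectional", "none",
     (-0.98, 0.13), (-0.70, 0.08), "", 0.50, "*", -0.70, "*", "synergistic"),
    ("Negr1", "uc008rva.1", "lncRNA", "bidirectional", "none",
     (0.98, 0.24), (1.15, 0.24), "", -0.53, "*", 0.93, "**", "inverse"),
    ("Nrxn1", "NM_020252", "mRNA", None, None,
     (-0.93, 0.18), (-0.14, 0.02), "##", 0.21, "**", -0.14, "", None),
    ("Nrxn1", "uc008dwg.1", "lncRNA", "sense_overlap", "intron",
     (0.08, 0.02), (0.35, 0.06), "##", -0.48, "", 0.95, "", "inverse"),
    # neurotrophin signalling pathway
    ("Ntrk2", "NM_008745", "mRNA", None, None,
     (-0.36, 0.04), (-0.25, 0.02), "#", 0.96, "**", -0.68, "*", None),
    ("Ntrk2", "AK021278", "lncRNA", "antisense_overlap", "intron",
     (0.16, 0.02), (-0.49, 0.05), "##", -0.87, "**", -0.72, "", "inconclusive"),
    ("Sh2b3", "NM_008507", "mRNA", None, None,
     (-1.50, 0.34), (-1.77, 0.42), "", 0.84, "**", -0.93, "**", None),
    ("Sh2b3", "AK007127", "lncRNA", "antisense_overlap", "first_intron",
     (-0.06, 0.02), (0.37, 0.07), "##", -0.53, "*", 0.79, "", "inverse"),
]

#: OGD sampling hours; SLRs are anchored to the 0 hr control.
INJURY_HOURS = (0.0, 2.0, 4.0)


def injury_pairs() -> list[dict]:
    """The 14 mRNA-lncRNA pairs as classifier input (printed R values)."""
    mrna_by_gene = {
        r[0]: r for r in INJURY_ROWS if r[2] == "mRNA"
    }
    pairs = []
    for row in INJURY_ROWS:
        if row[2] != "lncRNA":
            continue
        m = mrna_by_gene[row[0]]
        pairs.append(
            {
                "gene": row[0],
                "mrna": m[1],
                "lnc": row[1],
                "r_mrna_maturation": m[8],
                "r_lnc_maturation": row[8],
                "r_mrna_injury": m[10],
                "r_lnc_injury": row[10],
                "printed_label": row[12],
            }
        )
    return pairs


# ---------------------------------------------------------------------------
# pathway membership (over-represented pathways of the dual-DE gene list).
# Genes marked as predicted targets of the differentially expressed miRNAs
# are listed separately in PATHWAY_MIRNA_TARGETS.

PATHWAYS = {
    "Proliferation and differentiation related pathways": [
        "Abl1", "Araf", "Axin2", "Brca2", "Cdh1", "Ctnna2", "E2f2", "Fgf12",
        "Fgfr1", "Gli2", "Igf1r", "Ikbkb", "Ikbkg", "Itgb1", "Kit", "Pax8",
        "Plcg1", "Prkcb", "Ptch1", "Ptgs2", "Pik3cd", "Ralgds", "Tcf7l1",
        "Wnt11",
    ],
    "Cell adhesion molecules": [
        "Cd40", "Cd8b1", "Cdh1", "Cdh4", "Cntn1", "F11r", "H2-d1", "Itgb1",
        "Madcam1", "Ncam1", "Negr1", "Nrxn1", "Nrxn3",
    ],
    "Neurotrophin signalling pathway": [
        "Abl1", "Calm1", "Camk2d", "Ikbkb", "Ntrk2", "Pik3cd", "Plcg1",
        "Rapgef1", "Sh2b1", "Sh2b3", "Sort1", "Trp73",
    ],
    "Prostate cancer": [
        "Araf", "Creb3l2", "E2f2", "Fgfr1", "Igf1r", "Ikbkb", "Ikbkg",
        "Pdgfc", "Pik3cd", "Tcf7l1",
    ],
    "Glioma": [
        "Araf", "Calm1", "Camk2d", "E2f2", "Igf1r", "Pik3cd", "Plcg1",
        "Prkcb",
    ],
}

#: The 23 pathway genes that are predicted targets of the differentially
#: expressed miRNAs (top-3 pathways, bold entries).
PATHWAY_MIRNA_TARGETS = [
    "Abl1", "Axin2", "E2f2", "Fgfr1", "Igf1r", "Ikbkb", "Itgb1", "Kit",
    "Prkcb", "Ptgs2", "Ralgds",
    "Cdh4", "Cntn1", "F11r", "Ncam1", "Negr1", "Nrxn1", "Nrxn3",
    "Camk2d", "Ntrk2", "Rapgef1", "Sh2b3", "Sort1",
]

#: The 11 genes of the 23 still differentially expressed on days 6 and 8.
MATURE_GENES_11 = [
    "Axin2", "Igf1r", "Ikbkb", "Prkcb", "Ralgds",
    "Cntn1", "Ncam1", "Negr1", "Nrxn1", "Ntrk2", "Sh2b3",
]

#: The 7 genes with a distinct inverse or synergistic mRNA-lncRNA pair.
ELIGIBLE_GENES_7 = ["Axin2", "Prkcb", "Cntn1", "Ncam1", "Negr1", "Nrxn1", "Sh2b3"]

#: The 10 miRNAs targeting >=2 of the 7 eligible genes.
NETWORK_MIRNAS_10 = [
    "miR-124", "miR-128", "miR-129-5p", "miR-203", "miR-218",
    "miR-290-5p", "miR-326", "miR-329", "miR-377", "miR-495",
]

# ---------------------------------------------------------------------------
# qPCR purity panel: mean C_T +/- SD (3 biological replicates, 40 cycles)

QPCR_REPLICATES = 3

#: assay -> {sample: (mean_ct, sd)}; "NTC" is the no-template control.
QPCR_PURITY = {
    "miR-124": {
        "NTC": (39.0, 0.3),
        "E15 Day 2": (21.1, 0.7), "E15 Day 4": (21.0, 0.7),
        "E15 Day 6": (21.1, 0.3), "E15 Day 8": (21.0, 0.0),
        "0 hr OGD": (21.7, 0.8), "2 hr OGD": (21.3, 0.1),
        "4 hr OGD": (21.1, 0.1), "E18 astrocyte": (38.5, 0.6),
    },
    "miR-143": {
        "NTC": (34.4, 0.9),
        "E15 Day 2": (32.3, 1.6), "E15 Day 4": (32.6, 0.7),
        "E15 Day 6": (33.9, 1.0), "E15 Day 8": (33.0, 0.0),
        "0 hr OGD": (34.1, 0.3), "2 hr OGD": (33.6, 0.4),
        "4 hr OGD": (34.1, 0.6), "E18 astrocyte": (30.4, 0.0),
    },
    "miR-223": {
        "NTC": (38.4, 0.6),
        "E15 Day 2": (36.3, 0.2), "E15 Day 4": (38.4, 0.2),
        "E15 Day 6": (39.0, 0.4), "E15 Day 8": (38.8, 0.4),
        "0 hr OGD": (39.3, 0.2), "2 hr OGD": (38.8, 0.4),
        "4 hr OGD": (39.3, 0.3), "E18 astrocyte": (33.0, 0.2),
    },
}

#: Genome-wide probe/DE counts reported for the three channels.
REPORTED_COUNTS = {
    "mrna": {"detected": 14213, "de": 6965},
    "lncrna": {"detected": 15715, "de": 7455},
    "mirna": {"probes": 1040, "detected": 395},
}

#: Orientation census over the differentially expressed lncRNAs (percent).
REPORTED_ORIENTATION_CENSUS = {
    "intergenic": 60.0,
    "antisense_overlap": 20.0,
    "sense_overlap": 13.0,
    "bidirectional": 7.0,
}
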