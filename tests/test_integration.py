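import math
from math import comb

import numpy as np
import pandas as pd
import pytest

from trioma.data import Channel, GeneSetCollection, SLRMatrix, TargetTable
from trioma.differential import DifferentialCall
from trioma.integration import (
    build_network,
    enrich_pathways,
    intersect_mirna_targets,
    map_mirnas_min_genes,
    mature_phenotype_filter,
    network_to_json,
    shortlist_dual_de,
    summary_report,
)
from trioma.loci import LocusRelation
from trioma.relationship import classify_pairs


def call(probe, de):
    return DifferentialCall(probe, (0.0,), de, ("flat",))


def rel(lnc, gene_id, cat="antisense_overlap"):
    return LocusRelation(lnc, gene_id, cat, "intron", 0)


def targets_from(rows):
    return TargetTable(
        pd.DataFrame(
            [
                {"mirna": m, "gene": g, "evidence": ev, "source": "t"}
                for m, g, ev in rows
            ]
        )
    )


class TestShortlistDualDe:
    def test_requires_both_channels_de(self):
        mrna = [call("mA", True), call("mB", True), call("mC", False)]
        lnc = [call("lA", True), call("lB", False), call("lC", True)]
        gene_of = {"mA": "A", "mB": "B", "mC": "C"}
        rels = [rel("lA", "A"), rel("lB", "B"), rel("lC", "C")]
        # A: both DE -> in; B: lnc not DE -> out; C: mRNA not DE -> out
        assert shortlist_dual_de(mrna, lnc, gene_of, rels) == ["A"]

    def test_planted_truth_recovery(self, rng):
        genes = [f"G{i}" for i in range(30)]
        planted = set(rng.choice(genes, size=12, replace=False))
        mrna, lnc, gene_of, rels = [], [], {}, []
        for i, g in enumerate(genes):
            gene_of[f"m{i}"] = g
            mrna.append(call(f"m{i}", g in planted or bool(rng.random() < 0.3)))
            lnc.append(call(f"l{i}", g in planted))
            rels.append(rel(f"l{i}", g))
        assert set(shortlist_dual_de(mrna, lnc, gene_of, rels)) == planted


class TestEnrichPathways:
    def test_full_containment_fisher_p(self):
        universe = {f"G{i}" for i in range(20)}
        sets = GeneSetCollection({"s": {f"G{i}" for i in range(5)}}, universe)
        (res,) = enrich_pathways([f"G{i}" for i in range(5)], sets, method="fisher")
        assert res.p == pytest.approx(1 / comb(20, 5))
        assert res.overlap == 5

    def test_zero_overlap_ease_is_one(self):
        universe = {"A", "B", "C", "D"}
        sets = GeneSetCollection({"s": {"A", "B"}}, universe)
        (res,) = enrich_pathways(["C", "D"], sets, method="ease")
        assert res.p == 1.0

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(20):
            N = int(rng.integers(5, 26))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            universe = {f"G{i}" for i in range(N)}
            member = set(list(universe)[:K])
            picked = set(rng.choice(sorted(universe), size=n, replace=False))
            sets = GeneSetCollection({"s": member}, universe)
            (res,) = enrich_pathways(picked, sets, method="fisher")
            k = len(picked & member)
            brute = sum(
                comb(K, j) * comb(N - K, n - j)
                for j in range(k, min(K, n) + 1)
                if n - j <= N - K
            ) / comb(N, n)
            assert res.p == pytest.approx(brute, rel=1e-9)

    def test_empty_universe_is_an_error(self):
        with pytest.raises(ValueError, match="universe"):
            enrich_pathways([], GeneSetCollection({}, set()))


class TestCascade:
    def test_intersect_requires_de_mirna(self):
        t = targets_from([("m1", "A", "predicted"), ("m2", "B", "predicted")])
        out = intersect_mirna_targets(["A", "B"], t, de_mirnas={"m1"})
        assert out == ["A"]

    def test_intersect_empty_targets(self):
        assert intersect_mirna_targets(["A"], TargetTable(), {"m1"}) == []

    def test_mature_filter_both_vs_either(self, maturation_design):
        df = pd.DataFrame(
            [[0, 1.4, 1.2, 1.1], [0, 1.4, 0.9, 1.1]],
            index=["mA", "mB"],
            columns=maturation_design.sample_ids,
        )
        slr = SLRMatrix(data=df, design=maturation_design)
        gene_of = {"mA": "A", "mB": "B"}
        both = mature_phenotype_filter(["A", "B"], slr, gene_of, days=(6, 8), cut=1.0)
        either = mature_phenotype_filter(["A", "B"], slr, gene_of, days=(6, 8),
                                         cut=1.0, mode="either")
        assert both == ["A"]  # B fails Day 6
        assert either == ["A", "B"]

    def test_mature_filter_missing_day_is_an_error(self, maturation_design):
        df = pd.DataFrame([[0, 1, 1, 1]], index=["m"],
                          columns=maturation_design.sample_ids)
        slr = SLRMatrix(data=df, design=maturation_design)
        with pytest.raises(ValueError, match="day"):
            mature_phenotype_filter(["A"], slr, {"m": "A"}, days=(6, 14), cut=1.0)

    def test_min_genes_coverage(self):
        t = targets_from(
            [("m1", "A", "predicted"), ("m2", "A", "predicted"),
             ("m2", "B", "validated"), ("m2", "Z", "predicted")]
        )
        assert map_mirnas_min_genes({"A", "B"}, t, k=2) == ["m2"]

    def test_funnel_is_monotone_on_synthetic_run(self):
        from trioma.pipeline import run_synthetic

        result = run_synthetic(seed=7, noise_sd=0.1, n_genes=20, n_lnc=80,
                               n_mirna=60, n_mrna_probes=200)
        funnel = result.report["funnel"]
        assert set(result.eligible) <= set(
            p["gene"] for p in result.truth.pairs
        )
        assert set(funnel["eligible"]["members"]) <= set(
            funnel["dual_de"]["members"]
        ) | set(result.eligible)


class TestNetwork:
    def test_minimal_network_shape(self):
        pairs = classify_pairs(
            [
                {
                    "gene": "A", "mrna": "NM_1", "lnc": "lncA",
                    "r_mrna_maturation": 0.9, "r_lnc_maturation": -0.9,
                    "r_mrna_injury": -0.9, "r_lnc_injury": 0.9,
                }
            ]
        )
        rels = [rel("lncA", "A")]
        t = targets_from([("miR-x", "A", "validated")])
        g = build_network(["A"], pairs, rels, t, ["miR-x"])
        assert g.number_of_nodes() == 3
        kinds = sorted(d["kind"] for _, _, d in g.edges(data=True))
        assert kinds == ["association", "relationship", "targeting"]
        rel_edge = [d for _, _, d in g.edges(data=True) if d["kind"] == "relationship"]
        assert rel_edge[0]["label"] == "inverse"

    def test_json_export_round_trips(self):
        import json

        pairs = classify_pairs(
            [
                {
                    "gene": "A", "mrna": "NM_1", "lnc": "lncA",
                    "r_mrna_maturation": 0.9, "r_lnc_maturation": 0.9,
                    "r_mrna_injury": -0.9, "r_lnc_injury": -0.9,
                }
            ]
        )
        g = build_network(["A"], pairs, [rel("lncA", "A")], TargetTable(), [])
        payload = json.loads(network_to_json(g))
        assert {n["id"] for n in payload["nodes"]} == {"A", "lncA"}


class TestSummaryReport:
    @pytest.mark.parametrize(
        "count, total, expected",
        [(395, 1040, 38.0), (6965, 14213, 49.0), (7455, 15715, 47.4)],
    )
    def test_percentages_recompute_from_counts(self, count, total, expected):
        report = summary_report(detection_counts={"x": (count, total)})
        assert report["fractions"]["x"]["percent"] == expected

    def test_zero_total_no_error(self):
        report = summary_report(detection_counts={"x": (0, 0)})
        assert report["fractions"]["x"]["percent"] == 0.0
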