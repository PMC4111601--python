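import numpy as np
import pytest

from trioma.data import Channel, Condition
from trioma.differential import call_differential
from trioma.integration import enrich_pathways, map_mirnas_min_genes
from trioma.loci import classify_locus
from trioma.normalization import compute_slr
from trioma.pipeline import run_synthetic
from trioma.qpcr import ddct_fold_change
from trioma.synthetic import (
    SyntheticTruth,
    default_designs,
    generate_ancillary,
    generate_annotation,
    generate_expression,
)

SMALL = dict(n_genes=15, n_lnc=60, n_mirna=40, n_mrna_probes=120)


@pytest.fixture(scope="module")
def small_world():
    genes, loci, truth = generate_annotation(seed=5, **SMALL)
    return genes, loci, truth


class TestGenerateAnnotation:
    def test_planted_classes_recovered_exactly(self, small_world):
        genes, loci, truth = small_world
        for lnc in loci:
            cat, sub, gid = truth.lnc_class[lnc.lnc_id]
            r = classify_locus(lnc, genes, window=1000)
            assert (r.category, r.subregion) == (cat, sub), lnc.lnc_id
            if cat != "intergenic":
                assert r.gene_id == gid

    def test_all_intergenic_mix_has_no_associations(self):
        mix = {"intergenic": 1.0, "antisense_overlap": 0.0,
               "sense_overlap": 0.0, "bidirectional": 0.0}
        _, _, truth = generate_annotation(seed=1, class_mix=mix, **SMALL)
        assert all(v[2] == "" for v in truth.lnc_class.values())

    def test_same_seed_is_bit_reproducible(self):
        a = generate_annotation(seed=9, **SMALL)
        b = generate_annotation(seed=9, **SMALL)
        assert [l for l in a[1]] == [l for l in b[1]]
        assert a[2] == b[2]

    def test_infeasible_bidirectional_mix_rejected(self):
        mix = {"intergenic": 0.0, "antisense_overlap": 0.0,
               "sense_overlap": 0.0, "bidirectional": 1.0}
        with pytest.raises(ValueError, match="infeasible"):
            generate_annotation(n_genes=5, n_lnc=50, class_mix=mix, seed=0)

    def test_truth_json_round_trip(self, small_world):
        _, _, truth = small_world
        again = SyntheticTruth.from_json(truth.to_json())
        assert again == truth


class TestGenerateExpression:
    def test_noiseless_slr_recovers_de_flags_exactly(self, small_world):
        _, _, truth = small_world
        maturation, ogd = default_designs()
        for design, cond in ((maturation, Condition.MATURATION), (ogd, Condition.OGD)):
            mats = generate_expression(design, truth, noise_sd=0.0, seed=3)
            for channel, cut in ((Channel.MRNA, 1.0), (Channel.LNCRNA, 1.0),
                                 (Channel.MIRNA, 0.6)):
                slr = compute_slr(mats[channel], design)
                calls = {c.probe_id: c.is_de for c in call_differential(slr, cut)}
                for probe, want in truth.de_flags(channel, cond).items():
                    assert calls[probe] == want, (channel, probe)

    def test_noiseless_baseline_column_zero_and_monotone_trajectories(self, small_world):
        _, _, truth = small_world
        maturation, _ = default_designs()
        mats = generate_expression(maturation, truth, noise_sd=0.0, seed=3)
        slr = compute_slr(mats[Channel.MRNA], maturation)
        assert (slr.data["Day2"] == 0).all()
        for probe, info in truth.probe_truth[Channel.MRNA.value].items():
            row = slr.data.loc[probe].to_numpy()
            if info["maturation"] == "up":
                assert np.all(np.diff(row) > 0)
            elif info["maturation"] == "down":
                assert np.all(np.diff(row) < 0)

    def test_same_seed_reproducible(self, small_world):
        _, _, truth = small_world
        maturation, _ = default_designs()
        a = generate_expression(maturation, truth, noise_sd=0.2, seed=11)
        b = generate_expression(maturation, truth, noise_sd=0.2, seed=11)
        for ch in a:
            assert np.array_equal(a[ch].values, b[ch].values)


class TestGenerateAncillary:
    def test_planted_enriched_set_has_smallest_p(self, small_world):
        _, _, truth = small_world
        targets, sets, _ = generate_ancillary(truth, seed=2)
        results = enrich_pathways(truth.enriched_genes, sets, method="fisher")
        assert results[0].name == "planted_pathway"

    def test_qpcr_tables_encode_planted_folds(self, small_world):
        _, _, truth = small_world
        _, _, qpcr = generate_ancillary(truth, seed=2)
        for pair in truth.pairs:
            fam = truth.probe_truth[Channel.MRNA.value][f"m-{pair['gene']}"]["maturation"]
            want = {"up": 4.0, "down": 0.25, "flat": 1.0}[fam]
            recs = {(r.assay, r.sample): r for r in qpcr[pair["gene"]]}
            res = ddct_fold_change(
                recs[(pair["gene"], "Day8")].ct,
                recs[("REF", "Day8")].ct,
                recs[(pair["gene"], "Day2")].ct,
                recs[("REF", "Day2")].ct,
            )
            assert res.fold == pytest.approx(want)

    def test_decoy_targets_never_reach_min_gene_coverage(self, small_world):
        _, _, truth = small_world
        targets, _, _ = generate_ancillary(truth, seed=2)
        eligible = [p["gene"] for p in truth.pairs if p["label"] != "inconclusive"]
        got = map_mirnas_min_genes(eligible, targets, k=2)
        planted = sorted(m for m, gs in truth.mirna_targets.items() if len(gs) >= 2)
        assert got == planted


class TestFullPipeline:
    def test_noiseless_run_recovers_every_truth_field(self):
        result = run_synthetic(seed=21, noise_sd=0.0, **SMALL)
        for key, rate in result.recovery.items():
            assert rate == 1.0, key

    def test_noisy_run_recovery_above_95_percent(self):
        result = run_synthetic(seed=22, noise_sd=0.1, **SMALL)
        assert result.recovery["orientation"] == 1.0
        for key, rate in result.recovery.items():
            assert rate >= 0.95, (key, rate)
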