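"""Triple filtering, pair scoring, network assembly and export round trips."""

import numpy as np
import pandas as pd
import pytest
from _oracles import brute_force_triples

from spongenet import (CeRNAConfig, GroundTruth, build_network, core_circrnas,
                       export_network, infer_triples, layer_correlations,
                       make_design, read_network, score_pairs,
                       select_top_pairs, simulate_bundle)
from spongenet.cerna import LayerCorrelations, _cross_corr
from spongenet.diffexp import correlate
from spongenet.simulate import ExpressionBundle
from spongenet.targets import DuplexSite


def _sites_from_pairs(pairs, n_sites=1):
    """Fabricate DuplexSite lists for given (mir, target) pairs."""
    sites = []
    for mir, tgt in pairs:
        for k in range(n_sites):
            sites.append(DuplexSite(mir, tgt, 10 * k, 10 * k + 7,
                                    70.0, -17.5, "7mer-m8"))
    return sites


def _triple_row(circ, mir, mrna, r_cm=0.9, r_mc=-0.8, r_mm=-0.7):
    return dict(circ_id=circ, mir_id=mir, mrna_id=mrna,
                r_circ_mrna=r_cm, p_circ_mrna=0.001,
                r_mir_circ=r_mc, p_mir_circ=0.001,
                r_mir_mrna=r_mm, p_mir_mrna=0.001,
                n_sites_circ=1, n_sites_mrna=1,
                site_score_circ=70.0, site_score_mrna=70.0,
                energy_circ=-17.5, energy_mrna=-17.5)


class TestLayerCorrelations:
    def test_matches_scipy_per_pair(self, small_bundle):
        corrs = layer_correlations(small_bundle)
        for circ in list(small_bundle.circ.index)[:3]:
            for mrna in list(small_bundle.mrna.index)[:3]:
                ref = correlate(small_bundle.circ.loc[circ],
                                small_bundle.mrna.loc[mrna])
                assert corrs.circ_mrna_r.loc[circ, mrna] == pytest.approx(ref.r)
                assert corrs.circ_mrna_p.loc[circ, mrna] == pytest.approx(
                    ref.p, rel=1e-6)

    def test_spearman_matches_scipy(self, small_bundle):
        corrs = layer_correlations(small_bundle, method="spearman")
        circ = small_bundle.circ.index[0]
        mrna = small_bundle.mrna.index[0]
        ref = correlate(small_bundle.circ.loc[circ],
                        small_bundle.mrna.loc[mrna], method="spearman")
        assert corrs.circ_mrna_r.loc[circ, mrna] == pytest.approx(ref.r)

    def test_noiseless_planted_axis_correlations_saturate(self, design16):
        truth = GroundTruth.random(3, n_circ=10, n_mir=5, n_mrna=10,
                                   delta=1.0, noise_sd=1e-6, seed=4)
        bundle = simulate_bundle(truth, design16, seed=4)
        corrs = layer_correlations(bundle)
        for ax in truth.axes:
            assert corrs.circ_mrna_r.loc[ax.circ_id, ax.mrna_id] > 0.999
            assert corrs.mir_circ_r.loc[ax.mir_id, ax.circ_id] < -0.999

    def test_identical_column_permutation_invariance(self, small_bundle):
        perm = np.random.default_rng(0).permutation(len(small_bundle.design.sample_ids))
        cols = [small_bundle.design.sample_ids[i] for i in perm]
        from spongenet.simulate import SampleDesign
        design2 = SampleDesign(tuple(cols),
                               tuple(small_bundle.design.groups[i] for i in perm))
        b2 = ExpressionBundle(small_bundle.circ[cols], small_bundle.mir[cols],
                              small_bundle.mrna[cols], design2)
        c1 = layer_correlations(small_bundle)
        c2 = layer_correlations(b2)
        pd.testing.assert_frame_equal(c1.circ_mrna_r, c2.circ_mrna_r)

    def test_too_few_samples_rejected(self, small_truth):
        design = make_design(2, groups=("control",))
        # 2 samples < 3 required
        bundle = simulate_bundle(small_truth, design, seed=0)
        with pytest.raises(ValueError):
            layer_correlations(bundle)


class TestInferTriples:
    @pytest.mark.parametrize("seed", range(3))
    def test_brute_force_oracle_small_instance(self, design16, seed):
        truth = GroundTruth.random(6, n_circ=20, n_mir=10, n_mrna=30,
                                   delta=1.0, noise_sd=0.5, seed=seed)
        bundle = simulate_bundle(truth, design16, seed=seed)
        corrs = layer_correlations(bundle)
        pairs = [(ax.mir_id, ax.circ_id) for ax in truth.axes]
        pairs += [(ax.mir_id, ax.mrna_id) for ax in truth.axes]
        # extra decoy sites exercise the binding predicate both ways
        pairs += [("miR_0000", "circ_0001"), ("miR_0001", "mRNA_0002")]
        sites = _sites_from_pairs(pairs)
        cfg = CeRNAConfig()
        got = infer_triples(corrs, sites, cfg)
        got_keys = list(zip(got["circ_id"], got["mir_id"], got["mrna_id"]))
        expected = brute_force_triples(
            corrs, {(m, t): 1 for m, t in pairs}, cfg)
        assert sorted(got_keys) == expected

    def test_impossible_positive_threshold_empty(self, small_bundle):
        corrs = layer_correlations(small_bundle)
        sites = _sites_from_pairs([("miR_0000", "circ_0000"),
                                   ("miR_0000", "mRNA_0000")])
        cfg = CeRNAConfig(r_min_pos=1.0)
        assert infer_triples(corrs, sites, cfg).empty

    def test_tightening_thresholds_never_adds_triples(self, design16):
        truth = GroundTruth.random(8, n_circ=15, n_mir=8, n_mrna=15,
                                   delta=1.0, noise_sd=0.5, seed=9)
        bundle = simulate_bundle(truth, design16, seed=9)
        corrs = layer_correlations(bundle)
        pairs = [(ax.mir_id, ax.circ_id) for ax in truth.axes]
        pairs += [(ax.mir_id, ax.mrna_id) for ax in truth.axes]
        sites = _sites_from_pairs(pairs, n_sites=2)
        loose = infer_triples(corrs, sites, CeRNAConfig())
        for tight_cfg in (CeRNAConfig(r_min_pos=0.6),
                          CeRNAConfig(r_max_neg=-0.6),
                          CeRNAConfig(p_max=0.001),
                          CeRNAConfig(min_sites_per_pair=2)):
            tight = infer_triples(corrs, sites, tight_cfg)
            loose_keys = set(zip(loose["circ_id"], loose["mir_id"], loose["mrna_id"]))
            tight_keys = set(zip(tight["circ_id"], tight["mir_id"], tight["mrna_id"]))
            assert tight_keys <= loose_keys

    def test_removing_mirna_correlation_removes_its_edges(self, design16):
        truth = GroundTruth.random(4, n_circ=10, n_mir=6, n_mrna=10,
                                   delta=1.0, noise_sd=0.3, seed=2)
        bundle = simulate_bundle(truth, design16, seed=2)
        corrs = layer_correlations(bundle)
        pairs = [(ax.mir_id, ax.circ_id) for ax in truth.axes]
        pairs += [(ax.mir_id, ax.mrna_id) for ax in truth.axes]
        sites = _sites_from_pairs(pairs)
        full = infer_triples(corrs, sites, CeRNAConfig())
        assert not full.empty
        drop = full["mir_id"].iloc[0]
        pruned = LayerCorrelations(
            corrs.circ_mrna_r, corrs.circ_mrna_p,
            corrs.mir_circ_r.drop(index=drop), corrs.mir_circ_p.drop(index=drop),
            corrs.mir_mrna_r.drop(index=drop), corrs.mir_mrna_p.drop(index=drop),
            corrs.n_samples, corrs.method)
        rerun = infer_triples(pruned, sites, CeRNAConfig())
        expected = full[full["mir_id"] != drop].reset_index(drop=True)
        pd.testing.assert_frame_equal(rerun, expected)


class TestScorePairs:
    def test_unit_case_score_one(self):
        triples = pd.DataFrame([_triple_row("c", "m", "g", 1.0, -1.0, -1.0)])
        pairs = score_pairs(triples, universe_mirna_count=10)
        assert pairs["score"].iloc[0] == pytest.approx(1.0)

    def test_hypergeometric_overlap_value(self):
        # circ binds 5 miRNAs, mRNA binds 4, all 4 shared, universe 10:
        # P(X>=4) = C(5,4)C(5,0)/C(10,4) = 5/210
        rows = [_triple_row("c", f"m{i}", "g") for i in range(4)]
        rows += [_triple_row("c", "m_extra", "g_other")]
        triples = pd.DataFrame(rows)
        pairs = score_pairs(triples, universe_mirna_count=10)
        cg = pairs[(pairs["circ_id"] == "c") & (pairs["mrna_id"] == "g")]
        assert cg["enrichment_p"].iloc[0] == pytest.approx(5 / 210, rel=1e-9)

    def test_doubling_shared_mirnas_doubles_score(self):
        one = pd.DataFrame([_triple_row("c", "m1", "g")])
        two = pd.DataFrame([_triple_row("c", "m1", "g"),
                            _triple_row("c", "m2", "g")])
        s1 = score_pairs(one, 10)["score"].iloc[0]
        s2 = score_pairs(two, 10)["score"].iloc[0]
        assert s2 == pytest.approx(2 * s1)

    def test_universe_smaller_than_bound_set_rejected(self):
        rows = [_triple_row("c", f"m{i}", "g") for i in range(5)]
        with pytest.raises(ValueError, match="universe"):
            score_pairs(pd.DataFrame(rows), universe_mirna_count=3)


class TestSelectTopPairs:
    def _pairs(self, rows):
        return pd.DataFrame(rows, columns=["circ_id", "mrna_id", "r", "p",
                                           "shared_mirnas", "n_shared",
                                           "score", "enrichment_p", "energy"])

    def test_undersized_input_returned_whole(self):
        pairs = self._pairs([("c1", "g1", .9, .01, "m", 1, 5.0, .1, -17.5)] * 5)
        assert len(select_top_pairs(pairs, 200)) == 5

    def test_tie_break_by_enrichment_then_ids(self):
        pairs = self._pairs([
            ("c2", "g1", .9, .01, "m", 1, 5.0, 0.2, -1.0),
            ("c1", "g2", .9, .01, "m", 1, 5.0, 0.1, -1.0),
            ("c1", "g1", .9, .01, "m", 1, 5.0, 0.2, -1.0),
        ])
        top = select_top_pairs(pairs, 3)
        assert list(zip(top["circ_id"], top["mrna_id"])) == [
            ("c1", "g2"), ("c1", "g1"), ("c2", "g1")]

    def test_top_1_is_global_best(self):
        pairs = self._pairs([
            ("c1", "g1", .9, .01, "m", 1, 2.0, .1, -1.0),
            ("c2", "g2", .9, .01, "m", 1, 7.0, .1, -1.0),
        ])
        top = select_top_pairs(pairs, 1)
        assert top["circ_id"].iloc[0] == "c2"


class TestBuildNetwork:
    def test_single_triple_minimal_network(self):
        triples = pd.DataFrame([_triple_row("c", "m", "g")])
        pairs = score_pairs(triples, 10)
        net = build_network(pairs, triples)
        assert net.number_of_nodes() == 3
        assert net.number_of_edges() == 2
        assert net.nodes["c"]["kind"] == "circRNA"
        assert net.edges["c", "m"]["relation"] == "sponge"

    def test_shared_mirna_hand_counted_degrees(self):
        triples = pd.DataFrame([_triple_row("c1", "m", "g1"),
                                _triple_row("c2", "m", "g2")])
        net = build_network(score_pairs(triples, 10), triples)
        assert net.number_of_nodes() == 5
        assert net.number_of_edges() == 4
        assert net.degree("m") == 4

    def test_circ_sponging_four_mirnas_has_degree_four(self):
        # the hub pattern: one circRNA acting as a ceRNA for four miRNAs
        triples = pd.DataFrame([_triple_row("hub", f"m{i}", f"g{i}")
                                for i in range(4)])
        net = build_network(score_pairs(triples, 10), triples)
        assert net.degree("hub") == 4
        assert core_circrnas(net, 1) == [("hub", 4)]

    def test_no_forbidden_edges(self):
        triples = pd.DataFrame([_triple_row(f"c{i}", f"m{i % 2}", f"g{i}")
                                for i in range(4)])
        net = build_network(score_pairs(triples, 10), triples)
        for u, v in net.edges:
            kinds = {net.nodes[u]["kind"], net.nodes[v]["kind"]}
            assert kinds in ({"circRNA", "miRNA"}, {"miRNA", "mRNA"})

    def test_empty_selection_warns_empty_network(self):
        with pytest.warns(UserWarning):
            net = build_network(pd.DataFrame(columns=["circ_id", "mrna_id"]),
                                pd.DataFrame())
        assert net.number_of_nodes() == 0


class TestExport:
    @pytest.fixture()
    def net(self):
        triples = pd.DataFrame([_triple_row("c1", "m", "g1"),
                                _triple_row("c2", "m", "g2")])
        return build_network(score_pairs(triples, 10), triples)

    def test_sif_lines(self, net, tmp_path):
        p = tmp_path / "net.sif"
        export_network(net, p, "sif")
        lines = p.read_text().strip().split("\n")
        assert len(lines) == 4
        assert all(len(line.split("\t")) == 3 for line in lines)

    def test_sif_round_trip_topology(self, net, tmp_path):
        p = tmp_path / "net.sif"
        export_network(net, p, "sif")
        back = read_network(p, "sif")
        assert set(back.edges) == set(net.edges)
        for u, v in net.edges:
            assert back.edges[u, v]["relation"] == net.edges[u, v]["relation"]

    def test_graphml_round_trip_attribute_identical(self, net, tmp_path):
        p = tmp_path / "net.graphml"
        export_network(net, p, "graphml")
        back = read_network(p, "graphml")
        assert set(back.nodes) == set(net.nodes)
        assert set(map(frozenset, back.edges)) == set(map(frozenset, net.edges))
        for node in net.nodes:
            assert back.nodes[node]["kind"] == net.nodes[node]["kind"]
        for u, v, d in net.edges(data=True):
            assert back.edges[u, v]["relation"] == d["relation"]
            assert back.edges[u, v]["r"] == pytest.approx(d["r"])
            assert back.edges[u, v]["score"] == pytest.approx(d["score"])

    def test_empty_edge_tsv_has_header_only(self, tmp_path):
        import networkx as nx
        p = tmp_path / "empty.tsv"
        export_network(nx.Graph(), p, "edge_tsv")
        assert p.read_text() == "source\trelation\ttarget\tr\tscore\n"

    def test_unknown_format_rejected(self, net, tmp_path):
        with pytest.raises(ValueError):
            export_network(net, tmp_path / "x", "gexf")
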