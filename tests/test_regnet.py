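import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cardionet.datatypes import DECallTable, EmergenceTable, pearson
from cardionet.de import call_de, classify_emergence
from cardionet.regnet import (Edge, build_network, cv_enrichment, hub_record,
                              mirna_target_edges, network_targets, rank_hubs,
                              suppression_edges, tf_mirna_edges,
                              tf_target_edges, validate_network)
from cardionet.suppression import SuppressionEvent

from conftest import TPS


def profiles_from(rng, names):
    return pd.DataFrame(rng.normal(size=(len(names), 5)), index=names,
                        columns=TPS)


def table(pairs):
    return pd.DataFrame(pairs, columns=["regulator", "target"])


class TestTfTargetEdges:
    def test_positive_and_negative_signs(self):
        profiles = pd.DataFrame(
            [[1, 2, 3, 4, 5], [2, 4, 6, 8, 10], [5, 4, 3, 2, 1]],
            index=["tf1", "gpos", "gneg"], columns=TPS, dtype=float)
        edges = tf_target_edges(profiles, {"tf1", "gpos", "gneg"},
                                table([("tf1", "gpos"), ("tf1", "gneg")]))
        by_target = {e.target: e for e in edges}
        assert by_target["gpos"].sign == 1
        assert by_target["gneg"].sign == -1

    def test_weak_pcc_no_edge(self, rng):
        profiles = pd.DataFrame([[1, 2, 3, 4, 5], [1, 5, 2, 4, 3]],
                                index=["tf1", "g1"], columns=TPS, dtype=float)
        assert tf_target_edges(profiles, {"tf1", "g1"},
                               table([("tf1", "g1")])) == []

    def test_non_de_excluded(self):
        profiles = pd.DataFrame([[1, 2, 3, 4, 5], [2, 4, 6, 8, 10]],
                                index=["tf1", "g1"], columns=TPS, dtype=float)
        assert tf_target_edges(profiles, {"tf1"}, table([("tf1", "g1")])) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        names = [f"f{i}" for i in range(20)]
        profiles = profiles_from(rng, names)
        pairs = [(a, b) for a in names for b in names
                 if a != b and rng.random() < 0.2]
        threshold = 0.6
        edges = tf_target_edges(profiles, set(names), table(pairs), threshold)
        got = {(e.source, e.target, e.sign) for e in edges}
        expected = set()
        for a, b in pairs:
            r = pearson(profiles.loc[a].to_numpy(), profiles.loc[b].to_numpy())
            if abs(r) >= threshold:
                expected.add((a, b, 1 if r > 0 else -1))
        assert got == expected


class TestMirnaTargetEdges:
    def test_negative_pair_in_table(self):
        profiles = pd.DataFrame([[1, 2, 3, 4, 5], [5, 4, 3, 2, 1]],
                                index=["m1", "g1"], columns=TPS, dtype=float)
        edges = mirna_target_edges(profiles, {"m1", "g1"},
                                   table([("m1", "g1")]))
        assert len(edges) == 1 and edges[0].sign == -1

    def test_negative_pair_not_in_table(self):
        profiles = pd.DataFrame([[1, 2, 3, 4, 5], [5, 4, 3, 2, 1]],
                                index=["m1", "g1"], columns=TPS, dtype=float)
        assert mirna_target_edges(profiles, {"m1", "g1"}, table([])) == []

    def test_positive_correlation_no_edge(self):
        profiles = pd.DataFrame([[1, 2, 3, 4, 5], [2, 4, 6, 8, 10]],
                                index=["m1", "g1"], columns=TPS, dtype=float)
        assert mirna_target_edges(profiles, {"m1", "g1"},
                                  table([("m1", "g1")])) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        names = [f"f{i}" for i in range(15)]
        profiles = profiles_from(rng, names)
        pairs = [(a, b) for a in names for b in names
                 if a != b and rng.random() < 0.3]
        threshold = 0.6
        edges = mirna_target_edges(profiles, set(names), table(pairs),
                                   threshold)
        got = {(e.source, e.target) for e in edges}
        expected = {(a, b) for a, b in pairs
                    if pearson(profiles.loc[a].to_numpy(),
                               profiles.loc[b].to_numpy()) <= -threshold}
        assert got == expected


class TestTfMirnaEdges:
    def _profiles(self, r_tab, r_sham):
        # construct pairs with controllable correlation via shared signal
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        tab = pd.DataFrame({"tf1": base, "m1": r_tab * base
                            + (1 - abs(r_tab)) * np.array([3, 1, 4, 1, 5])},
                           index=TPS).T
        sham = pd.DataFrame({"tf1": base, "m1": r_sham * base
                             + (1 - abs(r_sham)) * np.array([3, 1, 4, 1, 5])},
                            index=TPS).T
        return tab, sham

    def test_treatment_specific_edge(self):
        tab, sham = self._profiles(1.0, 0.0)
        edges = tf_mirna_edges(tab, sham, {"tf1"}, {"m1"})
        assert len(edges) == 1
        assert edges[0].source == "tf1" and edges[0].target == "m1"
        assert edges[0].sign == 1

    def test_correlated_in_both_conditions_no_edge(self):
        tab, sham = self._profiles(1.0, 1.0)
        assert tf_mirna_edges(tab, sham, {"tf1"}, {"m1"}) == []

    def test_specificity_flag_off(self):
        tab, sham = self._profiles(1.0, 1.0)
        edges = tf_mirna_edges(tab, sham, {"tf1"}, {"m1"},
                               treatment_specific=False)
        assert len(edges) == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        tfs = [f"tf{i}" for i in range(6)]
        mirnas = [f"m{i}" for i in range(6)]
        tab = profiles_from(rng, tfs + mirnas)
        sham = profiles_from(rng, tfs + mirnas)
        threshold = 0.5
        edges = tf_mirna_edges(tab, sham, set(tfs), set(mirnas), threshold)
        got = {(e.source, e.target) for e in edges}
        expected = set()
        for tf in tfs:
            for m in mirnas:
                r_t = pearson(tab.loc[tf].to_numpy(), tab.loc[m].to_numpy())
                r_s = pearson(sham.loc[tf].to_numpy(), sham.loc[m].to_numpy())
                if r_t >= threshold and r_s < threshold:
                    expected.add((tf, m))
        assert got == expected


def classes_for(nodes):
    def clazz(n):
        if n.startswith("tf"):
            return "tf"
        if n.startswith("m"):
            return "mirna"
        return "gene"
    return pd.Series({n: clazz(n) for n in nodes})


class TestBuildNetwork:
    def test_empty(self):
        net = build_network([], classes_for([]))
        assert net.number_of_nodes() == 0

    def test_dangling_endpoint_errors(self):
        with pytest.raises(ValueError, match="ghost"):
            build_network([Edge("tf1", "ghost", "tf_target", 1, 0.95)],
                          classes_for(["tf1"]))

    def test_duplicate_pair_collapses(self):
        nodes = classes_for(["m1", "tf1"])
        edges = [Edge("m1", "tf1", "mirna_target", -1, -0.95),
                 Edge("m1", "tf1", "suppression", -1, float("nan"))]
        net = build_network(edges, nodes)
        assert net.number_of_edges() == 1
        assert net.edges["m1", "tf1"]["etype"] == "mirna_target"

    def test_star_regulator_mostly_positive(self):
        # a single TF with 30 targets, ~75% positively regulated
        targets = [f"g{i:02d}" for i in range(30)]
        edges = [Edge("tf1", g, "tf_target", 1 if i < 22 else -1, 0.95)
                 for i, g in enumerate(targets)]
        net = build_network(edges, classes_for(["tf1"] + targets))
        record = hub_record(net, "tf1")
        assert record.outward == 30
        assert record.inward == 0
        assert record.outward_pos / record.outward == pytest.approx(22 / 30)

    def test_round_trip_serialization(self, tmp_path, rng):
        from cardionet import io as cio
        names = [f"tf{i}" for i in range(5)] + [f"g{i}" for i in range(5)]
        edges = [Edge(f"tf{i}", f"g{i}", "tf_target", 1, 0.91 + 0.01 * i)
                 for i in range(5)]
        path = cio.write_edge_list(edges, tmp_path / "edges.tsv")
        back = cio.read_edge_list(path)
        assert [(e.source, e.target, e.etype, e.sign, e.pcc) for e in back] \
            == [(e.source, e.target, e.etype, e.sign, e.pcc) for e in edges]

    def test_validator_accepts_consistent_network(self, rng):
        profiles = pd.DataFrame([[1, 2, 3, 4, 5], [2, 4, 6, 8, 10]],
                                index=["tf1", "g1"], columns=TPS, dtype=float)
        edges = tf_target_edges(profiles, {"tf1", "g1"},
                                table([("tf1", "g1")]))
        net = build_network(edges, classes_for(["tf1", "g1"]))
        validate_network(net, profiles, tf_table=table([("tf1", "g1")]))

    def test_validator_rejects_weak_edge(self):
        profiles = pd.DataFrame([[1, 2, 3, 4, 5], [1, 5, 2, 4, 3]],
                                index=["tf1", "g1"], columns=TPS, dtype=float)
        net = build_network([Edge("tf1", "g1", "tf_target", 1, 0.99)],
                            classes_for(["tf1", "g1"]))
        with pytest.raises(ValueError):
            validate_network(net, profiles)


class TestHubs:
    def _emergence(self, mapping):
        return EmergenceTable(pd.Series(mapping), {}, {}, tuple(TPS))

    def test_bookkeeping_identities(self):
        # one regulator with outward 53 (43 pos, 10 neg), inward 11 (5, 6)
        edges = []
        for i in range(43):
            edges.append(Edge("tf1", f"g{i:03d}", "tf_target", 1, 0.95))
        for i in range(43, 53):
            edges.append(Edge("tf1", f"g{i:03d}", "tf_target", -1, -0.95))
        for i in range(5):
            edges.append(Edge(f"m{i}", "tf1", "tf_mirna", 1, 0.95))
        for i in range(5, 11):
            edges.append(Edge(f"m{i}", "tf1", "suppression", -1, float("nan")))
        nodes = classes_for(["tf1"] + [f"g{i:03d}" for i in range(53)]
                            + [f"m{i}" for i in range(11)])
        net = build_network(edges, nodes)
        h = hub_record(net, "tf1")
        assert (h.total, h.outward, h.outward_pos, h.outward_neg,
                h.inward, h.inward_pos, h.inward_neg) == (64, 53, 43, 10, 11, 5, 6)

    def test_edgeless_regulator_rankable(self):
        net = build_network([Edge("tf1", "g1", "tf_target", 1, 0.95)],
                            classes_for(["tf1", "g1", "tf2"]))
        net.add_node("tf2", clazz="tf", cv=False, first_emergence="d3")
        emergence = self._emergence({"tf1": "d3", "tf2": "d3"})
        hubs = rank_hubs(net, emergence)
        names = [h.regulator for h in hubs["d3"]["tf"]]
        assert names == ["tf1", "tf2"]
        assert hubs["d3"]["tf"][1].total == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_ranking_matches_sort_oracle(self, seed):
        rng = np.random.default_rng(seed)
        tfs = [f"tf{i}" for i in range(12)]
        genes = [f"g{i}" for i in range(40)]
        edges = []
        for tf in tfs:
            for g in genes:
                if rng.random() < 0.2:
                    edges.append(Edge(tf, g, "tf_target",
                                      1 if rng.random() < 0.7 else -1, 0.95))
        nodes = classes_for(tfs + genes)
        emergence = self._emergence(
            {tf: TPS[rng.integers(0, 5)] for tf in tfs})
        net = build_network(edges, nodes, emergence=emergence)
        hubs = rank_hubs(net, emergence, k_tf=3)
        for t in TPS:
            cohort = [tf for tf in tfs
                      if emergence.first_emergence.get(tf) == t
                      and tf in net]
            degs = sorted(((net.degree(tf), tf) for tf in cohort),
                          key=lambda x: (-x[0], x[1]))
            expected = [tf for _, tf in degs[:3]]
            assert [h.regulator for h in hubs[t]["tf"]] == expected

    def test_hub_identities_hold_for_all_nodes(self, planted_dataset):
        from cardionet.preprocess import compute_fold_changes
        dataset, truth = planted_dataset
        fc = compute_fold_changes(dataset)
        calls = call_de(fc)
        emergence = classify_emergence(calls)
        profiles = dataset.condition("TAB")
        de = set(calls.de_features())
        edges = tf_target_edges(profiles, de,
                                table(truth.tf_target_pairs))
        edges += mirna_target_edges(profiles, de,
                                    table(truth.mirna_target_pairs))
        net = build_network(edges, dataset.classes, emergence=emergence)
        for node in net.nodes:
            h = hub_record(net, node)
            assert h.total == h.outward + h.inward
            assert h.outward == h.outward_pos + h.outward_neg
            assert h.inward == h.inward_pos + h.inward_neg


class TestCvEnrichment:
    def test_all_cv_proportion_one(self):
        prop, p = cv_enrichment({"a", "b"}, {"a", "b", "c"},
                                {"a", "b", "c", "d"})
        assert prop == 1.0

    def test_background_composition_p_large(self):
        background = {f"g{i}" for i in range(100)}
        cv = {f"g{i}" for i in range(20)}
        targets = {f"g{i}" for i in range(0, 100, 5)}  # exactly 20% CV
        prop, p = cv_enrichment(targets, cv, background)
        assert prop == pytest.approx(0.2)
        assert p >= 0.3

    def test_matches_exhaustive_enumeration(self):
        # 5-of-10 targets CV, background 20-of-100
        M, K, n, k = 100, 20, 10, 5
        background = [f"g{i}" for i in range(M)]
        cv = set(background[:K])
        targets = set(background[:k]) | set(background[K:K + (n - k)])
        prop, p = cv_enrichment(targets, cv, set(background))
        expected = sum(
            math.comb(K, j) * math.comb(M - K, n - j) / math.comb(M, n)
            for j in range(k, min(K, n) + 1))
        assert prop == pytest.approx(0.5)
        assert p == pytest.approx(expected, rel=1e-12)

    def test_empty_background_errors(self):
        with pytest.raises(ValueError):
            cv_enrichment({"a"}, {"a"}, set())


class TestNetworkTargets:
    def test_targets_are_inward_nodes(self):
        edges = [Edge("tf1", "g1", "tf_target", 1, 0.95),
                 Edge("m1", "g2", "mirna_target", -1, -0.95)]
        net = build_network(edges, classes_for(["tf1", "g1", "m1", "g2"]))
        assert network_targets(net) == {"g1", "g2"}

    def test_suppression_edges_collapse_per_pair(self):
        events = [SuppressionEvent("m1", "tf1", "d3"),
                  SuppressionEvent("m1", "tf1", "d5"),
                  SuppressionEvent("m1", "tf2", "d3")]
        edges = suppression_edges(events)
        assert [(e.source, e.target) for e in edges] == \
            [("m1", "tf1"), ("m1", "tf2")]
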