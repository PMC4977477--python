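import itertools
import math

import networkx as nx
import numpy as np
import pytest

from ancfold.energy import EnergyModel
from ancfold.protein_model import Conformation
from ancfold.roadmap import (BuildConfig, Roadmap, RoadmapError,
                             SSFODistribution, _dijkstra_path, dominant_order,
                             extract_folding_pathways, max_shift,
                             method_report, orders_agree, pathway_quality,
                             segment_formation_fractions, ssfo_of_path)


def toy_roadmap(topo, edges, native="native", unfolded=("u",)):
    rm = Roadmap(topo=topo, native_id=native)
    ids = {u for e in edges for u in e[:2]} | {native} | set(unfolded)
    for cid in sorted(ids):
        rm.add_node(Conformation(torsions=np.zeros(topo.n_torsions), id=cid,
                                 energy=1.0))
    for u, v, w in edges:
        rm.add_edge(u, v, w, "m", 1)
    rm.unfolded_ids = tuple(unfolded)
    return rm


class TestPathExtraction:
    def test_three_node_hand_example(self, helix_topo):
        rm = toy_roadmap(helix_topo, [("u", "a", 1.0), ("a", "native", 1.0),
                                      ("u", "native", 3.0)])
        (path, weight), = extract_folding_pathways(rm)
        assert path == ["u", "a", "native"]
        assert weight == 2.0

    def test_single_edge_graph(self, helix_topo):
        rm = toy_roadmap(helix_topo, [("u", "native", 0.5)])
        (path, weight), = extract_folding_pathways(rm)
        assert path == ["u", "native"] and weight == 0.5

    def test_unreachable_unfolded_state_skipped(self, helix_topo):
        rm = toy_roadmap(helix_topo, [("u", "native", 1.0)],
                         unfolded=("u", "island"))
        pathways = extract_folding_pathways(rm)
        assert len(pathways) == 1

    def test_matches_exhaustive_enumeration_on_random_graphs(self, helix_topo):
        """Dijkstra path weight equals brute-force enumeration over all
        simple paths on random digraphs with <= 8 nodes."""
        rng = np.random.default_rng(23)
        for trial in range(40):
            n = int(rng.integers(3, 9))
            nodes = [f"n{i}" for i in range(n)]
            g = nx.DiGraph()
            g.add_nodes_from(nodes)
            for u, v in itertools.permutations(nodes, 2):
                if rng.random() < 0.4:
                    g.add_edge(u, v, weight=float(rng.uniform(0.0, 5.0)))
            src, dst = nodes[0], nodes[-1]
            res = _dijkstra_path(g, src, dst)
            best = math.inf
            for r in range(n - 1):
                for mid in itertools.permutations(nodes[1:-1], r):
                    cand = (src, *mid, dst)
                    if all(g.has_edge(u, v) for u, v in zip(cand, cand[1:])):
                        best = min(best, sum(g[u][v]["weight"]
                                             for u, v in zip(cand, cand[1:])))
            if res is None:
                assert math.isinf(best)
            else:
                assert res[1] == pytest.approx(best, rel=1e-12)


class TestSSFO:
    def _staged_path(self, topo, order):
        """Conformations walking unfolded -> native, forming helices in the
        given order (checked independently via formation fractions)."""
        native = topo.native_conformation()
        unfolded = Conformation(torsions=np.full(topo.n_torsions, 180.0),
                                id="u")
        mid_t = np.full(topo.n_torsions, 180.0)
        first = next(s for s in topo.native_segments if s.label == order[0])
        for i in first.residues:
            mid_t[2 * i] = native.torsions[2 * i]
            mid_t[2 * i + 1] = native.torsions[2 * i + 1]
        mid = Conformation(torsions=mid_t, id="mid")
        return [unfolded, mid, native]

    def test_formation_fractions_native_vs_extended(self, two_helix_topo, model):
        native_fracs = segment_formation_fractions(
            two_helix_topo, model, two_helix_topo.native_conformation())
        assert all(f == 1.0 for f in native_fracs.values())
        ext = Conformation(torsions=np.full(two_helix_topo.n_torsions, 180.0),
                           id="ext")
        ext_fracs = segment_formation_fractions(two_helix_topo, model, ext)
        assert all(f < 0.7 for f in ext_fracs.values())

    @pytest.mark.parametrize("order", [("a1", "a2"), ("a2", "a1")])
    def test_constructed_formation_orders(self, two_helix_topo, model, order):
        path = self._staged_path(two_helix_topo, order)
        assert ssfo_of_path(two_helix_topo, model, path) == order

    def test_native_only_path_ties_to_native_order(self, two_helix_topo, model):
        path = [two_helix_topo.native_conformation()]
        assert ssfo_of_path(two_helix_topo, model, path) == ("a1", "a2")

    def test_dominant_order_and_agreement(self):
        dist = SSFODistribution(percentages={("a1", "a2"): 60.0,
                                             ("a2", "a1"): 40.0},
                                pathway_count=10)
        assert dominant_order(dist) == ("a1", "a2")
        assert orders_agree(("a1", "a2"), "A1, a2")
        assert not orders_agree(("a1", "a2"), "a2,a1")
        with pytest.raises(RoadmapError):
            dominant_order(SSFODistribution(percentages={}, pathway_count=0))

    def test_stability_shift_boundary(self):
        a = SSFODistribution(percentages={("x",): 70.0, ("y",): 30.0},
                             pathway_count=10)
        b = SSFODistribution(percentages={("x",): 40.0, ("y",): 60.0},
                             pathway_count=10)
        assert max_shift(a, a) == 0.0
        assert max_shift(a, b) == pytest.approx(30.0)  # exactly 30 -> stable
        c = SSFODistribution(percentages={("z",): 100.0}, pathway_count=4)
        assert max_shift(a, c) == pytest.approx(100.0)


class TestQualityAndReport:
    def test_quality_hand_examples(self, helix_topo):
        rm = toy_roadmap(helix_topo, [("u", "a", 1.0), ("a", "native", 2.0)])
        pathways = extract_folding_pathways(rm)
        assert pathway_quality(rm, pathways) == 3.0  # dominance 1 each
        # the same edge on two pathways counts twice
        rm2 = toy_roadmap(helix_topo, [("u", "a", 0.0), ("v", "a", 0.0),
                                       ("a", "native", 2.0)],
                          unfolded=("u", "v"))
        pw2 = extract_folding_pathways(rm2)
        assert pathway_quality(rm2, pw2) == 4.0
        assert pathway_quality(rm2, []) == 0.0

    def test_method_report_matches_raw_rescan(self, helix_topo):
        from ancfold.anc import AttemptRecord
        rm = toy_roadmap(helix_topo, [("u", "native", 1.0)])
        stream = [("m1", True, 2.0), ("m1", False, 7.0), ("m2", True, 3.0),
                  ("m1", True, 1.0), ("m2", False, 4.0)]
        for i, (mid, ok, cost) in enumerate(stream, start=1):
            rm.history._step = i - 1
            rm.history.append(AttemptRecord("u", mid, 0.0, cost, i, ok,
                                            1.0 if ok else math.inf))
        rm.selections = [("u", "m1"), ("v", "m2"), ("w", "m1"), ("x", "m1")]
        rep = method_report(rm)
        assert rep.success_rate["m1"] == pytest.approx(2 / 3)
        assert rep.success_rate["m2"] == pytest.approx(1 / 2)
        assert rep.usage_percent["m1"] == pytest.approx(75.0)
        assert rep.usage_percent["m2"] == pytest.approx(25.0)
        assert rep.total_cost["m1"] == pytest.approx(10.0)
        assert sum(rep.usage_percent.values()) == pytest.approx(100.0)

    def test_ten_attempts_four_edges_rate(self, helix_topo):
        from ancfold.anc import AttemptRecord
        rm = toy_roadmap(helix_topo, [("u", "native", 1.0)])
        for i in range(10):
            rm.history._step = i
            rm.history.append(AttemptRecord("u", "m", 0.0, 1.0, i + 1, i < 4,
                                            1.0 if i < 4 else math.inf))
        rep = method_report(rm)
        assert rep.success_rate["m"] == pytest.approx(0.4)


class TestSerialization:
    def test_round_trip_preserves_graph_and_quality(self, helix_topo):
        rm = toy_roadmap(helix_topo, [("u", "a", 1.25), ("a", "native", 0.75),
                                      ("u", "native", 9.0)])
        text = rm.to_json()
        back = Roadmap.from_json(text, helix_topo)
        assert set(back.nodes) == set(rm.nodes)
        assert sorted(back.graph.edges(data="weight")) == \
            sorted(rm.graph.edges(data="weight"))
        pw = extract_folding_pathways(rm)
        assert pathway_quality(back, extract_folding_pathways(back)) == \
            pathway_quality(rm, pw)
        assert back.to_json() == text  # serialization is a fixed point

    def test_edge_validation(self, helix_topo):
        rm = toy_roadmap(helix_topo, [])
        with pytest.raises(ValueError):
            rm.add_edge("u", "u", 1.0, "m", 1)
        with pytest.raises(ValueError):
            rm.add_edge("u", "native", math.inf, "m", 1)
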