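"""Weighted-network assembly, localization-ordered path search, permutation
significance and network merging."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from spnkit.datamodel import (
    LOCALIZATION_INDEX,
    AnnotationRecord,
    ExpressionMatrix,
    InteractionEdge,
    LocalizationRecord,
    PipelineConfig,
)
from spnkit.network import (
    PathSegment,
    build_weighted_network,
    compute_coexpression,
    geometric_mean_score,
    merge_to_spn,
    search_segments,
    segment_significance,
)

LOCS = ["extracellular", "membrane", "cytoplasm", "nucleus"]


class TestCoexpression:
    def _expr(self):
        x = np.array([1.0, 2.0, 4.0, 3.0, 5.0])
        df = pd.DataFrame(np.c_[x, -x, np.full(5, 2.0)].T,
                          index=["A", "B", "C"], columns=[f"S{i}" for i in range(5)])
        return ExpressionMatrix(df)

    def test_self_correlation_is_one(self):
        r = compute_coexpression(self._expr(), [("A", "A")])
        assert r[("A", "A")] == 1.0

    def test_exact_anticorrelation(self):
        r = compute_coexpression(self._expr(), [("A", "B")])
        assert r[("A", "B")] == pytest.approx(-1.0)

    def test_zero_variance_gene_missing(self):
        r = compute_coexpression(self._expr(), [("A", "C")])
        assert math.isnan(r[("A", "C")])

    def test_too_few_shared_samples_missing(self):
        df = pd.DataFrame(
            [[1.0, np.nan, np.nan, 4.0], [np.nan, 2.0, 3.0, 1.0]],
            index=["A", "B"], columns=list("wxyz"),
        )
        r = compute_coexpression(ExpressionMatrix(df), [("A", "B")])
        assert math.isnan(r[("A", "B")])


def make_graph(edge_spec, loc, seeds=(), weights=None, reliability=0.5):
    """Small helper: edge_spec list of pairs, loc dict node->set, seeds list."""
    g = nx.Graph()
    for n, l in loc.items():
        g.add_node(n, localization=frozenset(l),
                   seed_class="hot" if n in seeds else "none")
    for i, (u, v) in enumerate(edge_spec):
        w = weights[i] if weights is not None else reliability
        g.add_edge(u, v, weight=w, reliability=reliability,
                   coexpression_r=0.5, source="known")
    return g


class TestBuildNetwork:
    def _inputs(self):
        edges = [
            InteractionEdge("A", "B", "known", 1.0),
            InteractionEdge("B", "C", "predicted", 0.4),
            InteractionEdge("A", "D", "known", 0.8),
        ]
        locs = [
            LocalizationRecord("A", frozenset({"membrane"})),
            LocalizationRecord("B", frozenset({"cytoplasm"})),
            LocalizationRecord("C", frozenset({"nucleus"})),
            LocalizationRecord("D", frozenset({"nucleus"})),
        ]
        annots = [
            AnnotationRecord("A", frozenset({"T1"})),
            AnnotationRecord("B", frozenset({"T1"})),
            AnnotationRecord("C", frozenset({"T2"})),
        ]
        return edges, locs, annots

    def test_maximal_weight_is_one(self):
        edges, locs, annots = self._inputs()
        net = build_weighted_network(
            edges[:1], locs, annots, {("A", "B"): 1.0}, {"A": "hot"},
        )
        assert net.edges["A", "B"]["weight"] == pytest.approx(1.0)

    def test_incompatible_localization_edge_removed(self):
        edges, locs, annots = self._inputs()
        net = build_weighted_network(edges, locs, annots, {}, {})
        assert not net.has_edge("A", "D")  # membrane-only vs nucleus-only
        assert net.has_edge("A", "B") and net.has_edge("B", "C")

    def test_missing_r_renormalizes_not_penalizes(self):
        edges, locs, annots = self._inputs()
        cfg = PipelineConfig(score_weights=(0.4, 0.4, 0.2))
        net = build_weighted_network(
            edges[:1], locs, annots, {}, {}, cfg
        )
        # reliability 1.0, Jaccard("A","B") = 1.0, r missing:
        # (0.4*1 + 0.2*1) / 0.6 = 1.0
        assert net.edges["A", "B"]["weight"] == pytest.approx(1.0)

    def test_weights_invariant_under_relabeling(self):
        edges, locs, annots = self._inputs()
        r = {("A", "B"): 0.3, ("B", "C"): -0.6}
        net = build_weighted_network(edges, locs, annots, r, {})
        ren = {"A": "Z", "B": "Y", "C": "X", "D": "W"}
        edges2 = [InteractionEdge(ren[e.gene_a], ren[e.gene_b], e.source, e.reliability)
                  for e in edges]
        locs2 = [LocalizationRecord(ren[l.gene_id], l.compartments) for l in locs]
        annots2 = [AnnotationRecord(ren[a.gene_id], a.terms) for a in annots]
        r2 = {tuple(sorted((ren[a], ren[b]))): v for (a, b), v in r.items()}
        net2 = build_weighted_network(edges2, locs2, annots2, r2, {})
        for u, v, d in net.edges(data=True):
            u2, v2 = ren[u], ren[v]
            assert net2.edges[u2, v2]["weight"] == pytest.approx(d["weight"])

    def test_unreachable_seed_reported(self):
        edges, locs, annots = self._inputs()
        net = build_weighted_network(edges, locs, annots, {}, {"GHOST": "hot"})
        assert net.graph["unreachable_seeds"] == ["GHOST"]


def exhaustive_segments(g, cfg):
    """Oracle: enumerate every simple path by brute force over all node
    sequences reachable via edges, then filter with an independent validity
    check based on explicit compartment assignments."""
    seeds = {n for n, d in g.nodes(data=True) if d.get("seed_class", "none") != "none"}
    found = {}
    for source in g.nodes:
        stack = [[source]]
        while stack:
            path = stack.pop()
            if 2 <= len(path) <= cfg.max_segment_length + 1 and _valid(g, path, seeds):
                key = min(tuple(path), tuple(reversed(path)))
                if key not in found:
                    found[key] = PathSegment(tuple(path), geometric_mean_score(g, path))
            if len(path) <= cfg.max_segment_length:
                for nb in g.neighbors(path[-1]):
                    if nb not in path:
                        stack.append(path + [nb])
    return sorted(found.values(), key=lambda s: (-s.score, s.nodes))


def _valid(g, path, seeds):
    if path[0] not in seeds or path[-1] not in seeds:
        return False
    levels = [
        {LOCALIZATION_INDEX[c] for c in g.nodes[n]["localization"]} for n in path
    ]
    start_ok = levels[0] & {0, 1}
    end_ok = 3 in levels[-1]
    if not (start_ok and end_ok):
        return False
    # existence of a nondecreasing assignment with first level in {0,1} and
    # last level = nucleus, by explicit product search on small paths
    choices = [sorted(l) for l in levels]
    for combo in itertools.product(*choices):
        if combo[0] not in (0, 1) or combo[-1] != 3:
            continue
        if all(a <= b for a, b in zip(combo, combo[1:])):
            return True
    return False


def random_localized_graph(seed, n=25, p=0.15, seed_frac=0.35):
    rng = np.random.default_rng(seed)
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
    for node in g.nodes:
        k = int(rng.integers(1, 3))
        g.nodes[node]["localization"] = frozenset(
            rng.choice(LOCS, size=k, replace=False)
        )
        g.nodes[node]["seed_class"] = "hot" if rng.random() < seed_frac else "none"
    for u, v in g.edges:
        g.edges[u, v]["weight"] = float(rng.uniform(0.1, 1.0))
        g.edges[u, v]["reliability"] = 0.5
        g.edges[u, v]["coexpression_r"] = float(rng.uniform(-1, 1))
        g.edges[u, v]["source"] = "known"
    return g


class TestSearch:
    def test_single_planted_path_hand_score(self):
        g = make_graph(
            [("A", "B"), ("B", "C"), ("C", "D")],
            {"A": {"membrane"}, "B": {"cytoplasm"}, "C": {"cytoplasm"}, "D": {"nucleus"}},
            seeds={"A", "D"},
            weights=[0.9, 0.6, 0.8],
        )
        segs = search_segments(g, PipelineConfig(max_segment_length=4))
        assert len(segs) == 1
        assert segs[0].nodes in (("A", "B", "C", "D"), ("D", "C", "B", "A"))
        assert segs[0].score == pytest.approx((0.9 * 0.6 * 0.8) ** (1 / 3))

    def test_localization_order_blocks_backtracking(self):
        # nucleus-localized interior node blocks continuing to a cytoplasm one
        g = make_graph(
            [("A", "N"), ("N", "B"), ("B", "D")],
            {"A": {"membrane"}, "N": {"nucleus"}, "B": {"cytoplasm"}, "D": {"nucleus"}},
            seeds={"A", "D"},
        )
        segs = search_segments(g, PipelineConfig(max_segment_length=5))
        assert [s.nodes for s in segs] == []

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_enumeration(self, seed):
        g = random_localized_graph(seed)
        cfg = PipelineConfig(max_segment_length=4)
        fast = {s.canonical(): s.score for s in search_segments(g, cfg)}
        slow = {s.canonical(): s.score for s in exhaustive_segments(g, cfg)}
        assert fast.keys() == slow.keys()
        for k in fast:
            assert fast[k] == pytest.approx(slow[k])

    def test_longer_limit_only_adds_segments(self):
        g = random_localized_graph(123)
        short = {s.canonical() for s in search_segments(g, PipelineConfig(max_segment_length=3))}
        long = {s.canonical() for s in search_segments(g, PipelineConfig(max_segment_length=5))}
        assert short <= long

    def test_score_reversal_invariant(self):
        g = random_localized_graph(7)
        for s in search_segments(g, PipelineConfig(max_segment_length=4))[:20]:
            assert geometric_mean_score(g, s.nodes[::-1]) == pytest.approx(s.score)

    def test_no_membrane_seeds_warns_empty(self, caplog):
        g = make_graph(
            [("A", "B")], {"A": {"cytoplasm"}, "B": {"nucleus"}}, seeds={"A", "B"},
        )
        with caplog.at_level("WARNING"):
            assert search_segments(g, PipelineConfig()) == []
        assert any("membrane" in r.message for r in caplog.records)


class TestSignificance:
    def test_planted_high_weight_path_retained(self):
        # strong planted chain (0.9) among weak background (0.2)
        rng = np.random.default_rng(5)
        g = nx.barabasi_albert_graph(60, 2, seed=3)
        g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
        for node in g.nodes:
            g.nodes[node]["localization"] = frozenset(
                {LOCS[int(rng.integers(0, 4))]}
            )
            g.nodes[node]["seed_class"] = "none"
        for u, v in g.edges:
            g.edges[u, v].update(weight=0.2, reliability=0.2, coexpression_r=0.0,
                                 source="known")
        path = ["P0", "P1", "P2", "P3"]
        locs = [{"membrane"}, {"cytoplasm"}, {"cytoplasm"}, {"nucleus"}]
        for n, l in zip(path, locs):
            g.add_node(n, localization=frozenset(l), seed_class="none")
        g.nodes["P0"]["seed_class"] = "hot"
        g.nodes["P3"]["seed_class"] = "cold"
        for u, v in zip(path, path[1:]):
            g.add_edge(u, v, weight=0.9, reliability=0.9, coexpression_r=0.8,
                       source="known")
        # planted nodes also carry weak background edges, as in real networks
        background = list(g.nodes)[:8]
        for i, n in enumerate(path):
            for b in background[2 * i: 2 * i + 2]:
                g.add_edge(n, b, weight=0.2, reliability=0.2, coexpression_r=0.0,
                           source="known")
        cfg = PipelineConfig(max_segment_length=4, permutations_B=999, alpha_segment=0.01)
        segs = search_segments(g, cfg)
        retained = segment_significance(segs, g, cfg, np.random.default_rng(77))
        assert any(set(s.nodes) == set(path) for s in retained)

    def test_p_lower_bound_add_one(self):
        # even a path that beats every null draw gets p = 1/(B+1), never 0
        g = make_graph(
            [("A", "B"), ("B", "C"), ("A", "B2"), ("B2", "C2"), ("B2", "C")],
            {"A": {"membrane"}, "B": {"cytoplasm"}, "B2": {"cytoplasm"},
             "C": {"nucleus"}, "C2": {"nucleus"}},
            seeds={"A", "C"}, weights=[0.99, 0.99, 0.1, 0.1, 0.1],
        )
        cfg = PipelineConfig(max_segment_length=2, permutations_B=99, alpha_segment=0.5)
        retained = segment_significance(search_segments(g, cfg), g, cfg, 1)
        assert retained
        assert all(s.p_value >= 1 / (99 + 1) for s in retained)
        best = min(retained, key=lambda s: s.p_value)
        assert set(best.nodes) == {"A", "B", "C"}

    def test_equal_weights_tie_never_significant(self):
        # every null walk ties the observed score; add-one rule forces p = 1
        g = random_localized_graph(9)
        for u, v in g.edges:
            g.edges[u, v]["weight"] = 0.5
        cfg = PipelineConfig(max_segment_length=3, permutations_B=199, alpha_segment=0.01)
        segs = search_segments(g, cfg)
        assert segs
        assert segment_significance(segs, g, cfg, 2) == []

    def test_impossible_null_length_raises(self):
        g = make_graph(
            [("A", "B")], {"A": {"membrane"}, "B": {"nucleus"}}, seeds={"A", "B"},
        )
        seg = PathSegment(("A", "B", "XX", "YY"), 0.5)  # 3 edges, unrealizable
        cfg = PipelineConfig(permutations_B=200)
        with pytest.raises(ValueError, match="null paths"):
            segment_significance([seg], g, cfg, 0)


class TestMerge:
    def _retained(self, g, cfg=None):
        # merge semantics are independent of the significance filter; feed the
        # scored candidates straight through
        cfg = cfg or PipelineConfig(max_segment_length=4)
        return search_segments(g, cfg)

    def test_union_of_overlapping_segments(self):
        g = make_graph(
            [("A", "B"), ("B", "C"), ("B", "D")],
            {"A": {"membrane"}, "B": {"cytoplasm"},
             "C": {"nucleus"}, "D": {"nucleus"}},
            seeds={"A", "C", "D"},
        )
        retained = self._retained(g)
        assert len(retained) == 2
        spn = merge_to_spn(retained, g, hot_genes={"A"}, cold_genes={"C"})
        # two 3-node segments sharing the A-B stem: 3 + 3 - 2 shared = 4 nodes
        assert spn.number_of_nodes() == 4
        assert spn.number_of_edges() == 3

    def test_node_colors_follow_windows(self):
        g = make_graph(
            [("A", "B"), ("B", "C")],
            {"A": {"membrane"}, "B": {"cytoplasm"}, "C": {"nucleus"}},
            seeds={"A", "C"},
        )
        spn = merge_to_spn(self._retained(g), g, hot_genes={"A"}, cold_genes={"C"})
        assert spn.nodes["A"]["color"] == "red"
        assert spn.nodes["C"]["color"] == "blue"
        assert spn.nodes["B"]["color"] == "pink"

    def test_hot_and_cold_conflict_is_red_and_logged(self, caplog):
        g = make_graph(
            [("A", "B"), ("B", "C")],
            {"A": {"membrane"}, "B": {"cytoplasm"}, "C": {"nucleus"}},
            seeds={"A", "C"},
        )
        with caplog.at_level("WARNING"):
            spn = merge_to_spn(self._retained(g), g, hot_genes={"A"}, cold_genes={"A"})
        assert spn.nodes["A"]["color"] == "red"
        assert any("both" in r.message for r in caplog.records)

    def test_edge_sign_colors_and_missing_r(self, caplog):
        g = make_graph(
            [("A", "B"), ("B", "C")],
            {"A": {"membrane"}, "B": {"cytoplasm"}, "C": {"nucleus"}},
            seeds={"A", "C"},
        )
        g.edges["A", "B"]["coexpression_r"] = -0.5
        g.edges["B", "C"]["coexpression_r"] = math.nan
        with caplog.at_level("INFO"):
            spn = merge_to_spn(self._retained(g), g, set(), set())
        assert spn.edges["A", "B"]["color"] == "green"
        assert spn.edges["B", "C"]["color"] == "gray"

    def test_predicted_edges_dashed(self):
        g = make_graph(
            [("A", "B"), ("B", "C")],
            {"A": {"membrane"}, "B": {"cytoplasm"}, "C": {"nucleus"}},
            seeds={"A", "C"},
        )
        g.edges["B", "C"]["source"] = "predicted"
        spn = merge_to_spn(self._retained(g), g, set(), set())
        assert spn.edges["A", "B"]["style"] == "solid"
        assert spn.edges["B", "C"]["style"] == "dashed"
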