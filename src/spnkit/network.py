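"""Weighted-network construction and signaling pathway segment discovery.

The integrated network carries, per edge, interaction reliability, the
Pearson coexpression r of the two genes' expression profiles, and an
annotation-term Jaccard similarity; the edge weight is their convex mixture.
Pathway *segments* are simple paths whose endpoints are seed genes (genes in
the window of a significant marker), oriented from the plasma membrane down
to the nucleus: along the path the assigned subcellular compartment is
nondecreasing in the order extracellular - membrane - cytoplasm - nucleus.
A segment's score is the geometric mean of its edge weights; significance is
assessed against random localization-valid walks of the same length, and the
retained segments are merged into one signaling pathway network per tissue
compartment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .datamodel import (
    LOCALIZATION_INDEX,
    AnnotationRecord,
    ExpressionMatrix,
    InteractionEdge,
    LocalizationRecord,
    PipelineConfig,
)

log = logging.getLogger(__name__)

_START_LEVELS = {LOCALIZATION_INDEX["extracellular"], LOCALIZATION_INDEX["membrane"]}
_NUCLEUS = LOCALIZATION_INDEX["nucleus"]


@dataclass(frozen=True)
class PathSegment:
    """A scored linear signaling chain.  ``length`` is the edge count."""

    nodes: tuple[str, ...]
    score: float
    p_value: float = math.nan

    @property
    def length(self) -> int:
        return len(self.nodes) - 1

    def canonical(self) -> tuple[str, ...]:
        rev = self.nodes[::-1]
        return min(self.nodes, rev)


def compute_coexpression(
    expr: ExpressionMatrix, pairs: Iterable[tuple[str, str]]
) -> dict[tuple[str, str], float]:
    """Pearson r for the requested gene pairs only (never the full matrix).

    Pairs with fewer than 3 shared non-missing samples, a gene absent from the
    matrix, or a zero-variance gene get NaN and are logged.
    """
    out: dict[tuple[str, str], float] = {}
    values = expr.values
    n_skipped = 0
    for a, b in pairs:
        key = (min(a, b), max(a, b))
        if a not in values.index or b not in values.index:
            out[key] = math.nan
            n_skipped += 1
            continue
        x = values.loc[a].to_numpy()
        y = values.loc[b].to_numpy()
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 3:
            out[key] = math.nan
            n_skipped += 1
            continue
        xs, ys = x[ok], y[ok]
        if xs.std() == 0.0 or ys.std() == 0.0:
            out[key] = math.nan
            n_skipped += 1
            continue
        if a == b:
            out[key] = 1.0
            continue
        out[key] = float(np.corrcoef(xs, ys)[0, 1])
    if n_skipped:
        log.info("compute_coexpression: %d pairs without a defined r", n_skipped)
    return out


def _localization_compatible(locs_a: frozenset[str], locs_b: frozenset[str]) -> bool:
    """Two proteins can interact if they share a compartment or occupy
    adjacent compartments in the membrane->nucleus order."""
    ia = {LOCALIZATION_INDEX[c] for c in locs_a}
    ib = {LOCALIZATION_INDEX[c] for c in locs_b}
    return any(abs(a - b) <= 1 for a in ia for b in ib)


def build_weighted_network(
    edges: Sequence[InteractionEdge],
    localization: Sequence[LocalizationRecord],
    annotations: Sequence[AnnotationRecord],
    coexpression: Mapping[tuple[str, str], float],
    seeds: Mapping[str, str],
    cfg: PipelineConfig | None = None,
) -> nx.Graph:
    """Assemble the integrated weighted network for one tissue compartment.

    ``seeds`` maps seed gene -> class ("hot" | "cold" | "cpf").  Edge weight is
    beta_rel*reliability + beta_coexp*|r| + beta_go*Jaccard(terms); when r is
    undefined the remaining weights are renormalized so a missing measurement
    is not a penalty.  Edges between localization-incompatible proteins are
    dropped.  Seeds absent from the resulting graph are kept on the graph-level
    ``unreachable_seeds`` roster.
    """
    cfg = cfg or PipelineConfig()
    b_rel, b_r, b_go = cfg.score_weights
    loc_of = {r.gene_id: r.compartments for r in localization}
    terms_of = {r.gene_id: r.terms for r in annotations}

    g = nx.Graph()
    n_removed = 0
    for e in edges:
        la, lb = loc_of.get(e.gene_a), loc_of.get(e.gene_b)
        if la is not None and lb is not None and not _localization_compatible(la, lb):
            n_removed += 1
            continue
        r = coexpression.get((e.gene_a, e.gene_b), math.nan)
        jac = _jaccard(terms_of.get(e.gene_a, frozenset()), terms_of.get(e.gene_b, frozenset()))
        if math.isnan(r):
            denom = b_rel + b_go
            w = (b_rel * e.reliability + b_go * jac) / denom if denom > 0 else e.reliability
        else:
            w = b_rel * e.reliability + b_r * abs(r) + b_go * jac
        g.add_edge(
            e.gene_a, e.gene_b,
            reliability=e.reliability, source=e.source,
            coexpression_r=r, go_similarity=jac, weight=float(w),
        )
    if n_removed:
        log.info("build_weighted_network: removed %d localization-incompatible edges", n_removed)
    for n in g.nodes:
        g.nodes[n]["localization"] = loc_of.get(n, frozenset(LOCALIZATION_INDEX))
        g.nodes[n]["seed_class"] = seeds.get(n, "none")
    unreachable = sorted(set(seeds) - set(g.nodes))
    if unreachable:
        log.info("build_weighted_network: %d seeds not in network: %s",
                 len(unreachable), unreachable)
    g.graph["unreachable_seeds"] = unreachable
    return g


def _jaccard(a: frozenset[str], b: frozenset[str]) -> float:
    """Jaccard index of two term sets; 0 when either is empty."""
    if not a or not b:
        return 0.0
    return len(a & b) / len(a | b)


def _levels(g: nx.Graph, node: str) -> set[int]:
    return {LOCALIZATION_INDEX[c] for c in g.nodes[node]["localization"]}


def geometric_mean_score(g: nx.Graph, nodes: Sequence[str]) -> float:
    """Geometric mean of edge weights along a path; invariant to reversal and
    length-normalized so longer chains are not penalized multiplicatively."""
    logs = [math.log(g.edges[u, v]["weight"]) for u, v in zip(nodes, nodes[1:])]
    return math.exp(sum(logs) / len(logs))


def search_segments(g: nx.Graph, cfg: PipelineConfig | None = None) -> list[PathSegment]:
    """Enumerate all candidate pathway segments, scored but unfiltered.

    A candidate is a simple path of <= max_segment_length edges whose endpoints
    are seeds, whose first node can sit at the membrane (or extracellular
    space), whose last node can sit in the nucleus, and whose compartment
    assignment is nondecreasing along the path (greedy minimal assignment).
    Output is deterministic: score descending, then lexicographic node ids;
    a path and its reversal count once.
    """
    cfg = cfg or PipelineConfig()
    seeds = {n for n, d in g.nodes(data=True) if d.get("seed_class", "none") != "none"}
    start_nodes = sorted(n for n in seeds if _levels(g, n) & _START_LEVELS)
    nucleus_capable = {n for n in g.nodes if _NUCLEUS in _levels(g, n)}
    if not start_nodes or not (seeds & nucleus_capable):
        log.warning("search_segments: no membrane seeds or no nucleus seeds")
        return []

    found: dict[tuple[str, ...], PathSegment] = {}

    def dfs(path: list[str], on_path: set[str], level: int) -> None:
        u = path[-1]
        if len(path) >= 2 and u in seeds and _NUCLEUS in _levels(g, u):
            seg = PathSegment(tuple(path), geometric_mean_score(g, path))
            key = seg.canonical()
            if key not in found:
                found[key] = seg
        if len(path) - 1 >= cfg.max_segment_length:
            return
        for v in sorted(g.neighbors(u)):
            if v in on_path:
                continue
            nxt = {l for l in _levels(g, v) if l >= level}
            if not nxt:
                continue
            path.append(v)
            on_path.add(v)
            dfs(path, on_path, min(nxt))
            on_path.remove(v)
            path.pop()

    for s in start_nodes:
        start_level = min(_levels(g, s) & _START_LEVELS)
        dfs([s], {s}, start_level)

    return sorted(found.values(), key=lambda seg: (-seg.score, seg.nodes))


def _random_valid_walk(
    g: nx.Graph, start_nodes: Sequence[str], n_edges: int, rng: np.random.Generator
) -> tuple[str, ...] | None:
    """One attempt at a localization-valid simple walk of n_edges edges from a
    random membrane-capable start; None when the walk gets stuck."""
    u = start_nodes[int(rng.integers(len(start_nodes)))]
    level = min(_levels(g, u) & _START_LEVELS)
    path = [u]
    on_path = {u}
    for _ in range(n_edges):
        candidates = []
        for v in g.neighbors(u):
            if v in on_path:
                continue
            nxt = {l for l in _levels(g, v) if l >= level}
            if nxt:
                candidates.append((v, min(nxt)))
        if not candidates:
            return None
        v, level = candidates[int(rng.integers(len(candidates)))]
        path.append(v)
        on_path.add(v)
        u = v
    return tuple(path)


def segment_significance(
    segments: Sequence[PathSegment],
    g: nx.Graph,
    cfg: PipelineConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> list[PathSegment]:
    """Permutation p-values for segments; retain those with p < alpha_segment.

    The null for a segment of k edges is the score distribution of B random
    localization-valid simple paths of k edges, drawn by random walks from
    random membrane-capable starts with seed status ignored.  p uses the
    add-one rule, so its lower bound is 1/(B+1) and never 0.
    """
    cfg = cfg or PipelineConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng if rng is not None else cfg.rng_seed)
    if not segments:
        return []
    B = cfg.permutations_B
    start_nodes = sorted(n for n in g.nodes if _levels(g, n) & _START_LEVELS)
    if not start_nodes:
        raise ValueError("no membrane-capable start nodes for the permutation null")

    null_scores: dict[int, np.ndarray] = {}
    for k in sorted({s.length for s in segments}):
        scores: list[float] = []
        attempts = 0
        max_attempts = 50 * B
        while len(scores) < B and attempts < max_attempts:
            attempts += 1
            walk = _random_valid_walk(g, start_nodes, k, rng)
            if walk is not None:
                scores.append(geometric_mean_score(g, walk))
        if len(scores) < max(1, B // 10):
            raise ValueError(
                f"only {len(scores)} valid null paths of {k} edges realizable in "
                f"{attempts} attempts; reduce max_segment_length or enlarge the graph"
            )
        null_scores[k] = np.asarray(scores)

    out = []
    for seg in segments:
        null = null_scores[seg.length]
        p = (1.0 + int((null >= seg.score).sum())) / (len(null) + 1.0)
        # alpha_segment = 1.0 disables the filter entirely
        if p < cfg.alpha_segment or cfg.alpha_segment >= 1.0:
            out.append(replace(seg, p_value=p))
    return sorted(out, key=lambda s: (-s.score, s.nodes))


def merge_to_spn(
    retained: Sequence[PathSegment],
    g: nx.Graph,
    hot_genes: Iterable[str],
    cold_genes: Iterable[str],
) -> nx.Graph:
    """Union the retained segments into one signaling pathway network.

    Node color: red if the gene lies within the window of a hot spot, blue if
    of a cold spot, pink for intermediaries recruited by the search.  A gene in
    both a hot and a cold window is colored red and the conflict logged.  Edge
    color encodes the sign of the coexpression r (red positive, green
    negative, gray when r is undefined); style is dashed for predicted
    interactions, solid for known ones.
    """
    hot, cold = set(hot_genes), set(cold_genes)
    spn = nx.Graph()
    spn.graph["n_segments"] = len(retained)
    for seg in retained:
        for n in seg.nodes:
            if n not in spn:
                spn.add_node(
                    n,
                    localization=g.nodes[n].get("localization", frozenset()),
                    seed_class=g.nodes[n].get("seed_class", "none"),
                )
        for u, v in zip(seg.nodes, seg.nodes[1:]):
            d = g.edges[u, v]
            r = d.get("coexpression_r", math.nan)
            if isinstance(r, float) and math.isnan(r):
                color = "gray"
                log.info("merge_to_spn: edge %s-%s has no coexpression r", u, v)
            else:
                color = "red" if r > 0 else ("green" if r < 0 else "gray")
            spn.add_edge(
                u, v,
                coexpression_r=r,
                reliability=d.get("reliability", math.nan),
                source=d.get("source", "known"),
                color=color,
                style="dashed" if d.get("source") == "predicted" else "solid",
            )
    for n in spn.nodes:
        if n in hot and n in cold:
            log.warning("merge_to_spn: %s in both a hot and a cold window; colored red", n)
            spn.nodes[n]["color"] = "red"
        elif n in hot:
            spn.nodes[n]["color"] = "red"
        elif n in cold:
            spn.nodes[n]["color"] = "blue"
        else:
            spn.nodes[n]["color"] = "pink"
    return spn
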