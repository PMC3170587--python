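"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

The generator emulates the study design the pipeline targets: ~122 patients
genotyped in two tissue compartments at ~366 microsatellite markers spaced
~9 cM apart, with compartment-specific planted hot/cold spots; a roughly
uniform gene track (homogeneous Poisson placement, so gene counts grow
linearly with window size in expectation); a heavy-tailed protein-interaction
graph with planted membrane->nucleus linear paths through seed genes; and
expression in which genes along a planted path share a latent factor
(pairwise Pearson correlation ~ r_path) that also drives sample labels.

Identical seed + params give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import io as spio
from .datamodel import (
    AnnotationRecord,
    Call,
    Compartment,
    ExpressionMatrix,
    GeneRecord,
    GenotypeCall,
    InteractionEdge,
    LocalizationRecord,
    MarkerLocus,
)
from .windows import map_genes_to_markers

#: planted-spot compartment targets; "shared" plants the same spot in both
SPOT_TARGETS = ("epithelium", "stroma", "shared")


@dataclass
class SimulationParams:
    """Generator knobs.  Defaults mirror the emulated study design: 122
    patients x 2 compartments, 22 chromosomes x 17 markers (374 total) at 9 cM
    (~9 Mb) spacing, ~70% informative markers, 15% background LOH/AI vs 50%
    at hot and 2% at cold spots."""

    n_patients: int = 122
    n_chromosomes: int = 22
    markers_per_chromosome: int = 17
    intermarker_cM: float = 9.0
    bp_per_cM: float = 1e6
    informative_prob: float = 0.7
    background_loh_rate: float = 0.15
    hot_rate: float = 0.5
    cold_rate: float = 0.02
    planted_spots: tuple[tuple[str, str, str], ...] = ()  # (marker_id, target, kind)
    gene_density_per_100kb: float = 1.0
    ppi_nodes: int = 300
    ppi_mean_degree: float = 4.0
    background_reliability: float = 0.3
    planted_paths: tuple[tuple[str, ...], ...] = ()
    r_path: float = 0.7
    normal_fraction: float = 0.2
    label_shift: float = 1.0
    n_samples: int = 60
    outcome_effect: float = 2.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("informative_prob", "background_loh_rate", "hot_rate", "cold_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not (self.hot_rate > self.background_loh_rate >= self.cold_rate):
            raise ValueError("require hot_rate > background_loh_rate >= cold_rate")
        if not (0.0 <= self.r_path < 1.0):
            raise ValueError("r_path must be in [0, 1)")
        for m, target, kind in self.planted_spots:
            if target not in SPOT_TARGETS:
                raise ValueError(f"planted spot {m}: bad target {target!r}")
            if kind not in ("hot", "cold"):
                raise ValueError(f"planted spot {m}: bad kind {kind!r}")
        self.planted_spots = tuple((m, t, k) for m, t, k in self.planted_spots)
        self.planted_paths = tuple(tuple(p) for p in self.planted_paths)


def simulate_genome_map(params: SimulationParams) -> tuple[list[MarkerLocus], list[GeneRecord]]:
    """Markers on an even cM grid; genes by a homogeneous Poisson process.

    Marker i on a chromosome sits at i * intermarker_cM (bp via bp_per_cM).
    Genes are placed at ``gene_density_per_100kb`` per 100 kb over each
    chromosome's marker span (plus one spacing margin) with lengths uniform in
    [5 kb, 50 kb], clipped to nonnegative start.
    """
    rng = np.random.default_rng(params.rng_seed)
    spacing_bp = int(round(params.intermarker_cM * params.bp_per_cM))
    markers: list[MarkerLocus] = []
    genes: list[GeneRecord] = []
    gene_no = 0
    for c in range(1, params.n_chromosomes + 1):
        chrom = f"chr{c}"
        for i in range(params.markers_per_chromosome):
            markers.append(
                MarkerLocus(
                    marker_id=f"M{c:02d}_{i:02d}",
                    chromosome=chrom,
                    position_bp=i * spacing_bp,
                    position_cM=i * params.intermarker_cM,
                )
            )
        span = params.markers_per_chromosome * spacing_bp
        n_genes = rng.poisson(params.gene_density_per_100kb * span / 100_000)
        starts = np.sort(rng.integers(0, span, size=n_genes))
        lengths = rng.integers(5_000, 50_000, size=n_genes, endpoint=True)
        for s, l in zip(starts, lengths):
            genes.append(GeneRecord(f"G{gene_no:05d}", chrom, int(s), int(s + l)))
            gene_no += 1
    return markers, genes


def _rates_per_marker(
    params: SimulationParams, markers: Sequence[MarkerLocus]
) -> dict[Compartment, dict[str, float]]:
    known = {m.marker_id for m in markers}
    rates = {
        comp: dict.fromkeys(known, params.background_loh_rate) for comp in Compartment
    }
    kind_rate = {"hot": params.hot_rate, "cold": params.cold_rate}
    for marker_id, target, kind in params.planted_spots:
        if marker_id not in known:
            raise ValueError(f"planted spot on unknown marker {marker_id}")
        comps = list(Compartment) if target == "shared" else [Compartment(target)]
        for comp in comps:
            rates[comp][marker_id] = kind_rate[kind]
    return rates


def simulate_loh_calls(
    params: SimulationParams, markers: Sequence[MarkerLocus]
) -> list[GenotypeCall]:
    """Draw per-(patient, compartment, marker) calls.

    Each cell is informative with ``informative_prob``; informative cells are
    LOH/AI with the marker's planted rate (or background).  All draws are
    independent across patients and compartments; a "shared" planted spot
    raises the *rate* in both compartments but the Bernoulli draws remain
    independent.
    """
    rng = np.random.default_rng(params.rng_seed)
    rates = _rates_per_marker(params, markers)
    calls: list[GenotypeCall] = []
    marker_ids = [m.marker_id for m in markers]
    for comp in Compartment:
        rate_vec = np.array([rates[comp][m] for m in marker_ids])
        informative = rng.random((params.n_patients, len(marker_ids))) < params.informative_prob
        loh = rng.random((params.n_patients, len(marker_ids))) < rate_vec
        for p in range(params.n_patients):
            sid = f"P{p:03d}"
            for j, mid in enumerate(marker_ids):
                if not informative[p, j]:
                    call = Call.NONINFORMATIVE
                elif loh[p, j]:
                    call = Call.LOH_AI
                else:
                    call = Call.RETENTION
                calls.append(GenotypeCall(sid, comp, mid, call))
    return calls


def simulate_network(
    params: SimulationParams, genes: Sequence[GeneRecord]
) -> tuple[list[InteractionEdge], list[LocalizationRecord], list[AnnotationRecord]]:
    """Background preferential-attachment PPI graph plus planted linear paths.

    Planted path edges get reliability 0.9 and source "known"; background
    edges get ``background_reliability``.  Localization is assigned so each
    planted path runs membrane -> cytoplasm* -> nucleus (a gene appearing in
    two paths at incompatible positions is an error); all planted nodes on one
    path share an annotation-term pair, so adjacent planted nodes have Jaccard
    similarity >= 0.5.  Other nodes draw localization and terms at random.
    """
    rng = np.random.default_rng(params.rng_seed)
    gene_ids = [g.gene_id for g in genes]
    path_nodes = [n for p in params.planted_paths for n in p]
    unknown = sorted(set(path_nodes) - set(gene_ids))
    if unknown:
        raise ValueError(f"planted paths reference unknown genes: {unknown}")

    n_nodes = min(params.ppi_nodes, len(gene_ids))
    # planted nodes always included in the network node set
    pool = [g for g in gene_ids if g not in set(path_nodes)]
    n_extra = max(0, n_nodes - len(set(path_nodes)))
    extra = list(rng.choice(pool, size=min(n_extra, len(pool)), replace=False))
    nodes = sorted(set(path_nodes) | set(extra))

    m_attach = max(1, int(round(params.ppi_mean_degree / 2)))
    bg = nx.barabasi_albert_graph(len(nodes), m_attach, seed=int(rng.integers(2**31)))
    order = list(rng.permutation(nodes))
    relabel = dict(enumerate(order))

    edges: dict[tuple[str, str], InteractionEdge] = {}
    for u, v in bg.edges():
        a, b = sorted((relabel[u], relabel[v]))
        edges[(a, b)] = InteractionEdge(a, b, "known", params.background_reliability)

    loc_of: dict[str, str] = {}
    terms_of: dict[str, set[str]] = {g: set() for g in nodes}
    for k, path in enumerate(params.planted_paths):
        if len(path) < 2:
            raise ValueError(f"planted path {k} shorter than 2 nodes")
        want = ["membrane"] + ["cytoplasm"] * (len(path) - 2) + ["nucleus"]
        for node, w in zip(path, want):
            if loc_of.setdefault(node, w) != w:
                raise ValueError(
                    f"planted path {k}: {node} needs {w} but already {loc_of[node]} "
                    "(localization ordering violated)"
                )
        shared = {f"path{k}_a", f"path{k}_b"}
        for node in path:
            terms_of[node] |= shared
        for a, b in zip(path, path[1:]):
            a, b = sorted((a, b))
            edges[(a, b)] = InteractionEdge(a, b, "known", 0.9)

    vocab = [f"T{i:03d}" for i in range(40)]
    loc_records, annot_records = [], []
    for g in nodes:
        if g in loc_of:
            comps = frozenset({loc_of[g]})
        else:
            k = int(rng.integers(1, 3))
            comps = frozenset(rng.choice(spio_LOCALIZATIONS, size=k, replace=False))
        loc_records.append(LocalizationRecord(g, comps))
        n_terms = int(rng.integers(0, 4))
        terms = terms_of[g] | set(rng.choice(vocab, size=n_terms, replace=False))
        annot_records.append(AnnotationRecord(g, frozenset(terms)))
    return [edges[k] for k in sorted(edges)], loc_records, annot_records


spio_LOCALIZATIONS = np.array(["extracellular", "membrane", "cytoplasm", "nucleus"])


def simulate_expression(
    params: SimulationParams,
    gene_ids: Sequence[str],
    planted_paths: Sequence[Sequence[str]] | None = None,
    panel: str = "tumor",
) -> ExpressionMatrix:
    """Latent-factor expression with planted coexpression along paths.

    Each planted path gets one unit-variance latent factor per sample; each of
    its genes loads on the factor with magnitude sqrt(r_path) and a per-gene
    sign, so the population correlation of two genes on the same path is
    r_path in magnitude (positively or negatively coexpressed edges, matching
    real signaling chains where some interactions are activating and some
    inhibitory).  All other genes are independent standard normal.  Labels:

    - ``panel="tumor"``: samples are tumor (split evenly HPV+/HPV-) or normal
      with probability ``normal_fraction``; every path factor is shifted
      between the two classes by ``label_shift`` (variance renormalized to 1,
      so planted-edge |r| stays exactly r_path).  Planted genes therefore
      carry gene-specific, signed tumor-vs-normal expression shifts and the
      labels are recoverable from the planted structure.
    - ``panel="cellline"``: factors are unshifted; sensitive/resistant is
      drawn per sample via a logistic model with log-odds ``outcome_effect`` x
      (first path's factor, the pathway's latent activity).  outcome_effect =
      0 gives labels independent of expression.
    """
    if params.n_samples < 3:
        raise ValueError("need at least 3 samples for downstream correlations")
    if panel not in ("tumor", "cellline"):
        raise ValueError(f"unknown panel {panel!r}")
    planted_paths = [tuple(p) for p in (planted_paths if planted_paths is not None
                                        else params.planted_paths)]
    unknown = sorted({n for p in planted_paths for n in p} - set(gene_ids))
    if unknown:
        raise ValueError(f"planted paths reference genes missing from matrix: {unknown}")

    rng = np.random.default_rng(params.rng_seed)
    n = params.n_samples
    sample_ids = [f"S{i:03d}" for i in range(n)]
    X = rng.standard_normal((len(gene_ids), n))
    idx = {g: i for i, g in enumerate(gene_ids)}

    labels: dict[str, str] = {}
    class_shift = np.zeros(n)
    scale = 1.0
    if panel == "tumor":
        p_tumor = 1.0 - params.normal_fraction
        tumor = rng.random(n) < p_tumor
        hpv = rng.random(n) < 0.5
        for i, s in enumerate(sample_ids):
            labels[s] = ("HPV+" if hpv[i] else "HPV-") if tumor[i] else "normal"
        c = np.where(tumor, 1.0, -1.0)
        # center with the population mean and renormalize so Var(factor) = 1
        c_mean = 2.0 * p_tumor - 1.0
        c_var = 4.0 * p_tumor * (1.0 - p_tumor)
        class_shift = params.label_shift * (c - c_mean)
        scale = math.sqrt(1.0 + params.label_shift**2 * c_var)

    a = math.sqrt(params.r_path)
    sign_of: dict[str, float] = {}
    factors = []
    for path in planted_paths:
        f = (rng.standard_normal(n) + class_shift) / scale
        factors.append(f)
        for g in path:
            if g in sign_of:
                continue
            sign_of[g] = 1.0 if rng.random() < 0.5 else -1.0
            X[idx[g]] = (
                sign_of[g] * a * f
                + math.sqrt(1.0 - params.r_path) * rng.standard_normal(n)
            )

    if panel == "cellline":
        activity = factors[0] if factors else np.zeros(n)
        p_sens = 1.0 / (1.0 + np.exp(-params.outcome_effect * activity))
        sens = rng.random(n) < p_sens
        for i, s in enumerate(sample_ids):
            labels[s] = "sensitive" if sens[i] else "resistant"

    df = pd.DataFrame(X, index=list(gene_ids), columns=sample_ids)
    return ExpressionMatrix(df, labels)


# ---------------------------------------------------------------------------
# full-bundle orchestration


def default_planted_spots(
    markers: Sequence[MarkerLocus], rng: np.random.Generator
) -> tuple[tuple[str, str, str], ...]:
    """Plant hot/cold spots echoing the emulated design: a handful shared,
    roughly three-fold more compartment-specific spots in stroma than in
    epithelium."""
    ids = list(rng.permutation([m.marker_id for m in markers]))
    plan = (
        [("shared", "hot")] * 2 + [("shared", "cold")] * 2
        + [("epithelium", "hot")] * 3 + [("epithelium", "cold")] * 2
        + [("stroma", "hot")] * 6 + [("stroma", "cold")] * 5
    )
    return tuple((ids.pop(), target, kind) for target, kind in plan)


def default_planted_paths(
    params: SimulationParams,
    markers: Sequence[MarkerLocus],
    genes: Sequence[GeneRecord],
    window_bp: int,
    rng: np.random.Generator,
    n_paths_per_compartment: int = 2,
    path_len: int = 4,
) -> dict[str, tuple[tuple[str, ...], ...]]:
    """Choose planted membrane->nucleus paths per compartment: endpoints are
    seed genes (within window of that compartment's planted hot/cold markers),
    interiors are intermediary genes outside any window."""
    spot_markers: dict[str, list[str]] = {"epithelium": [], "stroma": []}
    for mid, target, _ in params.planted_spots:
        comps = ["epithelium", "stroma"] if target == "shared" else [target]
        for c in comps:
            spot_markers[c].append(mid)
    gmap = map_genes_to_markers(markers, genes, window_bp)
    by_marker: dict[str, list[str]] = {}
    for m, g, _ in gmap.entries:
        by_marker.setdefault(m, []).append(g)
    all_window_genes = gmap.gene_set()
    interior_pool = sorted(set(g.gene_id for g in genes) - all_window_genes)

    used: set[str] = set()
    out: dict[str, tuple[tuple[str, ...], ...]] = {}
    for comp in ("epithelium", "stroma"):
        seed_pool = sorted(
            {g for m in spot_markers[comp] for g in by_marker.get(m, [])} - used
        )
        paths = []
        for _ in range(n_paths_per_compartment):
            if len(seed_pool) < 2:
                break
            ends = list(rng.choice(seed_pool, size=2, replace=False))
            seed_pool = [g for g in seed_pool if g not in ends]
            avail = [g for g in interior_pool if g not in used and g not in ends]
            mids = list(rng.choice(avail, size=path_len - 2, replace=False))
            path = (ends[0], *mids, ends[1])
            used.update(path)
            paths.append(path)
        out[comp] = tuple(paths)
    return out


@dataclass
class SyntheticBundle:
    params: SimulationParams
    markers: list[MarkerLocus]
    genes: list[GeneRecord]
    calls: list[GenotypeCall]
    edges: list[InteractionEdge]
    localization: list[LocalizationRecord]
    annotations: list[AnnotationRecord]
    expression: ExpressionMatrix
    cellline_expression: ExpressionMatrix
    planted_paths: dict[str, tuple[tuple[str, ...], ...]] = field(default_factory=dict)


def simulate_bundle(params: SimulationParams, window_bp: int = 250_000) -> SyntheticBundle:
    """Generate the full input bundle: genome map, calls, network, expression.

    Planted spots/paths default to a design echoing the emulated study (shared
    plus compartment-specific spots, membrane->nucleus paths seeded from hot
    and cold windows); explicit ``params.planted_spots``/``planted_paths``
    override.  Deterministic in (params, window_bp).
    """
    root = np.random.SeedSequence(params.rng_seed)
    s_map, s_spots, s_calls, s_net, s_expr, s_cell = root.spawn(6)

    params = replace(params, rng_seed=int(s_map.generate_state(1)[0] % 2**31))
    markers, genes = simulate_genome_map(params)
    if not params.planted_spots:
        params = replace(
            params,
            planted_spots=default_planted_spots(
                markers, np.random.default_rng(s_spots.generate_state(2))
            ),
        )
    planted = {}
    if params.planted_paths:
        planted = {"epithelium": params.planted_paths, "stroma": ()}
    else:
        planted = default_planted_paths(
            params, markers, genes, window_bp,
            np.random.default_rng(s_net.generate_state(2)),
        )
    all_paths = tuple(p for comp in ("epithelium", "stroma") for p in planted.get(comp, ()))
    params = replace(params, planted_paths=all_paths)

    p_calls = replace(params, rng_seed=int(s_calls.generate_state(1)[0] % 2**31))
    calls = simulate_loh_calls(p_calls, markers)
    p_net = replace(params, rng_seed=int(s_net.generate_state(1)[0] % 2**31))
    edges, locs, annots = simulate_network(p_net, genes)
    net_genes = sorted({r.gene_id for r in locs})
    p_expr = replace(params, rng_seed=int(s_expr.generate_state(1)[0] % 2**31))
    expr = simulate_expression(p_expr, net_genes, all_paths, panel="tumor")
    p_cell = replace(params, rng_seed=int(s_cell.generate_state(1)[0] % 2**31))
    cell = simulate_expression(
        p_cell, net_genes, planted.get("stroma", ()) or all_paths, panel="cellline"
    )
    return SyntheticBundle(
        params, markers, genes, calls, edges, locs, annots, expr, cell, planted
    )


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Write every bundle component in the formats the loaders read."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "markers": outdir / "markers.tsv",
        "calls": outdir / "calls.tsv",
        "genes": outdir / "genes.bed",
        "ppi": outdir / "ppi.tsv",
        "localization": outdir / "localization.tsv",
        "annotations": outdir / "annotations.tsv",
        "expression": outdir / "expression.tsv",
        "labels": outdir / "labels.tsv",
        "cellline_expression": outdir / "cellline_expression.tsv",
        "cellline_labels": outdir / "cellline_labels.tsv",
        "planted_paths": outdir / "planted_paths.tsv",
    }
    spio.write_marker_map(bundle.markers, paths["markers"])
    spio.write_genotype_calls(bundle.calls, paths["calls"])
    spio.write_genes_bed(bundle.genes, paths["genes"])
    spio.write_interactions(bundle.edges, paths["ppi"])
    spio.write_localization(bundle.localization, paths["localization"])
    spio.write_annotations(bundle.annotations, paths["annotations"])
    spio.write_expression(bundle.expression, paths["expression"], paths["labels"])
    spio.write_expression(
        bundle.cellline_expression, paths["cellline_expression"], paths["cellline_labels"]
    )
    rows = [
        {"compartment": comp, "path": "|".join(p)}
        for comp in ("epithelium", "stroma")
        for p in bundle.planted_paths.get(comp, ())
    ]
    pd.DataFrame(rows, columns=["compartment", "path"]).to_csv(
        paths["planted_paths"], sep="\t", index=False
    )
    return paths
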