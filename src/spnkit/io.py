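"""Readers and writers for every external format the pipeline touches.

TSV for tabular inputs (markers, calls, edges, localization, annotations,
expression, reports), BED6 for genes, GraphML + SIF for networks.  Readers
never silently drop records; anything skipped or suspicious is counted and
logged.  Reader/writer pairs round-trip canonical content exactly.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .datamodel import (
    CALL_CODES,
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

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# marker map

def load_marker_map(path: str | Path) -> list[MarkerLocus]:
    """Load a marker map TSV (marker_id, chromosome, position_bp, position_cM).

    Returns loci sorted by (chromosome, position_bp).  Duplicate marker ids are
    a hard error; a cM column decreasing while bp increases within a chromosome
    is logged as a warning (genetic maps are noisy, only bp is used downstream).
    """
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chromosome": str})
    required = ["marker_id", "chromosome", "position_bp", "position_cM"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    dup = df["marker_id"][df["marker_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate marker_id {sorted(dup.unique())}")
    for col in ("position_bp", "position_cM"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            line = int(df.index[bad | df[col].isna()][0]) + 2  # header is line 1
            raise ValueError(f"{path}: non-numeric {col} at line {line}")
    loci = [
        MarkerLocus(
            marker_id=r.marker_id,
            chromosome=r.chromosome,
            position_bp=int(r.position_bp),
            position_cM=float(r.position_cM),
        )
        for r in df.itertuples()
    ]
    loci.sort(key=lambda m: (m.chromosome, m.position_bp, m.marker_id))
    for a, b in zip(loci, loci[1:]):
        if a.chromosome == b.chromosome and b.position_cM < a.position_cM:
            log.warning(
                "marker map: cM decreases from %s (%.3f) to %s (%.3f) while bp increases",
                a.marker_id, a.position_cM, b.marker_id, b.position_cM,
            )
    return loci


def write_marker_map(loci: Sequence[MarkerLocus], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "marker_id": [m.marker_id for m in loci],
            "chromosome": [m.chromosome for m in loci],
            "position_bp": [m.position_bp for m in loci],
            "position_cM": [m.position_cM for m in loci],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotype calls

def load_genotype_calls(
    path: str | Path, marker_map: Sequence[MarkerLocus] | None = None
) -> list[GenotypeCall]:
    """Load long-format calls (sample_id, compartment, marker_id, call in {L,R,N}).

    Unknown call codes are an error citing the offending line; if a marker map
    is supplied, calls referencing unknown markers are an error listing them.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "compartment", "marker_id", "call"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    calls: list[GenotypeCall] = []
    seen: set[tuple[str, str, str]] = set()
    for i, r in enumerate(df.itertuples()):
        if r.call not in CALL_CODES:
            raise ValueError(f"{path}: unknown call code {r.call!r} at line {i + 2}")
        try:
            comp = Compartment(r.compartment)
        except ValueError:
            raise ValueError(
                f"{path}: unknown compartment {r.compartment!r} at line {i + 2}"
            ) from None
        key = (r.sample_id, r.compartment, r.marker_id)
        if key in seen:
            raise ValueError(f"{path}: duplicate call for {key} at line {i + 2}")
        seen.add(key)
        calls.append(GenotypeCall(r.sample_id, comp, r.marker_id, CALL_CODES[r.call]))
    if marker_map is not None:
        known = {m.marker_id for m in marker_map}
        unknown = sorted({c.marker_id for c in calls} - known)
        if unknown:
            raise ValueError(f"{path}: calls reference unknown markers {unknown}")
    return calls


_CODE_FOR_CALL = {v: k for k, v in CALL_CODES.items()}


def write_genotype_calls(calls: Iterable[GenotypeCall], path: str | Path) -> None:
    calls = list(calls)
    df = pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "compartment": [c.compartment.value for c in calls],
            "marker_id": [c.marker_id for c in calls],
            "call": [_CODE_FOR_CALL[c.call] for c in calls],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene BED

def load_genes_bed(path: str | Path) -> list[GeneRecord]:
    """Load genes from BED6 (or BED4); intervals are 0-based half-open."""
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}: line {i}: expected >=4 BED fields")
            chrom, start, end, name = fields[:4]
            strand = fields[5] if len(fields) >= 6 else "."
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ValueError(f"{path}: line {i}: non-integer coordinates") from None
            if start_i >= end_i:
                raise ValueError(
                    f"{path}: line {i}: start {start_i} >= end {end_i} for {name}"
                )
            genes.append(GeneRecord(name, chrom, start_i, end_i, strand))
    return genes


def write_genes_bed(genes: Sequence[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chromosome}\t{g.start_bp}\t{g.end_bp}\t{g.gene_id}\t0\t{g.strand}\n")


# ---------------------------------------------------------------------------
# interaction / localization / annotation tables

def load_interactions(path: str | Path) -> list[InteractionEdge]:
    """Load PPI edges (gene_a, gene_b, source, reliability).

    Edges are canonicalized to gene_a < gene_b; duplicates are merged keeping
    the maximum reliability, and a known/predicted conflict keeps "known" and
    logs the conflict.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str, "source": str})
    merged: dict[tuple[str, str], InteractionEdge] = {}
    for r in df.itertuples():
        e = InteractionEdge(r.gene_a, r.gene_b, r.source, float(r.reliability))
        key = (e.gene_a, e.gene_b)
        if key in merged:
            old = merged[key]
            source = old.source
            if old.source != e.source:
                source = "known"
                log.warning("edge %s-%s: known/predicted conflict, keeping known", *key)
            merged[key] = InteractionEdge(
                e.gene_a, e.gene_b, source, max(old.reliability, e.reliability)
            )
        else:
            merged[key] = e
    return [merged[k] for k in sorted(merged)]


def write_interactions(edges: Sequence[InteractionEdge], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "gene_a": [e.gene_a for e in edges],
            "gene_b": [e.gene_b for e in edges],
            "source": [e.source for e in edges],
            "reliability": [e.reliability for e in edges],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def load_localization(path: str | Path) -> list[LocalizationRecord]:
    """Load subcellular localization (gene_id, comma-separated compartments)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        LocalizationRecord(r.gene_id, frozenset(r.compartments.split(",")))
        for r in df.itertuples()
    ]


def write_localization(records: Sequence[LocalizationRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "compartments": [",".join(sorted(r.compartments)) for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def load_annotations(path: str | Path) -> list[AnnotationRecord]:
    """Load annotation terms (gene_id, comma-separated term ids; may be empty)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for r in df.itertuples():
        terms = frozenset(t for t in r.terms.split(",") if t)
        out.append(AnnotationRecord(r.gene_id, terms))
    return out


def write_annotations(records: Sequence[AnnotationRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "terms": [",".join(sorted(r.terms)) for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression

def load_expression(
    path: str | Path, labels_path: str | Path | None = None
) -> ExpressionMatrix:
    """Load genes-in-rows expression TSV plus an optional two-column label file."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    labels = {}
    if labels_path is not None:
        ldf = pd.read_csv(labels_path, sep="\t", dtype=str)
        labels = dict(zip(ldf.iloc[:, 0], ldf.iloc[:, 1]))
    return ExpressionMatrix(df, labels)


def write_expression(
    expr: ExpressionMatrix, path: str | Path, labels_path: str | Path | None = None
) -> None:
    df = expr.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.10g")
    if labels_path is not None:
        pd.DataFrame(
            {
                "sample_id": expr.sample_ids,
                "label": [expr.sample_labels.get(s, "") for s in expr.sample_ids],
            }
        ).to_csv(labels_path, sep="\t", index=False)


def load_tracks(
    genes: str | Path,
    ppi: str | Path,
    localization: str | Path,
    annotations: str | Path,
    expression: str | Path,
    labels: str | Path | None = None,
) -> tuple[
    list[GeneRecord],
    list[InteractionEdge],
    list[LocalizationRecord],
    list[AnnotationRecord],
    ExpressionMatrix,
]:
    """Load the full annotation bundle and cross-reference it.

    Genes present in the expression matrix but absent from the BED are retained;
    only their count is logged.
    """
    gene_recs = load_genes_bed(genes)
    edges = load_interactions(ppi)
    locs = load_localization(localization)
    annots = load_annotations(annotations)
    expr = load_expression(expression, labels)
    bed_ids = {g.gene_id for g in gene_recs}
    orphan = [g for g in expr.gene_ids if g not in bed_ids]
    if orphan:
        log.info("%d expression genes absent from BED (retained)", len(orphan))
    return gene_recs, edges, locs, annots, expr


# ---------------------------------------------------------------------------
# network export / import

def export_network(net: nx.Graph, prefix: str | Path) -> dict[str, Path]:
    """Write a network as GraphML (all attributes), SIF (topology) and
    node/edge attribute TSVs.  Returns the written paths."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "graphml": prefix.with_suffix(".graphml"),
        "sif": prefix.with_suffix(".sif"),
        "nodes": Path(str(prefix) + ".nodes.tsv"),
        "edges": Path(str(prefix) + ".edges.tsv"),
    }
    # GraphML cannot carry sets/None; stringify those attributes
    g = nx.Graph()
    g.graph.update({k: str(v) for k, v in net.graph.items()})
    for n, d in net.nodes(data=True):
        g.add_node(n, **{k: _graphml_safe(v) for k, v in d.items()})
    for u, v, d in net.edges(data=True):
        g.add_edge(u, v, **{k: _graphml_safe(x) for k, x in d.items()})
    nx.write_graphml(g, paths["graphml"])
    with open(paths["sif"], "w") as fh:
        for u, v in sorted(net.edges()):
            fh.write(f"{u}\tpp\t{v}\n")
        for n in sorted(nx.isolates(net)):
            fh.write(f"{n}\n")
    node_rows = [{"node": n, **d} for n, d in sorted(net.nodes(data=True))]
    pd.DataFrame(node_rows, columns=None if node_rows else ["node"]).to_csv(
        paths["nodes"], sep="\t", index=False)
    edge_rows = [
        {"gene_a": min(u, v), "gene_b": max(u, v), **d}
        for u, v, d in sorted(net.edges(data=True), key=lambda t: (min(t[0], t[1]), max(t[0], t[1])))
    ]
    pd.DataFrame(edge_rows, columns=None if edge_rows else ["gene_a", "gene_b"]).to_csv(
        paths["edges"], sep="\t", index=False)
    return paths


def _graphml_safe(v):
    if v is None:
        return ""
    if isinstance(v, (frozenset, set, tuple, list)):
        return ",".join(sorted(str(x) for x in v))
    return v


def import_network(graphml_path: str | Path) -> nx.Graph:
    return nx.read_graphml(graphml_path)
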