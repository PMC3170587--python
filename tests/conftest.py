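import numpy as np
import pandas as pd
import pytest

from spnkit.datamodel import (
    AnnotationRecord,
    Compartment,
    ExpressionMatrix,
    GeneRecord,
    InteractionEdge,
    LocalizationRecord,
    MarkerLocus,
)


@pytest.fixture
def marker_map():
    return [
        MarkerLocus(marker_id="M1", chromosome="chr1", position_bp=100_000, position_cM=0.1),
        MarkerLocus(marker_id="M2", chromosome="chr1", position_bp=9_100_000, position_cM=9.1),
        MarkerLocus(marker_id="M3", chromosome="chr2", position_bp=50_000, position_cM=0.05),
    ]


@pytest.fixture
def tiny_genes():
    return [
        GeneRecord("GA", "chr1", 90_000, 110_000),
        GeneRecord("GB", "chr1", 400_000, 410_000),
        GeneRecord("GC", "chr2", 10_000, 30_000, "+"),
        GeneRecord("GD", "chr2", 600_000, 650_000, "-"),
    ]


@pytest.fixture
def tiny_bundle_files(tmp_path, marker_map, tiny_genes):
    """A minimal 5-gene on-disk bundle exercising every loader."""
    from spnkit import io as spio

    spio.write_marker_map(marker_map, tmp_path / "markers.tsv")
    spio.write_genes_bed(tiny_genes + [GeneRecord("GE", "chr2", 700_000, 720_000)],
                         tmp_path / "genes.bed")
    spio.write_interactions(
        [
            InteractionEdge("GA", "GB", "known", 0.9),
            InteractionEdge("GB", "GC", "predicted", 0.5),
            InteractionEdge("GC", "GD", "known", 0.7),
        ],
        tmp_path / "ppi.tsv",
    )
    spio.write_localization(
        [
            LocalizationRecord("GA", frozenset({"membrane"})),
            LocalizationRecord("GB", frozenset({"cytoplasm"})),
            LocalizationRecord("GC", frozenset({"cytoplasm", "nucleus"})),
            LocalizationRecord("GD", frozenset({"nucleus"})),
        ],
        tmp_path / "localization.tsv",
    )
    spio.write_annotations(
        [
            AnnotationRecord("GA", frozenset({"T1", "T2"})),
            AnnotationRecord("GB", frozenset({"T2"})),
            AnnotationRecord("GC", frozenset()),
        ],
        tmp_path / "annotations.tsv",
    )
    rng = np.random.default_rng(0)
    expr = ExpressionMatrix(
        pd.DataFrame(
            rng.standard_normal((5, 6)),
            index=["GA", "GB", "GC", "GD", "GE"],
            columns=[f"S{i}" for i in range(6)],
        ),
        {f"S{i}": ("HPV+" if i % 2 else "normal") for i in range(6)},
    )
    spio.write_expression(expr, tmp_path / "expression.tsv", tmp_path / "labels.tsv")
    return tmp_path


def make_calls(marker_counts, compartment=Compartment.EPITHELIUM):
    """Build GenotypeCall lists from {marker: (n_informative, n_loh)} plus
    optional noninformative padding: (n_inf, n_loh, n_noninf)."""
    from spnkit.datamodel import Call, GenotypeCall

    calls = []
    for marker, spec in marker_counts.items():
        n_inf, n_loh, *rest = spec
        n_non = rest[0] if rest else 0
        i = 0
        for _ in range(n_loh):
            calls.append(GenotypeCall(f"P{i:03d}", compartment, marker, Call.LOH_AI))
            i += 1
        for _ in range(n_inf - n_loh):
            calls.append(GenotypeCall(f"P{i:03d}", compartment, marker, Call.RETENTION))
            i += 1
        for _ in range(n_non):
            calls.append(GenotypeCall(f"P{i:03d}", compartment, marker, Call.NONINFORMATIVE))
            i += 1
    return calls
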