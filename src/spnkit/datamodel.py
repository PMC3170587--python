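"""Shared domain types for the bicompartmental LOH/AI -> signaling-network pipeline.

Coordinates follow BED conventions throughout: gene intervals are 0-based
half-open ``[start_bp, end_bp)``; marker positions are 0-based points.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


class Compartment(str, enum.Enum):
    """Tissue compartment isolated by laser-capture microdissection."""

    EPITHELIUM = "epithelium"
    STROMA = "stroma"


class Call(str, enum.Enum):
    """Per-marker genotyping outcome.

    ``NONINFORMATIVE`` markers are homozygous in the germline and carry no
    allelic-loss information; only informative calls enter frequencies.
    """

    LOH_AI = "LOH_AI"
    RETENTION = "retention"
    NONINFORMATIVE = "noninformative"


#: File codes for genotype calls; anything else is a hard error, never guessed.
CALL_CODES: Mapping[str, Call] = {
    "L": Call.LOH_AI,
    "R": Call.RETENTION,
    "N": Call.NONINFORMATIVE,
}

#: Subcellular compartments in signaling order, plasma membrane down to nucleus.
LOCALIZATION_ORDER: tuple[str, ...] = ("extracellular", "membrane", "cytoplasm", "nucleus")
LOCALIZATION_INDEX: Mapping[str, int] = {c: i for i, c in enumerate(LOCALIZATION_ORDER)}


@dataclass(frozen=True, order=True)
class MarkerLocus:
    """Genomic anchor for a microsatellite marker."""

    chromosome: str
    position_bp: int
    marker_id: str
    position_cM: float = 0.0

    def __post_init__(self) -> None:
        if self.position_bp < 0:
            raise ValueError(f"marker {self.marker_id}: negative position_bp")
        if self.position_cM < 0:
            raise ValueError(f"marker {self.marker_id}: negative position_cM")


@dataclass(frozen=True)
class GenotypeCall:
    sample_id: str
    compartment: Compartment
    marker_id: str
    call: Call


@dataclass(frozen=True)
class GeneRecord:
    """A gene as a half-open genomic interval; strand is never used downstream
    (marker windows are symmetric)."""

    gene_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start_bp < self.end_bp):
            raise ValueError(
                f"gene {self.gene_id}: require 0 <= start < end, "
                f"got [{self.start_bp}, {self.end_bp})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class InteractionEdge:
    """Undirected protein-protein interaction, canonically ordered."""

    gene_a: str
    gene_b: str
    source: str = "known"  # "known" | "predicted"
    reliability: float = 1.0

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-interaction on {self.gene_a}")
        if self.source not in ("known", "predicted"):
            raise ValueError(f"edge {self.gene_a}-{self.gene_b}: bad source {self.source!r}")
        if not (0.0 < self.reliability <= 1.0):
            raise ValueError(
                f"edge {self.gene_a}-{self.gene_b}: reliability {self.reliability} "
                "outside (0, 1]"
            )
        if self.gene_a > self.gene_b:
            a, b = self.gene_b, self.gene_a
            object.__setattr__(self, "gene_a", a)
            object.__setattr__(self, "gene_b", b)


@dataclass(frozen=True)
class LocalizationRecord:
    gene_id: str
    compartments: frozenset[str]

    def __post_init__(self) -> None:
        if not self.compartments:
            raise ValueError(f"gene {self.gene_id}: empty localization set")
        bad = set(self.compartments) - set(LOCALIZATION_ORDER)
        if bad:
            raise ValueError(f"gene {self.gene_id}: unknown localization {sorted(bad)}")
        object.__setattr__(self, "compartments", frozenset(self.compartments))


@dataclass(frozen=True)
class AnnotationRecord:
    """Functional annotation terms (e.g. GO ids, treated as opaque strings)."""

    gene_id: str
    terms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", frozenset(self.terms))


class ExpressionMatrix:
    """Genes x samples expression values with optional per-sample labels.

    Thin wrapper over a pandas DataFrame (genes in rows).  Missing values stay
    as NaN; they are never silently dropped.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        sample_labels: Mapping[str, str] | None = None,
    ) -> None:
        if values.index.duplicated().any():
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if values.columns.duplicated().any():
            dups = values.columns[values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        self.values = values.astype(float)
        self.sample_labels = dict(sample_labels or {})
        unknown = set(self.sample_labels) - set(values.columns)
        if unknown:
            raise ValueError(f"labels for unknown samples: {sorted(unknown)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        present = [g for g in gene_ids if g in self.values.index]
        return ExpressionMatrix(self.values.loc[present], self.sample_labels)

    def label_vector(self) -> pd.Series:
        return pd.Series({s: self.sample_labels.get(s, "") for s in self.sample_ids})

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.values.equals(other.values) and self.sample_labels == other.sample_labels

    def __repr__(self) -> str:
        g, s = self.shape
        return f"ExpressionMatrix({g} genes x {s} samples, {len(self.sample_labels)} labeled)"


@dataclass
class PipelineConfig:
    """Tunable thresholds shared across pipeline stages.

    ``window_bp`` is the symmetric marker flank (250 kb each side by default);
    ``alpha_spot`` the per-marker hot/cold significance level; ``alpha_segment``
    the retention threshold for pathway segments; ``score_weights`` the mixture
    of interaction reliability, |coexpression r| and annotation similarity in
    edge weights.
    """

    window_bp: int = 250_000
    alpha_spot: float = 0.05
    alpha_segment: float = 0.01
    min_informative: int = 10
    max_segment_length: int = 6
    permutations_B: int = 1000
    score_weights: tuple[float, float, float] = (0.4, 0.4, 0.2)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha_spot", "alpha_segment"):
            a = getattr(self, name)
            if not (0.0 < a < 1.0) and a != 1.0:
                raise ValueError(f"{name}={a} outside (0, 1]")
        if self.window_bp < 0:
            raise ValueError("window_bp must be >= 0")
        if self.max_segment_length < 2:
            raise ValueError("max_segment_length must be >= 2")
        if self.permutations_B < 99:
            raise ValueError("permutations_B must be >= 99")
        w = np.asarray(self.score_weights, dtype=float)
        if (w < 0).any() or not np.isclose(w.sum(), 1.0):
            raise ValueError(f"score_weights {tuple(w)} must be nonnegative and sum to 1")
        self.score_weights = tuple(float(x) for x in w)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["score_weights"] = list(self.score_weights)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        if "score_weights" in d:
            d["score_weights"] = tuple(d["score_weights"])
        return cls(**d)
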