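"""Per-marker LOH/AI frequencies and hot/cold-spot classification.

A *hot spot* is a marker whose LOH/AI frequency is significantly higher than
the pooled frequency of the other markers on the same chromosome (same
compartment); a *cold spot* is significantly lower.  Significance is a
two-sided exact binomial test of the marker's (n_loh, n_informative) against
the leave-one-out pooled background rate, at a per-marker alpha with no
multiplicity correction by default.  Clinicopathological-feature (CPF)
markers are supplied externally and enter the significant set regardless of
hot/cold status.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from scipy import stats

from .datamodel import Call, Compartment, GenotypeCall, MarkerLocus, PipelineConfig

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FrequencyRecord:
    marker_id: str
    compartment: Compartment
    n_informative: int
    n_loh: int

    @property
    def frequency(self) -> float:
        """LOH/AI fraction among informative calls; NaN when none informative."""
        if self.n_informative == 0:
            return math.nan
        return self.n_loh / self.n_informative


@dataclass(frozen=True)
class SpotCall:
    marker_id: str
    compartment: Compartment
    spot_class: str  # "hot" | "cold" | "none"
    p_value: float  # NaN when not applicable (single eligible marker, etc.)
    frequency: float
    background_rate: float
    cpf: bool = False

    @property
    def significant(self) -> bool:
        return self.spot_class in ("hot", "cold") or self.cpf


@dataclass
class SpotSummary:
    """Cross-tabulation of significant markers mirroring the compartment-sharing
    bookkeeping: shared / epithelium-only / stroma-only x hot / cold / CPF."""

    counts: dict[tuple[str, str], int] = field(default_factory=dict)

    CATEGORIES = ("shared", "epithelium_only", "stroma_only")
    KINDS = ("hot", "cold", "cpf")

    def __post_init__(self) -> None:
        for cat in self.CATEGORIES:
            for kind in self.KINDS:
                self.counts.setdefault((cat, kind), 0)

    def total(self) -> int:
        return sum(self.counts.values())

    def kind_total(self, kind: str) -> int:
        return sum(self.counts[(c, kind)] for c in self.CATEGORIES)

    def to_rows(self) -> list[dict]:
        rows = [
            {"category": c, "kind": k, "markers": self.counts[(c, k)]}
            for c in self.CATEGORIES
            for k in self.KINDS
        ]
        rows.append({"category": "all", "kind": "total", "markers": self.total()})
        return rows


def compute_loh_frequency(calls: Iterable[GenotypeCall]) -> list[FrequencyRecord]:
    """Count informative and LOH/AI calls per (marker, compartment).

    Only (marker, compartment) pairs with at least one call appear; pairs where
    every call is noninformative are emitted with n_informative = 0 so they can
    be reported rather than silently dropped.
    """
    counts: dict[tuple[str, Compartment], list[int]] = {}
    for c in calls:
        key = (c.marker_id, c.compartment)
        n = counts.setdefault(key, [0, 0])
        if c.call is not Call.NONINFORMATIVE:
            n[0] += 1
            if c.call is Call.LOH_AI:
                n[1] += 1
    return [
        FrequencyRecord(marker_id=m, compartment=comp, n_informative=ni, n_loh=nl)
        for (m, comp), (ni, nl) in sorted(counts.items(), key=lambda kv: (kv[0][0], kv[0][1].value))
    ]


def exact_binomial_p(n_loh: int, n_informative: int, background_rate: float) -> float:
    """Two-sided exact binomial p-value of observing n_loh/n_informative under
    the background rate.  Isolated so an alternative spot model can be swapped in."""
    if n_informative == 0:
        return math.nan
    if background_rate <= 0.0:
        return 1.0 if n_loh == 0 else 0.0
    if background_rate >= 1.0:
        return 1.0 if n_loh == n_informative else 0.0
    return stats.binomtest(n_loh, n_informative, background_rate, alternative="two-sided").pvalue


def classify_spots(
    freqs: Sequence[FrequencyRecord],
    marker_map: Sequence[MarkerLocus],
    cfg: PipelineConfig | None = None,
) -> list[SpotCall]:
    """Classify each eligible marker as hot, cold or neither.

    Background for marker m = pooled LOH fraction of all *other* eligible
    markers on m's chromosome in the same compartment.  Markers with fewer than
    ``cfg.min_informative`` informative calls are excluded and reported via the
    log.  A chromosome with a single eligible marker has no contrast: its
    marker is classed "none" with p-value NaN.  Raw p-values; no multiplicity
    correction.
    """
    cfg = cfg or PipelineConfig()
    chrom_of = {m.marker_id: m.chromosome for m in marker_map}
    unknown = sorted({f.marker_id for f in freqs} - set(chrom_of))
    if unknown:
        raise ValueError(f"frequency records for unmapped markers: {unknown}")

    eligible = [f for f in freqs if f.n_informative >= cfg.min_informative]
    excluded = [f for f in freqs if f.n_informative < cfg.min_informative]
    if excluded:
        log.info(
            "classify_spots: %d marker/compartment records below min_informative=%d: %s",
            len(excluded), cfg.min_informative,
            [(f.marker_id, f.compartment.value) for f in excluded],
        )

    by_group: dict[tuple[str, Compartment], list[FrequencyRecord]] = {}
    for f in eligible:
        by_group.setdefault((chrom_of[f.marker_id], f.compartment), []).append(f)

    out: list[SpotCall] = []
    for (_, _), group in sorted(by_group.items(), key=lambda kv: (kv[0][0], kv[0][1].value)):
        tot_inf = sum(f.n_informative for f in group)
        tot_loh = sum(f.n_loh for f in group)
        for f in sorted(group, key=lambda f: f.marker_id):
            rest_inf = tot_inf - f.n_informative
            rest_loh = tot_loh - f.n_loh
            if len(group) < 2 or rest_inf == 0:
                out.append(
                    SpotCall(f.marker_id, f.compartment, "none", math.nan,
                             f.frequency, math.nan)
                )
                continue
            background = rest_loh / rest_inf
            p = exact_binomial_p(f.n_loh, f.n_informative, background)
            spot_class = "none"
            if p < cfg.alpha_spot:
                if f.frequency > background:
                    spot_class = "hot"
                elif f.frequency < background:
                    spot_class = "cold"
            out.append(
                SpotCall(f.marker_id, f.compartment, spot_class, p, f.frequency, background)
            )
    out.sort(key=lambda s: (s.marker_id, s.compartment.value))
    return out


def attach_cpf(
    spots: Sequence[SpotCall],
    cpf_markers: Iterable[tuple[str, Compartment | str]],
    marker_map: Sequence[MarkerLocus] | None = None,
) -> list[SpotCall]:
    """Flag externally supplied clinicopathological-feature markers.

    CPF markers join the significant set regardless of hot/cold class; a CPF
    marker that is also hot or cold keeps its class (flagged both, counted once
    in summaries).
    """
    wanted = {(m, Compartment(c)) for m, c in cpf_markers}
    if marker_map is not None:
        known = {m.marker_id for m in marker_map}
        unknown = sorted({m for m, _ in wanted} - known)
        if unknown:
            raise ValueError(f"CPF markers absent from map: {unknown}")
    present = {(s.marker_id, s.compartment) for s in spots}
    out = [
        replace(s, cpf=True) if (s.marker_id, s.compartment) in wanted else s
        for s in spots
    ]
    # CPF markers with no spot record (e.g. filtered by min_informative) still
    # enter the significant set as pure CPF calls.
    for m, comp in sorted(wanted - present, key=lambda t: (t[0], t[1].value)):
        out.append(SpotCall(m, comp, "none", math.nan, math.nan, math.nan, cpf=True))
    out.sort(key=lambda s: (s.marker_id, s.compartment.value))
    return out


def summarize_spots(spots: Sequence[SpotCall]) -> SpotSummary:
    """Tabulate significant markers into shared / epithelium-only / stroma-only
    by hot / cold / CPF.

    "Shared" means the marker received the *same* hot or cold class in both
    compartments (counted once).  A marker hot in one compartment and cold in
    the other is tabulated under both compartment-only cells and logged as a
    conflict.  A CPF-only marker (not hot/cold anywhere) counts under the CPF
    column of the compartment(s) where it was flagged; a marker that is both
    CPF and hot/cold is counted once, under its hot/cold cell.
    """
    summary = SpotSummary()
    by_marker: dict[str, dict[Compartment, SpotCall]] = {}
    for s in spots:
        by_marker.setdefault(s.marker_id, {})[s.compartment] = s

    for marker_id in sorted(by_marker):
        comp_calls = by_marker[marker_id]
        epi = comp_calls.get(Compartment.EPITHELIUM)
        stro = comp_calls.get(Compartment.STROMA)
        epi_class = epi.spot_class if epi else "none"
        stro_class = stro.spot_class if stro else "none"

        if epi_class in ("hot", "cold") and epi_class == stro_class:
            summary.counts[("shared", epi_class)] += 1
            continue
        if epi_class in ("hot", "cold") and stro_class in ("hot", "cold"):
            log.warning(
                "marker %s: %s in epithelium but %s in stroma; counted in both "
                "compartment-only cells", marker_id, epi_class, stro_class,
            )
        counted = False
        if epi_class in ("hot", "cold"):
            summary.counts[("epithelium_only", epi_class)] += 1
            counted = True
        if stro_class in ("hot", "cold"):
            summary.counts[("stroma_only", stro_class)] += 1
            counted = True
        if not counted:
            # pure CPF marker
            epi_cpf = bool(epi and epi.cpf)
            stro_cpf = bool(stro and stro.cpf)
            if epi_cpf and stro_cpf:
                summary.counts[("shared", "cpf")] += 1
            elif epi_cpf:
                summary.counts[("epithelium_only", "cpf")] += 1
            elif stro_cpf:
                summary.counts[("stroma_only", "cpf")] += 1
    return summary
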