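"""End-to-end orchestration: simulate -> spots -> windows -> discover ->
cluster -> global test, with a reproducibility manifest.

One root seed fans out to per-stage seeds through numpy's splittable
SeedSequence, so any stage can be re-run in isolation; re-running with the
same config, seed and inputs reproduces every output file hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as spio
from .datamodel import Compartment, PipelineConfig
from .expression import (
    GeneGroup,
    build_gene_groups,
    coherence_vs_random,
    global_test_report,
    hierarchical_cluster,
    linkage_to_newick,
    plot_heatmap,
    znormalize_samples,
)
from .network import (
    PathSegment,
    build_weighted_network,
    compute_coexpression,
    merge_to_spn,
    search_segments,
    segment_significance,
)
from .simulate import SimulationParams, simulate_bundle, write_bundle
from .spots import attach_cpf, classify_spots, compute_loh_frequency, summarize_spots
from .windows import map_genes_to_markers

log = logging.getLogger(__name__)

STAGES = ("simulate", "spots", "windows", "discover", "cluster", "globaltest")


@dataclass
class RunManifest:
    config: dict
    stage_seeds: dict[str, int] = field(default_factory=dict)
    file_digests: dict[str, str] = field(default_factory=dict)
    stage_seconds: dict[str, float] = field(default_factory=dict)
    completed: list[str] = field(default_factory=list)
    failed_stage: str | None = None
    versions: dict[str, str] = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML config; unknown keys are an error, defaults fill the rest."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(PipelineConfig().to_dict())
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return PipelineConfig.from_dict(raw)


def _stage_seeds(root: np.random.SeedSequence) -> dict[str, int]:
    children = root.spawn(len(STAGES))
    return {
        stage: int(child.generate_state(1)[0] % 2**31)
        for stage, child in zip(STAGES, children)
    }


def run_pipeline(
    cfg: PipelineConfig,
    outdir: str | Path,
    sim_params: SimulationParams | None = None,
    input_dir: str | Path | None = None,
    make_plots: bool = False,
) -> RunManifest:
    """Execute the full workflow into ``outdir`` and return the manifest.

    Either ``sim_params`` (synthetic inputs are generated first) or
    ``input_dir`` (a pre-existing bundle in the simulate layout) must be
    given.  Each stage's outputs are on disk before the next consumes them;
    on stage failure the manifest records completed stages and the failure.
    """
    if (sim_params is None) == (input_dir is None):
        raise ValueError("provide exactly one of sim_params or input_dir")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(cfg.rng_seed)
    manifest = RunManifest(config=cfg.to_dict())
    manifest.versions = _versions()
    manifest.stage_seeds = _stage_seeds(root)

    def _digest_dir(d: Path) -> None:
        for p in sorted(d.rglob("*")):
            if p.is_file() and p.suffix not in (".png", ".svg"):
                manifest.file_digests[str(p.relative_to(outdir))] = file_sha256(p)

    try:
        # ---- simulate / load ------------------------------------------------
        t0 = time.perf_counter()
        in_dir = outdir / "inputs"
        if sim_params is not None:
            sim_params = replace(sim_params, rng_seed=manifest.stage_seeds["simulate"])
            bundle = simulate_bundle(sim_params, window_bp=cfg.window_bp)
            write_bundle(bundle, in_dir)
        else:
            in_dir = Path(input_dir)
        markers = spio.load_marker_map(in_dir / "markers.tsv")
        calls = spio.load_genotype_calls(in_dir / "calls.tsv", markers)
        genes, edges, locs, annots, expr = spio.load_tracks(
            in_dir / "genes.bed", in_dir / "ppi.tsv", in_dir / "localization.tsv",
            in_dir / "annotations.tsv", in_dir / "expression.tsv", in_dir / "labels.tsv",
        )
        cell_expr = spio.load_expression(
            in_dir / "cellline_expression.tsv", in_dir / "cellline_labels.tsv"
        )
        manifest.stage_seconds["simulate"] = time.perf_counter() - t0
        if sim_params is not None:
            _digest_dir(in_dir)
        manifest.completed.append("simulate")

        # ---- spots ----------------------------------------------------------
        t0 = time.perf_counter()
        spot_dir = outdir / "spots"
        spot_dir.mkdir(exist_ok=True)
        freqs = compute_loh_frequency(calls)
        spot_calls = classify_spots(freqs, markers, cfg)
        spot_calls = attach_cpf(spot_calls, [], markers)
        summary = summarize_spots(spot_calls)
        pd.DataFrame(
            {
                "marker_id": [s.marker_id for s in spot_calls],
                "compartment": [s.compartment.value for s in spot_calls],
                "class": [s.spot_class for s in spot_calls],
                "p_value": [s.p_value for s in spot_calls],
                "frequency": [s.frequency for s in spot_calls],
                "background_rate": [s.background_rate for s in spot_calls],
                "cpf": [s.cpf for s in spot_calls],
            }
        ).to_csv(spot_dir / "spot_calls.tsv", sep="\t", index=False)
        pd.DataFrame(summary.to_rows()).to_csv(spot_dir / "summary.tsv", sep="\t", index=False)
        manifest.stage_seconds["spots"] = time.perf_counter() - t0
        _digest_dir(spot_dir)
        manifest.completed.append("spots")

        # ---- windows --------------------------------------------------------
        t0 = time.perf_counter()
        win_dir = outdir / "windows"
        win_dir.mkdir(exist_ok=True)
        sig = [s for s in spot_calls if s.significant]
        window_genes: dict[str, dict[str, str]] = {}  # compartment -> gene -> class
        marker_pos = {m.marker_id: m for m in markers}
        rows = []
        for comp in Compartment:
            comp_sig = [s for s in sig if s.compartment is comp]
            comp_markers = [marker_pos[s.marker_id] for s in comp_sig]
            gmap = map_genes_to_markers(comp_markers, genes, cfg.window_bp)
            cls_of_marker = {
                s.marker_id: (s.spot_class if s.spot_class != "none" else "cpf")
                for s in comp_sig
            }
            gene_class: dict[str, str] = {}
            for m, g, d in gmap.entries:
                cls = cls_of_marker[m]
                prev = gene_class.get(g)
                # hot outranks cold outranks cpf when a gene sits in two windows
                rank = {"hot": 2, "cold": 1, "cpf": 0}
                if prev is None or rank[cls] > rank[prev]:
                    gene_class[g] = cls
                rows.append({"compartment": comp.value, "marker_id": m,
                             "gene_id": g, "distance_bp": d, "class": cls})
            window_genes[comp.value] = gene_class
        pd.DataFrame(
            rows, columns=["compartment", "marker_id", "gene_id", "distance_bp", "class"]
        ).to_csv(win_dir / "marker_gene_map.tsv", sep="\t", index=False)
        with open(win_dir / "marker_windows.bed", "w") as fh:
            for s in sorted(sig, key=lambda s: (s.marker_id, s.compartment.value)):
                m = marker_pos[s.marker_id]
                lo = max(0, m.position_bp - cfg.window_bp)
                fh.write(f"{m.chromosome}\t{lo}\t{m.position_bp + cfg.window_bp}\t"
                         f"{m.marker_id}|{s.compartment.value}\t0\t.\n")
        manifest.stage_seconds["windows"] = time.perf_counter() - t0
        _digest_dir(win_dir)
        manifest.completed.append("windows")

        # ---- discover -------------------------------------------------------
        t0 = time.perf_counter()
        disc_dir = outdir / "networks"
        disc_dir.mkdir(exist_ok=True)
        expr_norm = znormalize_samples(expr)
        pair_list = [(e.gene_a, e.gene_b) for e in edges]
        r = compute_coexpression(expr_norm, pair_list)
        rng_disc = np.random.default_rng(manifest.stage_seeds["discover"])
        network_genes: dict[str, set[str]] = {}
        hotcold_genes: dict[str, set[str]] = {}
        for comp in Compartment:
            seeds = window_genes[comp.value]
            net = build_weighted_network(edges, locs, annots, r, seeds, cfg)
            segments = search_segments(net, cfg)
            retained = segment_significance(segments, net, cfg, rng_disc)
            hot = {g for g, c in seeds.items() if c == "hot"}
            cold = {g for g, c in seeds.items() if c == "cold"}
            spn = merge_to_spn(retained, net, hot, cold)
            spio.export_network(spn, disc_dir / f"{comp.value}_spn")
            _write_segments(retained, disc_dir / f"{comp.value}_segments.tsv")
            network_genes[comp.value] = set(spn.nodes)
            hotcold_genes[comp.value] = {
                n for n, d in spn.nodes(data=True) if d["color"] in ("red", "blue")
            }
        manifest.stage_seconds["discover"] = time.perf_counter() - t0
        _digest_dir(disc_dir)
        manifest.completed.append("discover")

        # ---- gene groups + cluster -----------------------------------------
        t0 = time.perf_counter()
        clus_dir = outdir / "clustering"
        clus_dir.mkdir(exist_ok=True)
        groups = build_gene_groups(
            {c: set(window_genes[c]) for c in window_genes}, network_genes, hotcold_genes
        )
        rng_clus = np.random.default_rng(manifest.stage_seeds["cluster"])
        clus_rows = []
        universe = sorted({e.gene_a for e in edges} | {e.gene_b for e in edges})
        for grp in groups:
            present = [g for g in grp.gene_ids if g in set(expr_norm.gene_ids)]
            if len(present) < 2:
                clus_rows.append({"group": grp.name, "n_genes": len(grp.gene_ids),
                                  "coherence": float("nan"), "random_p": float("nan")})
                continue
            res = hierarchical_cluster(expr_norm, grp)
            (clus_dir / f"{grp.name}.samples.nwk").write_text(
                linkage_to_newick(res.sample_linkage, res.sample_leaves) + "\n"
            )
            if make_plots:
                plot_heatmap(expr_norm.subset_genes(present), res,
                             str(clus_dir / f"{grp.name}.png"))
            obs, _, p_rand = coherence_vs_random(
                expr_norm, grp, n_random=50, universe=universe, rng=rng_clus
            )
            clus_rows.append({"group": grp.name, "n_genes": len(grp.gene_ids),
                              "coherence": obs, "random_p": p_rand})
        pd.DataFrame(clus_rows).to_csv(clus_dir / "coherence.tsv", sep="\t", index=False)
        manifest.stage_seconds["cluster"] = time.perf_counter() - t0
        _digest_dir(clus_dir)
        manifest.completed.append("cluster")

        # ---- global test ----------------------------------------------------
        t0 = time.perf_counter()
        gt_dir = outdir / "globaltest"
        gt_dir.mkdir(exist_ok=True)
        rng_gt = np.random.default_rng(manifest.stage_seeds["globaltest"])
        report = global_test_report(
            znormalize_samples(cell_expr), groups, positive_label="sensitive",
            B=min(cfg.permutations_B, 999), rng=rng_gt,
        )
        report.to_csv(gt_dir / "global_test.tsv", sep="\t", index=False,
                      float_format="%.6g")
        manifest.stage_seconds["globaltest"] = time.perf_counter() - t0
        _digest_dir(gt_dir)
        manifest.completed.append("globaltest")
    except Exception as exc:
        manifest.failed_stage = STAGES[len(manifest.completed)]
        manifest.write(outdir / "manifest.json")
        raise RuntimeError(f"stage {manifest.failed_stage!r} failed: {exc}") from exc

    manifest.write(outdir / "manifest.json")
    return manifest


def _write_segments(segments: Sequence[PathSegment], path: Path) -> None:
    pd.DataFrame(
        {
            "nodes": ["|".join(s.nodes) for s in segments],
            "length": [s.length for s in segments],
            "score": [s.score for s in segments],
            "p_value": [s.p_value for s in segments],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def _versions() -> dict[str, str]:
    import networkx
    import scipy
    import sklearn

    from . import __version__

    return {
        "spnkit": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "networkx": networkx.__version__,
        "sklearn": sklearn.__version__,
    }


def load_sim_params(path: str | Path) -> SimulationParams:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return SimulationParams(**raw)
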