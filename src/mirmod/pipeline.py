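"""End-to-end orchestration of the two-step module-identification method.

Step 1 clusters each side (mRNAs on map rows, miRNAs on map columns),
sweeping K over a grid for each requested dissimilarity (unguided Euclidean
on map profiles, and/or guided 1 - MRF proximity), and keeps the method and K
with the highest Pr_enrich (ties: unguided, then smallest K). Step 2 pairs
every retained miRNA cluster with every enriched mRNA cluster, counts
linearly associated predicted pairs, bootstrap-tests each candidate module
and applies the majority-targeting filter.

Stages write plain-text artefacts (TSV/JSON) so they are resumable and
independently inspectable; a JSON manifest records the seed, configuration
and per-stage entity counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .association import ModuleResult, identify_modules
from .cluster import ClusterSet, unguided_dissimilarity
from .enrichment import EnrichmentSweep, sweep_K
from .forest import ForestConfig, forest_proximity, guided_dissimilarity
from .matrices import ExpressionMatrix, MapMatrix, align_entities, write_matrix
from .report import candidate_module_count

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything needed for one pipeline run (paths excluded; the CLI reads
    files and hands matrices in)."""

    mrna_methods: tuple = ("unguided", "guided")
    mirna_methods: tuple = ("unguided",)
    algorithm: str = "pam"
    linkage: str = "average"
    mrna_k_grid: tuple = (4, 6, 8, 10)
    mirna_k_grid: tuple = (6, 9, 12)
    node_size: int = 5
    n_trees: int = 100
    num_cov: Optional[int] = None
    row_bootstrap: bool = False
    b: int = 100
    alpha: float = 0.05
    direction: str = "negative"
    majority_threshold: float = 0.5
    bh_adjust: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for methods in (self.mrna_methods, self.mirna_methods):
            for m in methods:
                if m not in ("unguided", "guided"):
                    raise ValueError(f"unknown clustering method {m!r}")
        if not self.mrna_k_grid or not self.mirna_k_grid:
            raise ValueError("K grids must be non-empty")


@dataclass
class PipelineResult:
    mrna_method: str
    mirna_method: str
    mrna_sweep: EnrichmentSweep
    mirna_sweep: EnrichmentSweep
    mrna_sweeps_by_method: dict
    mirna_sweeps_by_method: dict
    enriched_mrna_clusters: list  # (label, member ids)
    retained_mirna_clusters: list  # (label, member ids), incl. untested singletons
    modules: list  # ModuleResult
    counts: dict


def _side_sweep(
    map_matrix: MapMatrix,
    expr: Optional[ExpressionMatrix],
    axis: str,
    methods: Sequence[str],
    k_grid: Sequence[int],
    config: PipelineConfig,
    seed_seq: np.random.SeedSequence,
    keep_singletons: bool,
) -> tuple[str, EnrichmentSweep, dict]:
    """Sweep K for each requested dissimilarity; pick the higher Pr_enrich
    (unguided wins ties, being the simpler method)."""
    children = {m: s for m, s in zip(("unguided", "guided"), seed_seq.spawn(2))}
    sweeps: dict[str, EnrichmentSweep] = {}
    for method in methods:
        if method == "unguided":
            d = unguided_dissimilarity(map_matrix, axis=axis)
        else:
            if expr is None:
                raise ValueError(f"guided clustering on axis={axis} requires expression data")
            side_map = map_matrix if axis == "rows" else map_matrix.transpose()
            if side_map.row_ids != expr.row_ids:
                raise ValueError("expression matrix is not aligned with the map matrix")
            forest_seed = int(children["guided"].generate_state(1)[0] % (2**31))
            fc = ForestConfig(
                node_size=config.node_size,
                n_trees=config.n_trees,
                num_cov=config.num_cov,
                seed=forest_seed,
                row_bootstrap=config.row_bootstrap,
            )
            d = guided_dissimilarity(forest_proximity(side_map, expr, fc))
        sweep_seed = int(children[method].generate_state(2)[1] % (2**31))
        sweeps[method] = sweep_K(
            d,
            map_matrix,
            k_grid,
            B=config.b,
            alpha=config.alpha,
            seed=sweep_seed,
            axis=axis,
            algorithm=config.algorithm,
            linkage_method=config.linkage,
            method=method,
            keep_singletons=keep_singletons,
        )
        best = sweeps[method].table["pr_enrich"].max()
        logger.info(
            "axis=%s method=%s: best Pr_enrich %.3f at K=%d",
            axis, method, best, sweeps[method].selected_K,
        )
    # unguided first so it wins exact ties (the simpler method)
    ordered = [m for m in ("unguided", "guided") if m in sweeps]
    best_pr = {m: sweeps[m].table["pr_enrich"].max() for m in ordered}
    chosen = ordered[0]
    for m in ordered[1:]:
        if best_pr[m] > best_pr[chosen] + 1e-12:
            chosen = m
    return chosen, sweeps[chosen], sweeps


def run_pipeline(
    map_matrix: MapMatrix,
    mrna_expr: Optional[ExpressionMatrix],
    mirna_expr: Optional[ExpressionMatrix],
    config: PipelineConfig,
    outdir: Optional[str | Path] = None,
) -> PipelineResult:
    """Run Step 1 on both sides and Step 2 on the retained clusters."""
    counts: dict = {"mrna_in_map": map_matrix.shape[0], "mirna_in_map": map_matrix.shape[1]}
    if mrna_expr is not None:
        map_matrix, mrna_expr = align_entities(map_matrix, mrna_expr, "rows")
    if mirna_expr is not None:
        map_matrix, mirna_expr = align_entities(map_matrix, mirna_expr, "cols")
    counts["mrna_aligned"] = map_matrix.shape[0]
    counts["mirna_aligned"] = map_matrix.shape[1]
    logger.info(
        "aligned inputs: %d mRNAs x %d miRNAs", map_matrix.shape[0], map_matrix.shape[1]
    )

    root = np.random.SeedSequence(config.seed)
    mrna_seed, mirna_seed, module_seed = root.spawn(3)

    mrna_method, mrna_sweep, mrna_sweeps = _side_sweep(
        map_matrix, mrna_expr, "rows", config.mrna_methods, config.mrna_k_grid,
        config, mrna_seed, keep_singletons=False,
    )
    mirna_method, mirna_sweep, mirna_sweeps = _side_sweep(
        map_matrix, mirna_expr, "cols", config.mirna_methods, config.mirna_k_grid,
        config, mirna_seed, keep_singletons=True,
    )

    mrna_cs = mrna_sweep.selected_clusters
    mirna_cs = mirna_sweep.selected_clusters
    enriched_mrna = [
        (r.cluster_label, mrna_cs.members(r.cluster_label))
        for r in mrna_sweep.selected_results
        if r.enriched and r.tested
    ]
    retained_mirna = [
        (r.cluster_label, mirna_cs.members(r.cluster_label))
        for r in mirna_sweep.selected_results
        if r.enriched
    ]
    counts.update(
        mrna_method=mrna_method,
        mirna_method=mirna_method,
        mrna_K=mrna_sweep.selected_K,
        mirna_K=mirna_sweep.selected_K,
        enriched_mrna_clusters=len(enriched_mrna),
        retained_mirna_clusters=len(retained_mirna),
        candidate_modules=candidate_module_count(len(retained_mirna), len(enriched_mrna)),
    )
    logger.info(
        "step 1: %d enriched mRNA clusters (K=%d, %s), %d retained miRNA clusters "
        "(K=%d, %s) -> %d candidate modules",
        len(enriched_mrna), mrna_sweep.selected_K, mrna_method,
        len(retained_mirna), mirna_sweep.selected_K, mirna_method,
        counts["candidate_modules"],
    )

    if mirna_expr is None or mrna_expr is None:
        raise ValueError("step 2 requires both miRNA and mRNA expression matrices")
    modules = identify_modules(
        retained_mirna,
        enriched_mrna,
        map_matrix,
        mirna_expr,
        mrna_expr,
        direction=config.direction,
        alpha=config.alpha,
        majority_threshold=config.majority_threshold,
        B=config.b,
        rng=np.random.default_rng(module_seed),
        bh_adjust=config.bh_adjust,
    )
    counts["significant_modules"] = sum(m.significant for m in modules)
    counts["regulatory_modules"] = sum(m.regulatory for m in modules)
    logger.info(
        "step 2: %d candidate modules, %d significant, %d regulatory",
        len(modules), counts["significant_modules"], counts["regulatory_modules"],
    )

    result = PipelineResult(
        mrna_method=mrna_method,
        mirna_method=mirna_method,
        mrna_sweep=mrna_sweep,
        mirna_sweep=mirna_sweep,
        mrna_sweeps_by_method=mrna_sweeps,
        mirna_sweeps_by_method=mirna_sweeps,
        enriched_mrna_clusters=enriched_mrna,
        retained_mirna_clusters=retained_mirna,
        modules=modules,
        counts=counts,
    )
    if outdir is not None:
        _write_artifacts(result, map_matrix, config, Path(outdir))
    return result


def _write_artifacts(
    result: PipelineResult,
    map_matrix: MapMatrix,
    config: PipelineConfig,
    outdir: Path,
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for side, sweeps in (
        ("mrna", result.mrna_sweeps_by_method),
        ("mirna", result.mirna_sweeps_by_method),
    ):
        for method, sweep in sweeps.items():
            sweep.table.to_csv(outdir / f"sweep_{side}_{method}.tsv", sep="\t", index=False)
    result.mrna_sweep.selected_clusters.write(outdir / "clusters_mrna.tsv")
    result.mirna_sweep.selected_clusters.write(outdir / "clusters_mirna.tsv")
    for side, sweep in (("mrna", result.mrna_sweep), ("mirna", result.mirna_sweep)):
        payload = [r.to_dict() for r in sweep.selected_results]
        (outdir / f"enrichment_{side}.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True)
        )

    (outdir / "modules.json").write_text(
        json.dumps([m.to_dict() for m in result.modules], indent=2, sort_keys=True)
    )
    edges = []
    col_index = map_matrix.col_index()
    row_index = map_matrix.row_index()
    for module_id, m in enumerate(r for r in result.modules if r.regulatory):
        for mid in m.mirna_ids:
            for gid in m.mrna_ids:
                if map_matrix.values[row_index[gid], col_index[mid]] == 1:
                    edges.append((mid, gid, f"{m.mirna_cluster_label}_{m.mrna_cluster_label}"))
    pd.DataFrame(edges, columns=["mirna_id", "mrna_id", "module_id"]).to_csv(
        outdir / "edges.tsv", sep="\t", index=False
    )
    manifest = {
        "package": "mirmod",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "counts": result.counts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
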