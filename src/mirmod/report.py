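"""Bookkeeping arithmetic used in run manifests and study summaries."""

from __future__ import annotations

__all__ = [
    "candidate_module_count",
    "enriched_cluster_count",
    "average_cluster_size",
    "mapping_coverage_percent",
]


def candidate_module_count(n_mirna_clusters: int, n_mrna_clusters: int) -> int:
    """Number of candidate modules: R_mir x R_gene."""
    if n_mirna_clusters < 0 or n_mrna_clusters < 0:
        raise ValueError("cluster counts must be non-negative")
    return int(n_mirna_clusters) * int(n_mrna_clusters)


def enriched_cluster_count(pr_enrich: float, n_clusters: int) -> int:
    """Enriched clusters implied by a Pr_enrich fraction over n clusters."""
    if not 0.0 <= pr_enrich <= 1.0:
        raise ValueError("pr_enrich must lie in [0, 1]")
    return round(pr_enrich * n_clusters)


def average_cluster_size(n_entities: int, k: int) -> float:
    """Mean entities per cluster for a K-cluster partition."""
    if k < 1:
        raise ValueError("K must be >= 1")
    return n_entities / k


def mapping_coverage_percent(n_mapped: int, n_total: int) -> float:
    """Percentage of DE entities with target-map information."""
    if n_total < 1 or n_mapped < 0 or n_mapped > n_total:
        raise ValueError("need 0 <= n_mapped <= n_total with n_total >= 1")
    return 100.0 * n_mapped / n_total
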