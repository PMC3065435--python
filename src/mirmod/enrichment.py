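"""Cluster enrichment: the ES statistic, its bootstrap test, and the K sweep.

A cluster is "enriched" when its members' binary map profiles are closer to
one another than random sets of the same size drawn from the clustered
universe. The enrichment score of cluster k is

    ES_k = sum_{o in k} d(o, o_m) / N_k,

the mean Euclidean distance of the members' map profiles to their
componentwise median o_m (small = tight). The test draws B random clusters of
size N_k without replacement, counts W1 = #{random ES <= ES_k}, and declares
enrichment when W1/B < alpha. Pr_enrich — the fraction of size->1 clusters
that are enriched — scores a whole partition and drives the choice of K and
of guided versus unguided dissimilarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cluster import ClusterSet, DissimilarityMatrix, hclust_cluster, pam_cluster
from .matrices import MapMatrix

__all__ = [
    "EnrichmentResult",
    "EnrichmentSweep",
    "enrichment_score",
    "random_enrichment_scores",
    "bootstrap_enrichment",
    "evaluate_cluster_set",
    "sweep_K",
]


@dataclass
class EnrichmentResult:
    """Bootstrap verdict for one cluster (untested singletons carry w1 = None)."""

    cluster_label: int
    size: int
    es: float
    w1: Optional[int]
    n_random: int
    enriched: bool
    tested: bool = True

    def to_dict(self) -> dict:
        return {
            "cluster_label": int(self.cluster_label),
            "size": int(self.size),
            "es": float(self.es),
            "w1": None if self.w1 is None else int(self.w1),
            "n_random": int(self.n_random),
            "enriched": bool(self.enriched),
            "tested": bool(self.tested),
        }


@dataclass
class EnrichmentSweep:
    """Per-K Pr_enrich table and the selected partition."""

    table: pd.DataFrame  # columns: K, N_total, N_enrich, pr_enrich
    selected_K: int
    selected_clusters: ClusterSet
    selected_results: list
    results_by_K: dict = field(default_factory=dict)


def _profiles(map_matrix: MapMatrix, axis: str) -> tuple[np.ndarray, list]:
    if axis == "rows":
        return map_matrix.values.astype(float), list(map_matrix.row_ids)
    if axis == "cols":
        return map_matrix.values.T.astype(float), list(map_matrix.col_ids)
    raise ValueError("axis must be 'rows' or 'cols'")


def enrichment_score(profiles: np.ndarray) -> float:
    """Mean Euclidean distance of member profiles to their componentwise median."""
    rows = np.atleast_2d(np.asarray(profiles, dtype=float))
    if rows.size == 0:
        raise ValueError("enrichment score of an empty cluster is undefined")
    centre = np.median(rows, axis=0)
    return float(np.sqrt(((rows - centre) ** 2).sum(axis=1)).mean())


def random_enrichment_scores(
    profiles: np.ndarray,
    size: int,
    B: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """ES of B random clusters of the given size, each drawn without
    replacement from the profile universe (vectorised over replicates)."""
    n = profiles.shape[0]
    if size > n:
        raise ValueError(f"cluster size {size} exceeds universe size {n}")
    keys = rng.random((B, n))
    idx = np.argpartition(keys, size - 1, axis=1)[:, :size]
    sub = profiles[idx]  # B x size x X
    centre = np.median(sub, axis=1, keepdims=True)
    return np.sqrt(((sub - centre) ** 2).sum(axis=2)).mean(axis=1)


def bootstrap_enrichment(
    member_ids: Sequence[str],
    universe_ids: Sequence[str],
    map_matrix: MapMatrix,
    B: int = 100,
    alpha: float = 0.05,
    rng: Optional[np.random.Generator] = None,
    axis: str = "rows",
    cluster_label: int = 1,
) -> EnrichmentResult:
    """Bootstrap test of one cluster's enrichment score against random clusters."""
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(0) if rng is None else rng
    profiles, ids = _profiles(map_matrix, axis)
    index = {e: i for i, e in enumerate(ids)}
    member_idx = np.array([index[m] for m in member_ids])
    universe_idx = np.array([index[u] for u in universe_ids])
    if member_idx.size > universe_idx.size:
        raise ValueError("cluster is larger than the sampling universe")
    es_obs = enrichment_score(profiles[member_idx])
    es_rand = random_enrichment_scores(profiles[universe_idx], member_idx.size, B, rng)
    w1 = int((es_rand <= es_obs).sum())
    return EnrichmentResult(
        cluster_label=cluster_label,
        size=int(member_idx.size),
        es=es_obs,
        w1=w1,
        n_random=B,
        enriched=(w1 / B) < alpha,
    )


def evaluate_cluster_set(
    clusters: ClusterSet,
    map_matrix: MapMatrix,
    B: int = 100,
    alpha: float = 0.05,
    rng: Optional[np.random.Generator] = None,
    axis: str = "rows",
    keep_singletons: bool = False,
) -> tuple[list, float]:
    """Test every cluster of size > 1; Pr_enrich = N_enrich / N_total.

    Singleton clusters never enter N_total. With ``keep_singletons`` (the
    miRNA side: a lone miRNA can still regulate many mRNAs) they are carried
    forward untested, flagged ``tested=False`` with ``enriched=True`` so that
    downstream module search considers them.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    profiles, ids = _profiles(map_matrix, axis)
    id_index = {e: i for i, e in enumerate(ids)}
    universe_idx = np.arange(len(ids))

    results: list[EnrichmentResult] = []
    n_total = n_enrich = 0
    for label in sorted(clusters.sizes()):
        members = clusters.members(label)
        member_idx = np.array([id_index[m] for m in members])
        if member_idx.size == 1:
            if keep_singletons:
                results.append(
                    EnrichmentResult(
                        cluster_label=label,
                        size=1,
                        es=0.0,
                        w1=None,
                        n_random=B,
                        enriched=True,
                        tested=False,
                    )
                )
            continue
        es_obs = enrichment_score(profiles[member_idx])
        es_rand = random_enrichment_scores(
            profiles[universe_idx], member_idx.size, B, rng
        )
        w1 = int((es_rand <= es_obs).sum())
        enriched = (w1 / B) < alpha
        n_total += 1
        n_enrich += int(enriched)
        results.append(
            EnrichmentResult(
                cluster_label=label,
                size=int(member_idx.size),
                es=es_obs,
                w1=w1,
                n_random=B,
                enriched=enriched,
            )
        )
    if n_total == 0:
        raise ValueError("no cluster of size > 1: nothing to test for enrichment")
    return results, n_enrich / n_total


def sweep_K(
    d: DissimilarityMatrix,
    map_matrix: MapMatrix,
    K_grid: Sequence[int],
    B: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    axis: str = "rows",
    algorithm: str = "pam",
    linkage_method: str = "average",
    method: str = "unguided",
    keep_singletons: bool = False,
) -> EnrichmentSweep:
    """Cluster at each K in the grid, score each partition by Pr_enrich, and
    select the K with the highest Pr_enrich (smallest K on ties)."""
    if len(K_grid) == 0:
        raise ValueError("K grid must be non-empty")
    K_grid = sorted(set(int(k) for k in K_grid))
    if max(K_grid) > d.n:
        raise ValueError(f"K={max(K_grid)} exceeds the number of entities ({d.n})")

    seed_seq = np.random.SeedSequence(seed)
    children = seed_seq.spawn(2 * len(K_grid))
    rows = []
    clusters_by_K: dict[int, ClusterSet] = {}
    results_by_K: dict[int, list] = {}
    for pos, K in enumerate(K_grid):
        cluster_seed = int(children[2 * pos].generate_state(1)[0] % (2**31))
        if algorithm == "pam":
            cs = pam_cluster(d, K, seed=cluster_seed, method=method)
        elif algorithm == "hclust":
            cs = hclust_cluster(d, K, linkage_method=linkage_method, method=method)
        else:
            raise ValueError("algorithm must be 'pam' or 'hclust'")
        rng = np.random.default_rng(children[2 * pos + 1])
        results, pr = evaluate_cluster_set(
            cs, map_matrix, B=B, alpha=alpha, rng=rng, axis=axis,
            keep_singletons=keep_singletons,
        )
        tested = [r for r in results if r.tested]
        rows.append(
            {
                "K": K,
                "N_total": len(tested),
                "N_enrich": sum(r.enriched for r in tested),
                "pr_enrich": pr,
            }
        )
        clusters_by_K[K] = cs
        results_by_K[K] = results

    table = pd.DataFrame(rows)
    best_pr = table["pr_enrich"].max()
    selected_K = int(table.loc[table["pr_enrich"] >= best_pr - 1e-12, "K"].min())
    return EnrichmentSweep(
        table=table,
        selected_K=selected_K,
        selected_clusters=clusters_by_K[selected_K],
        selected_results=results_by_K[selected_K],
        results_by_K=results_by_K,
    )
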