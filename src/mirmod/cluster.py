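"""Dissimilarities and clustering (PAM k-medoids, agglomerative comparator).

Unguided clustering works on Euclidean distances between binary map-matrix
profiles (rows for mRNAs, columns for miRNAs); guided clustering supplies
1 - forest-proximity instead. Either dissimilarity is partitioned with PAM
(partitioning around medoids: greedy BUILD followed by best-improvement SWAP)
or, for comparison, with agglomerative hierarchical clustering cut at K.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .matrices import MapMatrix

__all__ = [
    "DissimilarityMatrix",
    "ClusterSet",
    "unguided_dissimilarity",
    "KMedoids",
    "pam_cluster",
    "hclust_cluster",
]


@dataclass
class DissimilarityMatrix:
    """Symmetric non-negative dissimilarity with a zero diagonal."""

    ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("dissimilarity shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValueError("dissimilarity must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("dissimilarity diagonal must be zero")
        if v.min() < -1e-12:
            raise ValueError("dissimilarity entries must be non-negative")
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        self.values = np.clip(v, 0.0, None)

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class ClusterSet:
    """A K-cluster partition of labelled entities.

    ``labels`` holds cluster labels 1..K aligned with ``ids``; ``medoid_ids``
    is one representative per cluster for PAM (None for hierarchical).
    """

    ids: list
    labels: np.ndarray
    K: int
    method: str = "unguided"
    algorithm: str = "pam"
    medoid_ids: Optional[list] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.ids),):
            raise ValueError("labels must align with ids")
        if self.labels.min() < 1 or self.labels.max() > self.K:
            raise ValueError("labels must lie in 1..K")

    def members(self, label: int) -> list:
        return [i for i, l in zip(self.ids, self.labels) if l == label]

    def sizes(self) -> dict[int, int]:
        uniq, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(uniq.tolist(), counts.tolist()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"entity_id": self.ids, "cluster_label": self.labels})

    def write(self, tsv_path: str | Path) -> None:
        """2-column TSV plus a JSON sidecar with the run metadata."""
        tsv_path = Path(tsv_path)
        self.to_frame().to_csv(tsv_path, sep="\t", index=False)
        sidecar = {
            "K": int(self.K),
            "method": self.method,
            "algorithm": self.algorithm,
            "medoids": self.medoid_ids,
            "seed": self.seed,
        }
        tsv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))

    @classmethod
    def read(cls, tsv_path: str | Path) -> "ClusterSet":
        tsv_path = Path(tsv_path)
        frame = pd.read_csv(tsv_path, sep="\t", dtype={"entity_id": str, "cluster_label": int})
        meta = {}
        sidecar = tsv_path.with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        labels = frame["cluster_label"].to_numpy()
        return cls(
            ids=list(frame["entity_id"]),
            labels=labels,
            K=int(meta.get("K", labels.max())),
            method=meta.get("method", "unguided"),
            algorithm=meta.get("algorithm", "pam"),
            medoid_ids=meta.get("medoids"),
            seed=meta.get("seed"),
        )


def unguided_dissimilarity(map_matrix: MapMatrix, axis: str = "rows") -> DissimilarityMatrix:
    """Euclidean distance between binary map profiles (mRNA rows or miRNA columns)."""
    if axis == "rows":
        profiles, ids = map_matrix.values, map_matrix.row_ids
    elif axis == "cols":
        profiles, ids = map_matrix.values.T, map_matrix.col_ids
    else:
        raise ValueError("axis must be 'rows' or 'cols'")
    return DissimilarityMatrix(list(ids), squareform(pdist(profiles.astype(float))))


class KMedoids(BaseEstimator, ClusterMixin):
    """PAM (partitioning around medoids) on a precomputed dissimilarity.

    BUILD greedily selects K initial medoids; SWAP repeatedly evaluates every
    (medoid, non-medoid) exchange and applies the one giving the largest
    strict cost decrease, until none improves. Cost is the total dissimilarity
    of entities to their nearest medoid. ``random_state`` only breaks ties
    among equal-cost choices.

    Attributes (after ``fit``): ``medoid_indices_``, ``labels_`` (0-based),
    ``inertia_``.
    """

    def __init__(self, n_clusters: int = 2, random_state: int = 0):
        self.n_clusters = n_clusters
        self.random_state = random_state

    @staticmethod
    def _assignment_cost(d: np.ndarray, medoids: np.ndarray) -> float:
        return float(d[:, medoids].min(axis=1).sum())

    def fit(self, D, y=None) -> "KMedoids":
        d = D.values if isinstance(D, DissimilarityMatrix) else np.asarray(D, dtype=float)
        n = d.shape[0]
        k = self.n_clusters
        if not 1 <= k <= n:
            raise ValueError(f"n_clusters={k} must be in 1..{n}")
        rng = np.random.default_rng(self.random_state)

        def tie_pick(values: np.ndarray, best: float) -> int:
            ties = np.flatnonzero(np.abs(values - best) <= 1e-12)
            return int(ties[0] if ties.size == 1 else rng.choice(ties))

        # BUILD: first medoid minimises total dissimilarity, then greedy adds.
        totals = d.sum(axis=0)
        medoids = [tie_pick(totals, totals.min())]
        nearest = d[:, medoids[0]].copy()
        while len(medoids) < k:
            gains = np.maximum(nearest[:, None] - d, 0.0).sum(axis=0)
            gains[medoids] = -np.inf
            c = tie_pick(gains, gains.max())
            medoids.append(c)
            nearest = np.minimum(nearest, d[:, c])

        medoids = np.array(sorted(medoids))
        cost = self._assignment_cost(d, medoids)

        # SWAP: best strict improvement over all (medoid out, candidate in).
        while True:
            med_d = d[:, medoids]  # n x k
            order = np.argsort(med_d, axis=1)
            nearest_d = med_d[np.arange(n), order[:, 0]]
            second_d = med_d[np.arange(n), order[:, 1]] if k > 1 else np.full(n, np.inf)
            nearest_pos = order[:, 0]
            is_medoid = np.zeros(n, dtype=bool)
            is_medoid[medoids] = True
            candidates = np.flatnonzero(~is_medoid)
            best_cost, best_swaps = cost, []
            for pos in range(k):
                # distance to the nearest medoid once medoids[pos] is removed
                without = np.where(nearest_pos == pos, second_d, nearest_d)
                if candidates.size == 0:
                    continue
                new_costs = np.minimum(without[:, None], d[:, candidates]).sum(axis=0)
                local_best = new_costs.min()
                if local_best < best_cost - 1e-12:
                    best_cost = local_best
                    best_swaps = [(pos, int(c)) for c in candidates[
                        np.flatnonzero(np.abs(new_costs - local_best) <= 1e-12)
                    ]]
                elif abs(local_best - best_cost) <= 1e-12 and best_swaps:
                    best_swaps.extend(
                        (pos, int(c))
                        for c in candidates[np.flatnonzero(np.abs(new_costs - local_best) <= 1e-12)]
                    )
            if not best_swaps or best_cost >= cost - 1e-12:
                break
            pos, c = best_swaps[0] if len(best_swaps) == 1 else best_swaps[
                int(rng.integers(len(best_swaps)))
            ]
            medoids = medoids.copy()
            medoids[pos] = c
            medoids = np.array(sorted(medoids))
            cost = best_cost

        self.medoid_indices_ = medoids
        self.labels_ = np.argmin(d[:, medoids], axis=1)
        self.inertia_ = self._assignment_cost(d, medoids)
        return self

    def fit_predict(self, D, y=None) -> np.ndarray:
        return self.fit(D).labels_


def pam_cluster(
    d: DissimilarityMatrix,
    K: int,
    seed: int = 0,
    method: str = "unguided",
) -> ClusterSet:
    """Run PAM on a dissimilarity matrix and return a labelled partition."""
    est = KMedoids(n_clusters=K, random_state=seed).fit(d)
    return ClusterSet(
        ids=list(d.ids),
        labels=est.labels_ + 1,
        K=K,
        method=method,
        algorithm="pam",
        medoid_ids=[d.ids[m] for m in est.medoid_indices_],
        seed=seed,
    )


def hclust_cluster(
    d: DissimilarityMatrix,
    K: int,
    linkage_method: str = "average",
    method: str = "unguided",
) -> ClusterSet:
    """Agglomerative hierarchical clustering cut at K clusters."""
    if linkage_method not in ("average", "complete"):
        raise ValueError("linkage must be 'average' or 'complete'")
    if not 1 <= K <= d.n:
        raise ValueError(f"K={K} must be in 1..{d.n}")
    if d.n == 1:
        labels = np.array([1])
    else:
        z = linkage(squareform(d.values, checks=False), method=linkage_method)
        labels = fcluster(z, t=K, criterion="maxclust")
    return ClusterSet(
        ids=list(d.ids),
        labels=labels,
        K=K,
        method=method,
        algorithm="hclust",
        medoid_ids=None,
    )
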