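"""Multivariate random forest (MRF) proximity for guided clustering.

The forest grows multivariate regression trees over the entities being
clustered (mRNAs, or miRNAs on the transposed map). Candidate splits are the
binary columns of the target-prediction map: splitting on miRNA ``i`` sends
every mRNA targeted by ``i`` to one child and the rest to the other. A split
is scored in expression space by the drop in node homogeneity

    f(BN, DN1, DN2) = S(BN) - S(DN1) - S(DN2),

where S(node) is the sum over members of squared Euclidean distance between
the member's expression profile and the node's mean profile. At each node a
random subset of ``num_cov`` map columns is tried and the best admissible
split taken; a node with at most ``node_size`` members, or with no admissible
sampled split, is terminal. The forest proximity of two entities is the
fraction of trees in which they share a terminal node, and 1 - proximity is
the guided dissimilarity handed to clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator

from .matrices import ExpressionMatrix, MapMatrix

__all__ = [
    "ForestConfig",
    "TreeNode",
    "ProximityMatrix",
    "node_homogeneity",
    "split_score",
    "grow_tree",
    "forest_proximity",
    "guided_dissimilarity",
    "MRFProximity",
]


@dataclass
class ForestConfig:
    """Forest hyper-parameters.

    node_size
        A node with at most this many members is terminal, and both children
        of an admissible split must have at least this many members.
    n_trees
        Number of trees N; proximity averages N same-leaf indicators.
    num_cov
        Number of map columns sampled (without replacement) per node; ``None``
        means round(sqrt(X)).
    row_bootstrap
        Grow each tree on a bootstrap sample of rows (off by default: the
        only randomness is then the per-node covariate subsample).
    """

    node_size: int = 5
    n_trees: int = 100
    num_cov: Optional[int] = None
    seed: int = 0
    row_bootstrap: bool = False

    def __post_init__(self) -> None:
        if self.node_size < 1:
            raise ValueError("node_size must be >= 1")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.num_cov is not None and self.num_cov < 1:
            raise ValueError("num_cov must be >= 1")

    def resolve_num_cov(self, n_covariates: int) -> int:
        m = self.num_cov if self.num_cov is not None else int(round(np.sqrt(n_covariates)))
        m = max(1, m)
        if m > n_covariates:
            raise ValueError(f"num_cov={m} exceeds the number of covariates ({n_covariates})")
        return m


@dataclass
class TreeNode:
    """A node of a multivariate regression tree (member row indices plus,
    for internal nodes, the splitting map column and two children)."""

    member_indices: np.ndarray
    split_covariate: Optional[int] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None

    @property
    def is_terminal(self) -> bool:
        return self.split_covariate is None

    def leaves(self) -> list["TreeNode"]:
        if self.is_terminal:
            return [self]
        return self.left.leaves() + self.right.leaves()


@dataclass
class ProximityMatrix:
    ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("proximity shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValueError("proximity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("proximity diagonal must be 1")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("proximity entries must lie in [0, 1]")
        self.values = np.clip(v, 0.0, 1.0)


def node_homogeneity(expr_rows: np.ndarray) -> float:
    """S(node): sum of squared Euclidean distances to the mean profile."""
    rows = np.atleast_2d(np.asarray(expr_rows, dtype=float))
    if rows.size == 0:
        raise ValueError("node homogeneity of an empty member set is undefined")
    centred = rows - rows.mean(axis=0)
    return float(np.einsum("ij,ij->", centred, centred))


def _sum_sq(rows: np.ndarray) -> float:
    centred = rows - rows.mean(axis=0)
    return float(np.einsum("ij,ij->", centred, centred))


def split_score(
    member_indices: np.ndarray,
    covariate: int,
    map_values: np.ndarray,
    expr_values: np.ndarray,
    node_size: int = 1,
) -> Optional[float]:
    """Homogeneity gain of splitting a node on one map column.

    Members with map entry 1 for ``covariate`` form one child, the rest the
    other. Returns ``None`` (undefined) when either child would be empty or
    smaller than ``node_size``; otherwise S(parent) - S(left) - S(right),
    which is non-negative (the between-child sum of squares).
    """
    members = np.asarray(member_indices)
    if members.size < 2:
        raise ValueError("a node needs at least two members to be split")
    targeted = map_values[members, covariate] == 1
    n_left = int(targeted.sum())
    n_right = members.size - n_left
    if n_left < node_size or n_right < node_size or n_left == 0 or n_right == 0:
        return None
    parent_rows = expr_values[members]
    return _sum_sq(parent_rows) - _sum_sq(parent_rows[targeted]) - _sum_sq(parent_rows[~targeted])


def _grow(
    members: np.ndarray,
    map_values: np.ndarray,
    expr_values: np.ndarray,
    node_size: int,
    num_cov: int,
    rng: np.random.Generator,
) -> TreeNode:
    node = TreeNode(member_indices=members)
    if members.size <= node_size:
        return node
    n_cov_total = map_values.shape[1]
    candidates = rng.choice(n_cov_total, size=num_cov, replace=False)
    best_score = None
    best_covs: list[int] = []
    for cov in candidates:
        score = split_score(members, int(cov), map_values, expr_values, node_size)
        if score is None:
            continue
        if best_score is None or score > best_score + 1e-12:
            best_score, best_covs = score, [int(cov)]
        elif abs(score - best_score) <= 1e-12:
            best_covs.append(int(cov))
    if best_score is None:
        return node  # no admissible sampled split
    cov = best_covs[0] if len(best_covs) == 1 else int(best_covs[rng.integers(len(best_covs))])
    targeted = map_values[members, cov] == 1
    node.split_covariate = cov
    node.left = _grow(members[targeted], map_values, expr_values, node_size, num_cov, rng)
    node.right = _grow(members[~targeted], map_values, expr_values, node_size, num_cov, rng)
    return node


def grow_tree(
    map_matrix: MapMatrix,
    expr: ExpressionMatrix,
    config: ForestConfig,
    rng: np.random.Generator,
    row_indices: Optional[np.ndarray] = None,
) -> TreeNode:
    """Grow one multivariate regression tree over the map-matrix rows."""
    if map_matrix.row_ids != expr.row_ids:
        raise ValueError("map matrix and expression matrix must be row-aligned")
    num_cov = config.resolve_num_cov(map_matrix.shape[1])
    members = (
        np.arange(map_matrix.shape[0]) if row_indices is None else np.asarray(row_indices)
    )
    return _grow(members, map_matrix.values, expr.values, config.node_size, num_cov, rng)


def _leaf_labels(root: TreeNode, map_values: np.ndarray) -> np.ndarray:
    """Route every row of the map matrix to a terminal node; returns leaf ids."""
    n = map_values.shape[0]
    labels = np.zeros(n, dtype=np.int64)
    stack = [(root, np.arange(n))]
    leaf_id = 0
    while stack:
        node, rows = stack.pop()
        if node.is_terminal:
            labels[rows] = leaf_id
            leaf_id += 1
            continue
        targeted = map_values[rows, node.split_covariate] == 1
        stack.append((node.left, rows[targeted]))
        stack.append((node.right, rows[~targeted]))
    return labels


def forest_proximity(
    map_matrix: MapMatrix,
    expr: ExpressionMatrix,
    config: ForestConfig,
) -> ProximityMatrix:
    """Average same-terminal-node indicator over N independently grown trees."""
    n = map_matrix.shape[0]
    counts = np.zeros((n, n), dtype=np.int64)
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_trees)
    for ss in seeds:
        rng = np.random.default_rng(ss)
        row_indices = None
        if config.row_bootstrap:
            row_indices = rng.integers(0, n, size=n)
        root = grow_tree(map_matrix, expr, config, rng, row_indices=row_indices)
        labels = _leaf_labels(root, map_matrix.values)
        counts += labels[:, None] == labels[None, :]
    return ProximityMatrix(list(map_matrix.row_ids), counts / config.n_trees)


def guided_dissimilarity(prox: ProximityMatrix):
    """1 - proximity: the dissimilarity handed to guided clustering."""
    from .cluster import DissimilarityMatrix

    values = 1.0 - prox.values
    np.fill_diagonal(values, 0.0)
    return DissimilarityMatrix(list(prox.ids), values)


class MRFProximity(BaseEstimator):
    """Multivariate-random-forest proximity as an sklearn-style estimator.

    ``fit(map_matrix, expr)`` grows the forest and exposes ``proximity_``
    (a :class:`ProximityMatrix`) and ``dissimilarity_`` (1 - proximity).

    Parameters mirror :class:`ForestConfig`.
    """

    def __init__(
        self,
        node_size: int = 5,
        n_trees: int = 100,
        num_cov: Optional[int] = None,
        row_bootstrap: bool = False,
        random_state: int = 0,
    ):
        self.node_size = node_size
        self.n_trees = n_trees
        self.num_cov = num_cov
        self.row_bootstrap = row_bootstrap
        self.random_state = random_state

    def fit(self, map_matrix: MapMatrix, expr: ExpressionMatrix) -> "MRFProximity":
        config = ForestConfig(
            node_size=self.node_size,
            n_trees=self.n_trees,
            num_cov=self.num_cov,
            seed=self.random_state,
            row_bootstrap=self.row_bootstrap,
        )
        self.proximity_ = forest_proximity(map_matrix, expr, config)
        self.dissimilarity_ = guided_dissimilarity(self.proximity_)
        return self

    def transform(self, map_matrix: MapMatrix = None, expr: ExpressionMatrix = None):
        if not hasattr(self, "dissimilarity_"):
            raise AttributeError("MRFProximity is not fitted yet; call fit first")
        return self.dissimilarity_
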