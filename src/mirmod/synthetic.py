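"""Synthetic data with planted, recoverable miRNA-mRNA modules.

The generator emulates the inputs the pipeline expects after upstream
differential-expression filtering: a sparse binary target-prediction map and
matched log2 fold-change profiles over T conditions. Each planted module is a
block of miRNAs and a block of mRNAs: within the block target predictions are
dense (Bernoulli ``in_module_target_prob``), elsewhere sparse (Bernoulli
``background_target_prob``). Module miRNAs behave like a co-expressed family:
each member's profile is a shared module trajectory (standard Gaussian over
conditions) plus N(0, noise_sd) member deviation. A planted mRNA follows

    u = alpha + beta * mean(module miRNA profiles) + N(0, noise_sd),

with a negative slope beta drawn from ``beta_range``, so every in-module
predicted pair carries a genuine (negative) linear association. Background
entities have independent standard-Gaussian profiles. A pure-null generator
provides calibration data with no structure at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .matrices import ExpressionMatrix, MapMatrix

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "generate",
    "generate_null",
    "module_recovery",
    "planted_mrna_ari",
]


@dataclass
class SyntheticSpec:
    """Parameters of the planted-module generator (defaults: a small study
    with 300 mRNAs, 30 miRNAs, 5 non-reference conditions, 3 modules)."""

    y: int = 300
    x: int = 30
    t: int = 5
    n_modules: int = 3
    module_mirna_sizes: tuple = (3, 3, 3)
    module_mrna_sizes: tuple = (30, 30, 30)
    in_module_target_prob: float = 0.95
    background_target_prob: float = 0.02
    beta_range: tuple = (-2.0, -1.0)
    noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.module_mirna_sizes) != self.n_modules:
            raise ValueError("module_mirna_sizes must have n_modules entries")
        if len(self.module_mrna_sizes) != self.n_modules:
            raise ValueError("module_mrna_sizes must have n_modules entries")
        if sum(self.module_mirna_sizes) > self.x:
            raise ValueError("planted miRNA blocks exceed X")
        if sum(self.module_mrna_sizes) > self.y:
            raise ValueError("planted mRNA blocks exceed Y")
        for p in (self.in_module_target_prob, self.background_target_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("target probabilities must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.t < 1 or self.y < 1 or self.x < 1:
            raise ValueError("Y, X, T must be positive")


@dataclass
class SyntheticTruth:
    """Generated data plus the planted ground truth."""

    map_matrix: MapMatrix
    mirna_expr: ExpressionMatrix
    mrna_expr: ExpressionMatrix
    mirna_modules: list  # list of miRNA id lists, one per planted module
    mrna_modules: list  # list of mRNA id lists, one per planted module
    true_beta: np.ndarray  # Y x X; NaN outside planted modules
    spec: SyntheticSpec | None = None

    @property
    def n_modules(self) -> int:
        return len(self.mirna_modules)

    def truth_dict(self) -> dict:
        return {
            "n_modules": self.n_modules,
            "mirna_modules": [list(m) for m in self.mirna_modules],
            "mrna_modules": [list(m) for m in self.mrna_modules],
        }


def _ids(prefix: str, n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def generate(spec: SyntheticSpec) -> SyntheticTruth:
    """Generate a map matrix and matched expression with planted modules."""
    rng = np.random.default_rng(spec.seed)
    mrna_ids = _ids("gene", spec.y)
    mirna_ids = _ids("mir", spec.x)

    # contiguous planted blocks, background entities after them
    mirna_blocks, mrna_blocks = [], []
    mi = mj = 0
    for a, b in zip(spec.module_mirna_sizes, spec.module_mrna_sizes):
        mirna_blocks.append(np.arange(mi, mi + a))
        mrna_blocks.append(np.arange(mj, mj + b))
        mi += a
        mj += b

    map_values = (rng.random((spec.y, spec.x)) < spec.background_target_prob).astype(np.int8)
    for rows, cols in zip(mrna_blocks, mirna_blocks):
        # family members share their off-module target set, as same-family
        # miRNAs do in sequence-based prediction databases
        family_bg = (rng.random(spec.y) < spec.background_target_prob).astype(np.int8)
        map_values[:, cols] = family_bg[:, None]
        block = rng.random((rows.size, cols.size)) < spec.in_module_target_prob
        map_values[np.ix_(rows, cols)] = block.astype(np.int8)

    # an entity enters the map only if some database predicts a pair for it:
    # give empty rows one predicted unit each so the universe has no all-zero
    # profiles (mirrors the upstream inclusion rule of real map matrices).
    # A "unit" is a planted family or a lone background miRNA, so family
    # members keep identical off-module target sets.
    planted = set()
    units = []
    for cols in mirna_blocks:
        units.append(np.asarray(cols))
        planted.update(int(c) for c in cols)
    units.extend(np.array([i]) for i in range(spec.x) if i not in planted)
    for j in np.flatnonzero(map_values.sum(axis=1) == 0):
        map_values[j, units[rng.integers(len(units))]] = 1
    for i in np.flatnonzero(map_values.sum(axis=0) == 0):
        map_values[rng.integers(spec.y), i] = 1

    mirna_values = rng.standard_normal((spec.x, spec.t))
    for cols in mirna_blocks:
        trajectory = rng.standard_normal(spec.t)
        mirna_values[cols] = trajectory[None, :] + spec.noise_sd * rng.standard_normal(
            (cols.size, spec.t)
        )

    mrna_values = rng.standard_normal((spec.y, spec.t))
    true_beta = np.full((spec.y, spec.x), np.nan)
    for rows, cols in zip(mrna_blocks, mirna_blocks):
        v_mean = mirna_values[cols].mean(axis=0)
        betas = rng.uniform(spec.beta_range[0], spec.beta_range[1], size=rows.size)
        alphas = rng.normal(0.0, 0.5, size=rows.size)
        noise = spec.noise_sd * rng.standard_normal((rows.size, spec.t))
        mrna_values[rows] = alphas[:, None] + betas[:, None] * v_mean[None, :] + noise
        true_beta[np.ix_(rows, cols)] = betas[:, None]

    conditions = [f"t{k + 1}" for k in range(spec.t)]
    return SyntheticTruth(
        map_matrix=MapMatrix(mrna_ids, mirna_ids, map_values),
        mirna_expr=ExpressionMatrix(mirna_ids, conditions, mirna_values),
        mrna_expr=ExpressionMatrix(mrna_ids, conditions, mrna_values),
        mirna_modules=[[mirna_ids[i] for i in cols] for cols in mirna_blocks],
        mrna_modules=[[mrna_ids[j] for j in rows] for rows in mrna_blocks],
        true_beta=true_beta,
        spec=spec,
    )


def module_recovery(
    regulatory_modules: Sequence,
    truth: SyntheticTruth,
    min_jaccard: float = 0.5,
) -> dict:
    """Match reported regulatory modules against the planted ones.

    A module matches planted module p when the Jaccard index of its miRNA set
    with p's miRNAs and of its mRNA set with p's mRNAs are both at least
    ``min_jaccard``. Returns the number of planted modules recovered, the
    number of false (unmatched) regulatory modules, and module-level
    precision/recall.
    """

    def jaccard(a, b) -> float:
        a, b = set(a), set(b)
        return len(a & b) / len(a | b) if a | b else 1.0

    recovered: set[int] = set()
    n_false = 0
    for module in regulatory_modules:
        matched = False
        for p, (mirs, genes) in enumerate(zip(truth.mirna_modules, truth.mrna_modules)):
            if (
                jaccard(module.mirna_ids, mirs) >= min_jaccard
                and jaccard(module.mrna_ids, genes) >= min_jaccard
            ):
                recovered.add(p)
                matched = True
        n_false += not matched
    n_reported = len(list(regulatory_modules))
    return {
        "n_recovered": len(recovered),
        "n_planted": truth.n_modules,
        "n_false": n_false,
        "precision": (n_reported - n_false) / n_reported if n_reported else 1.0,
        "recall": len(recovered) / truth.n_modules if truth.n_modules else 1.0,
    }


def planted_mrna_ari(cluster_ids: Sequence[str], cluster_labels, truth: SyntheticTruth) -> float:
    """Adjusted Rand between the recovered mRNA partition and the planted one,
    restricted to planted mRNAs."""
    from sklearn.metrics import adjusted_rand_score

    label_of = dict(zip(cluster_ids, cluster_labels))
    true_labels, pred_labels = [], []
    for p, genes in enumerate(truth.mrna_modules):
        for g in genes:
            true_labels.append(p)
            pred_labels.append(label_of[g])
    return float(adjusted_rand_score(true_labels, pred_labels))


def generate_null(
    y: int,
    x: int,
    t: int,
    target_prob: float = 0.1,
    seed: int = 0,
) -> SyntheticTruth:
    """Structure-free data: i.i.d. Bernoulli map, independent Gaussian
    expression on both sides, zero planted modules (calibration null)."""
    if not 0.0 <= target_prob <= 1.0:
        raise ValueError("target_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    mrna_ids = _ids("gene", y)
    mirna_ids = _ids("mir", x)
    conditions = [f"t{k + 1}" for k in range(t)]
    return SyntheticTruth(
        map_matrix=MapMatrix(
            mrna_ids, mirna_ids, (rng.random((y, x)) < target_prob).astype(np.int8)
        ),
        mirna_expr=ExpressionMatrix(mirna_ids, conditions, rng.standard_normal((x, t))),
        mrna_expr=ExpressionMatrix(mrna_ids, conditions, rng.standard_normal((y, t))),
        mirna_modules=[],
        mrna_modules=[],
        true_beta=np.full((y, x), np.nan),
        spec=None,
    )
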