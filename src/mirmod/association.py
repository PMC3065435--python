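"""Step 2: linear miRNA-mRNA association and bootstrap module significance.

For a candidate module (miRNA cluster m, mRNA cluster n) every predicted pair
is fitted with the linear model u = alpha + beta * v, where v is the miRNA's
and u the mRNA's log2 fold-change profile over the T non-reference
conditions. The slope is tested with a t-test on T - 2 degrees of freedom;
the pipeline default is the one-sided negative alternative (miRNAs repress
their direct targets), with two-sided and positive modes available.
Assoc(m, n) counts the predicted-and-significant pairs; its significance is
judged against Assoc(m, n*) for B random mRNA clusters of the same size, and
a module is called potentially regulatory when the bootstrap test rejects and
every member miRNA targets a majority of the module's mRNAs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .matrices import ExpressionMatrix, MapMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PairAssociation",
    "PairwiseAssociation",
    "ModuleResult",
    "fit_pair",
    "pairwise_association",
    "module_assoc_count",
    "bootstrap_module_test",
    "identify_modules",
]

_DIRECTIONS = ("two_sided", "negative", "positive")


@dataclass
class PairAssociation:
    """OLS fit and verdict for one (miRNA, mRNA) pair."""

    mirna_id: str
    mrna_id: str
    predicted: bool
    alpha_hat: float
    beta_hat: float
    t_stat: float
    p_value: float
    associated: bool
    estimable: bool = True


@dataclass
class PairwiseAssociation:
    """Vectorised per-pair OLS over all Y x X pairs.

    Arrays are Y x X, indexed by (mRNA, miRNA); ``associated`` already folds
    in the prediction flag, the significance level and the sign constraint.
    """

    mrna_ids: list
    mirna_ids: list
    predicted: np.ndarray
    alpha_hat: np.ndarray
    beta_hat: np.ndarray
    t_stat: np.ndarray
    p_value: np.ndarray
    associated: np.ndarray
    direction: str
    alpha_level: float


@dataclass
class ModuleResult:
    """One candidate module: a miRNA cluster paired with an mRNA cluster."""

    mirna_cluster_label: int
    mrna_cluster_label: int
    mirna_ids: list
    mrna_ids: list
    n_mir: int
    n_gene: int
    assoc_count: int
    w2: int
    n_random: int
    p_boot: float
    targeting_fraction: dict
    significant: bool
    regulatory: bool
    p_boot_adjusted: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "mirna_cluster_label": int(self.mirna_cluster_label),
            "mrna_cluster_label": int(self.mrna_cluster_label),
            "mirna_ids": list(self.mirna_ids),
            "mrna_ids": list(self.mrna_ids),
            "n_mir": int(self.n_mir),
            "n_gene": int(self.n_gene),
            "assoc_count": int(self.assoc_count),
            "w2": int(self.w2),
            "n_random": int(self.n_random),
            "p_boot": float(self.p_boot),
            "targeting_fraction": {k: float(v) for k, v in self.targeting_fraction.items()},
            "significant": bool(self.significant),
            "regulatory": bool(self.regulatory),
            "p_boot_adjusted": None
            if self.p_boot_adjusted is None
            else float(self.p_boot_adjusted),
        }


def _p_from_t(t: np.ndarray, df: int, direction: str) -> np.ndarray:
    if direction == "two_sided":
        return 2.0 * stats.t.sf(np.abs(t), df)
    if direction == "negative":
        return stats.t.cdf(t, df)
    if direction == "positive":
        return stats.t.sf(t, df)
    raise ValueError(f"direction must be one of {_DIRECTIONS}")


def _sign_ok(beta: np.ndarray, direction: str) -> np.ndarray:
    if direction == "negative":
        return beta < 0
    if direction == "positive":
        return beta > 0
    return np.ones_like(beta, dtype=bool)


def fit_pair(
    v: np.ndarray,
    u: np.ndarray,
    direction: str = "negative",
    alpha_level: float = 0.05,
    predicted: bool = True,
    mirna_id: str = "",
    mrna_id: str = "",
) -> PairAssociation:
    """OLS fit of u = alpha + beta v with a t-test on beta.

    A constant miRNA profile makes the slope inestimable (flagged, never
    associated); a perfect fit gives p = 0 with a logged warning.
    """
    v = np.asarray(v, dtype=float)
    u = np.asarray(u, dtype=float)
    if v.shape != u.shape or v.ndim != 1:
        raise ValueError("u and v must be 1-D vectors of equal length")
    t_obs = v.size
    if t_obs < 3:
        raise ValueError("at least 3 conditions are required (df = T - 2 >= 1)")
    if direction not in _DIRECTIONS:
        raise ValueError(f"direction must be one of {_DIRECTIONS}")

    vc = v - v.mean()
    sxx = float(vc @ vc)
    if sxx <= 1e-24 * max(1.0, float(v @ v)):
        return PairAssociation(
            mirna_id, mrna_id, predicted,
            alpha_hat=np.nan, beta_hat=np.nan, t_stat=np.nan, p_value=np.nan,
            associated=False, estimable=False,
        )
    beta = float(vc @ (u - u.mean())) / sxx
    alpha_hat = float(u.mean() - beta * v.mean())
    resid = u - (alpha_hat + beta * v)
    rss = float(resid @ resid)
    df = t_obs - 2
    scale = max(float(u @ u), 1.0)
    if rss <= 1e-24 * scale:
        logger.warning("fit_pair(%s, %s): perfect fit, p-value set to 0", mirna_id, mrna_id)
        t_stat = np.inf if beta > 0 else (-np.inf if beta < 0 else 0.0)
        p = float(_p_from_t(np.array(t_stat), df, direction))
    else:
        se = np.sqrt(rss / df / sxx)
        t_stat = beta / se
        p = float(_p_from_t(np.array(t_stat), df, direction))
    associated = bool(predicted and p < alpha_level and _sign_ok(np.array(beta), direction))
    return PairAssociation(
        mirna_id, mrna_id, predicted,
        alpha_hat=alpha_hat, beta_hat=beta, t_stat=float(t_stat), p_value=p,
        associated=associated,
    )


def pairwise_association(
    mirna_expr: ExpressionMatrix,
    mrna_expr: ExpressionMatrix,
    map_matrix: MapMatrix,
    direction: str = "negative",
    alpha_level: float = 0.05,
) -> PairwiseAssociation:
    """Fit u = alpha + beta v for every (mRNA, miRNA) pair, vectorised.

    Matches :func:`fit_pair` exactly; pairs with an inestimable slope (a
    constant miRNA profile) get NaN statistics and are never associated.
    """
    if mirna_expr.condition_ids != mrna_expr.condition_ids:
        raise ValueError("miRNA and mRNA expression matrices must share conditions")
    if map_matrix.row_ids != mrna_expr.row_ids or map_matrix.col_ids != mirna_expr.row_ids:
        raise ValueError("expression matrices must be aligned to the map matrix")
    if direction not in _DIRECTIONS:
        raise ValueError(f"direction must be one of {_DIRECTIONS}")
    t_obs = len(mirna_expr.condition_ids)
    if t_obs < 3:
        raise ValueError("at least 3 conditions are required (df = T - 2 >= 1)")
    df = t_obs - 2

    u = mrna_expr.values  # Y x T
    vmat = mirna_expr.values  # X x T
    y, x = u.shape[0], vmat.shape[0]
    uc = u - u.mean(axis=1, keepdims=True)
    vc = vmat - vmat.mean(axis=1, keepdims=True)
    sxx = np.einsum("it,it->i", vc, vc)  # X
    estimable = sxx > 1e-24 * np.maximum(1.0, np.einsum("it,it->i", vmat, vmat))

    sxy = uc @ vc.T  # Y x X
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx[None, :]
        alpha_hat = u.mean(axis=1)[:, None] - beta * vmat.mean(axis=1)[None, :]
        syy = np.einsum("jt,jt->j", uc, uc)  # Y
        rss = np.maximum(syy[:, None] - beta * sxy, 0.0)
        scale = np.maximum(np.einsum("jt,jt->j", u, u), 1.0)[:, None]
        perfect = rss <= 1e-24 * scale
        se = np.sqrt(rss / df / sxx[None, :])
        t_stat = beta / se
        perfect_t = np.where(beta > 0, np.inf, np.where(beta < 0, -np.inf, 0.0))
        t_stat = np.where(perfect, perfect_t, t_stat)
        p = _p_from_t(t_stat, df, direction)
    beta[:, ~estimable] = np.nan
    alpha_hat[:, ~estimable] = np.nan
    t_stat[:, ~estimable] = np.nan
    p[:, ~estimable] = np.nan

    predicted = map_matrix.values.astype(bool)
    with np.errstate(invalid="ignore"):
        associated = (
            predicted
            & estimable[None, :]
            & (p < alpha_level)
            & _sign_ok(beta, direction)
        )
    return PairwiseAssociation(
        mrna_ids=list(map_matrix.row_ids),
        mirna_ids=list(map_matrix.col_ids),
        predicted=predicted,
        alpha_hat=alpha_hat,
        beta_hat=beta,
        t_stat=t_stat,
        p_value=p,
        associated=associated,
        direction=direction,
        alpha_level=alpha_level,
    )


def module_assoc_count(
    pairwise: PairwiseAssociation,
    mirna_idx: np.ndarray,
    mrna_idx: np.ndarray,
) -> int:
    """Assoc(m, n): predicted pairs between the clusters with a significant slope."""
    return int(pairwise.associated[np.ix_(np.asarray(mrna_idx), np.asarray(mirna_idx))].sum())


def bootstrap_module_test(
    pairwise: PairwiseAssociation,
    mirna_idx: np.ndarray,
    observed_count: int,
    n_gene: int,
    B: int = 100,
    alpha: float = 0.05,
    rng: Optional[np.random.Generator] = None,
) -> tuple[int, float, bool]:
    """Compare Assoc(m, n) with Assoc(m, n*) over B random mRNA clusters.

    Random clusters of size ``n_gene`` are drawn without replacement from all
    mRNAs in the map matrix. W2 counts random counts >= observed; the module
    association is significant when W2/B < alpha.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    n_universe = pairwise.associated.shape[0]
    if n_gene > n_universe:
        raise ValueError("random cluster size exceeds the mRNA universe")
    per_mrna = pairwise.associated[:, np.asarray(mirna_idx)].sum(axis=1)  # Y
    keys = rng.random((B, n_universe))
    idx = np.argpartition(keys, n_gene - 1, axis=1)[:, :n_gene]
    counts = per_mrna[idx].sum(axis=1)
    w2 = int((counts >= observed_count).sum())
    p_boot = w2 / B
    return w2, p_boot, p_boot < alpha


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n - 1, -1, -1):
        running = min(running, p[order[rank]] * n / (rank + 1))
        adj[order[rank]] = running
    return adj


def identify_modules(
    mirna_clusters: Sequence[tuple[int, Sequence[str]]],
    mrna_clusters: Sequence[tuple[int, Sequence[str]]],
    map_matrix: MapMatrix,
    mirna_expr: ExpressionMatrix,
    mrna_expr: ExpressionMatrix,
    direction: str = "negative",
    alpha: float = 0.05,
    majority_threshold: float = 0.5,
    B: int = 100,
    rng: Optional[np.random.Generator] = None,
    bh_adjust: bool = False,
) -> list[ModuleResult]:
    """Evaluate all R_mir x R_gene candidate modules.

    A module is potentially regulatory when (i) its association count is
    bootstrap-significant and (ii) every member miRNA targets more than
    ``majority_threshold`` of the module's mRNAs. ``bh_adjust`` optionally
    Benjamini-Hochberg-adjusts the bootstrap p-values across candidates (off
    by default); the significance verdict then uses the adjusted values.
    """
    if len(mirna_clusters) == 0 or len(mrna_clusters) == 0:
        raise ValueError("at least one cluster is required on each side")
    rng = np.random.default_rng(0) if rng is None else rng
    pairwise = pairwise_association(mirna_expr, mrna_expr, map_matrix, direction, alpha)
    row_index = map_matrix.row_index()
    col_index = map_matrix.col_index()

    results: list[ModuleResult] = []
    for m_label, mirna_ids in mirna_clusters:
        mirna_idx = np.array([col_index[i] for i in mirna_ids])
        for n_label, mrna_ids in mrna_clusters:
            mrna_idx = np.array([row_index[j] for j in mrna_ids])
            observed = module_assoc_count(pairwise, mirna_idx, mrna_idx)
            w2, p_boot, significant = bootstrap_module_test(
                pairwise, mirna_idx, observed, mrna_idx.size, B=B, alpha=alpha, rng=rng
            )
            fractions = {
                mid: float(map_matrix.values[mrna_idx, col_index[mid]].mean())
                for mid in mirna_ids
            }
            results.append(
                ModuleResult(
                    mirna_cluster_label=m_label,
                    mrna_cluster_label=n_label,
                    mirna_ids=list(mirna_ids),
                    mrna_ids=list(mrna_ids),
                    n_mir=len(mirna_ids),
                    n_gene=len(mrna_ids),
                    assoc_count=observed,
                    w2=w2,
                    n_random=B,
                    p_boot=p_boot,
                    targeting_fraction=fractions,
                    significant=significant,
                    regulatory=False,
                )
            )
    if bh_adjust:
        adj = _bh_adjust(np.array([r.p_boot for r in results]))
        for r, a in zip(results, adj):
            r.p_boot_adjusted = float(a)
            r.significant = a < alpha
    for r in results:
        r.regulatory = bool(
            r.significant and min(r.targeting_fraction.values()) > majority_threshold
        )
    return results
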