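"""Labelled matrices for miRNA-mRNA module discovery, and their TSV I/O.

Two containers run through the whole pipeline:

* :class:`MapMatrix` — a binary Y x X target-prediction map; entry ``[j, i]``
  is 1 iff miRNA ``i`` is predicted to target mRNA ``j``.
* :class:`ExpressionMatrix` — a Z x T matrix of log2 fold-changes versus a
  reference condition for Z entities (mRNAs or miRNAs) over T conditions
  (time points or patient categories).

Both are thin wrappers around a NumPy array plus label lists; they convert
to/from :class:`pandas.DataFrame` and read/write tab-separated text with a
header row and first-column labels (the corner cell is present but ignored).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MapMatrix",
    "ExpressionMatrix",
    "PredictionSource",
    "ProbesetExpression",
    "read_matrix",
    "write_matrix",
    "read_prediction_source",
    "build_map_matrix",
    "collapse_probesets",
    "align_entities",
]


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate {what} labels: {dupes[:5]}")
    return ids


@dataclass
class MapMatrix:
    """Binary target-prediction map: rows are mRNAs, columns are miRNAs."""

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.row_ids = _check_unique(self.row_ids, "row")
        self.col_ids = _check_unique(self.col_ids, "column")
        values = np.asarray(self.values)
        if values.ndim != 2 or values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError(
                f"values shape {values.shape} does not match labels "
                f"({len(self.row_ids)}, {len(self.col_ids)})"
            )
        if values.size == 0:
            raise ValueError("map matrix must have at least one row and one column")
        if not np.isin(values, (0, 1)).all():
            bad = np.unique(values[~np.isin(values, (0, 1))])
            raise ValueError(f"map matrix entries must be 0/1; found {bad[:5]}")
        self.values = values.astype(np.int8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def transpose(self) -> "MapMatrix":
        """Swap label roles: the miRNA-side map (X x Y) used for miRNA clustering."""
        return MapMatrix(list(self.col_ids), list(self.row_ids), self.values.T.copy())

    def row_index(self) -> dict[str, int]:
        return {r: i for i, r in enumerate(self.row_ids)}

    def col_index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.col_ids)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)


@dataclass
class ExpressionMatrix:
    """Log2 fold-change profiles: rows are entities, columns are conditions."""

    row_ids: list[str]
    condition_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.row_ids = _check_unique(self.row_ids, "row")
        self.condition_ids = [str(c) for c in self.condition_ids]
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape != (
            len(self.row_ids),
            len(self.condition_ids),
        ):
            raise ValueError(
                f"values shape {values.shape} does not match labels "
                f"({len(self.row_ids)}, {len(self.condition_ids)})"
            )
        if len(self.condition_ids) < 1:
            raise ValueError("expression matrix needs at least one condition")
        if not np.isfinite(values).all():
            raise ValueError("expression matrix entries must be finite")
        self.values = values

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row_index(self) -> dict[str, int]:
        return {r: i for i, r in enumerate(self.row_ids)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.condition_ids)


@dataclass
class PredictionSource:
    """One target-prediction database: a named set of (mRNA, miRNA) pairs."""

    source_name: str
    pairs: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.pairs = {(str(a), str(b)) for a, b in self.pairs}


@dataclass
class ProbesetExpression:
    """One probeset's per-condition log2 fold-changes, tied to a parent entity."""

    probeset_id: str
    parent_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("probeset values must be a 1-D vector")


def _read_frame(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if frame.index.has_duplicates:
        raise ValueError(f"{path}: duplicate row labels")
    if frame.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate column labels")
    if frame.isna().any().any():
        raise ValueError(f"{path}: ragged rows or missing values")
    return frame


def read_matrix(path: str | Path, kind: str) -> MapMatrix | ExpressionMatrix:
    """Read a labelled TSV matrix.

    Parameters
    ----------
    path
        Tab-separated file; first row = column labels, first column = row labels.
    kind
        ``"map"`` (binary target map, entries validated to be 0/1) or
        ``"expression"`` (real-valued log2 fold-changes).
    """
    frame = _read_frame(path)
    if kind == "map":
        try:
            values = frame.to_numpy(dtype=float)
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric entry in map matrix") from exc
        if not np.isin(values, (0.0, 1.0)).all():
            raise ValueError(f"{path}: map matrix entries must be 0 or 1")
        return MapMatrix(list(frame.index), list(frame.columns), values.astype(np.int8))
    if kind == "expression":
        try:
            values = frame.to_numpy(dtype=float)
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric entry in expression matrix") from exc
        return ExpressionMatrix(list(frame.index), list(frame.columns), values)
    raise ValueError(f"unknown matrix kind {kind!r} (expected 'map' or 'expression')")


def write_matrix(matrix: MapMatrix | ExpressionMatrix, path: str | Path) -> None:
    """Write a labelled matrix as TSV; floats use repr precision so the file
    round-trips bit-exact through :func:`read_matrix`."""
    frame = matrix.to_frame()
    if isinstance(matrix, ExpressionMatrix):
        frame = frame.map(repr)
    frame.to_csv(path, sep="\t", index_label="id")


def read_prediction_source(path: str | Path, source_name: str | None = None) -> PredictionSource:
    """Read a 2-column TSV (mRNA_id, miRNA_id) as one prediction source."""
    frame = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if frame.shape[1] != 2:
        raise ValueError(f"{path}: expected exactly two columns (mRNA_id, miRNA_id)")
    name = source_name if source_name is not None else Path(path).stem
    return PredictionSource(name, set(zip(frame[0], frame[1])))


def build_map_matrix(
    sources: Sequence[PredictionSource],
    min_support: int,
    mrna_universe: Sequence[str],
    mirna_universe: Sequence[str],
) -> MapMatrix:
    """Combine prediction sources by a vote rule.

    Entry ``[j, i]`` is 1 iff the pair (mRNA j, miRNA i) occurs in at least
    ``min_support`` distinct sources (the published analysis required support
    from at least two of four databases). Rows and columns are restricted to
    the given universes, in the given order.
    """
    if len(sources) == 0:
        raise ValueError("at least one prediction source is required")
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    mrna_universe = _check_unique(mrna_universe, "mRNA universe")
    mirna_universe = _check_unique(mirna_universe, "miRNA universe")
    if not mrna_universe or not mirna_universe:
        raise ValueError("universes must be non-empty")

    row_idx = {r: j for j, r in enumerate(mrna_universe)}
    col_idx = {c: i for i, c in enumerate(mirna_universe)}
    support = np.zeros((len(mrna_universe), len(mirna_universe)), dtype=np.int32)
    for source in sources:
        for mrna, mirna in source.pairs:
            j = row_idx.get(mrna)
            i = col_idx.get(mirna)
            if j is not None and i is not None:
                support[j, i] += 1
    return MapMatrix(mrna_universe, mirna_universe, (support >= min_support).astype(np.int8))


def collapse_probesets(
    probesets: Iterable[ProbesetExpression],
    parent_ids: Sequence[str],
    condition_ids: Sequence[str] | None = None,
) -> ExpressionMatrix:
    """Collapse probeset-level fold-changes to one row per parent entity.

    The per-condition value of a parent is the median over its probesets
    (midpoint of the two central values for even counts).
    """
    parent_ids = _check_unique(parent_ids, "parent")
    by_parent: dict[str, list[np.ndarray]] = {p: [] for p in parent_ids}
    t = None
    for ps in probesets:
        if t is None:
            t = len(ps.values)
        elif len(ps.values) != t:
            raise ValueError("probesets disagree on the number of conditions")
        if ps.parent_id in by_parent:
            by_parent[ps.parent_id].append(ps.values)
    missing = [p for p, rows in by_parent.items() if not rows]
    if missing:
        raise ValueError(f"parents with no probeset: {missing[:5]}")
    values = np.vstack([np.median(np.vstack(by_parent[p]), axis=0) for p in parent_ids])
    if condition_ids is None:
        condition_ids = [f"c{k + 1}" for k in range(values.shape[1])]
    return ExpressionMatrix(parent_ids, list(condition_ids), values)


def align_entities(
    map_matrix: MapMatrix,
    expr: ExpressionMatrix,
    axis: str,
) -> tuple[MapMatrix, ExpressionMatrix]:
    """Restrict a map matrix and an expression matrix to their shared entities.

    ``axis="rows"`` aligns map rows (mRNAs) with expression rows;
    ``axis="cols"`` aligns map columns (miRNAs) with expression rows. Order
    follows the map matrix; dropped identifiers are logged as a warning.
    """
    if axis not in ("rows", "cols"):
        raise ValueError("axis must be 'rows' or 'cols'")
    map_ids = map_matrix.row_ids if axis == "rows" else map_matrix.col_ids
    expr_set = set(expr.row_ids)
    shared = [i for i in map_ids if i in expr_set]
    if not shared:
        raise ValueError("no shared identifiers between map matrix and expression matrix")
    dropped = sorted((set(map_ids) | expr_set) - set(shared))
    if dropped:
        logger.warning(
            "align_entities(axis=%s): dropped %d identifiers: %s%s",
            axis,
            len(dropped),
            ", ".join(dropped[:10]),
            "..." if len(dropped) > 10 else "",
        )
    expr_idx = expr.row_index()
    expr_aligned = ExpressionMatrix(
        shared, list(expr.condition_ids), expr.values[[expr_idx[i] for i in shared]]
    )
    if axis == "rows":
        map_idx = map_matrix.row_index()
        map_aligned = MapMatrix(
            shared, list(map_matrix.col_ids), map_matrix.values[[map_idx[i] for i in shared]]
        )
    else:
        map_idx = map_matrix.col_index()
        map_aligned = MapMatrix(
            list(map_matrix.row_ids), shared, map_matrix.values[:, [map_idx[i] for i in shared]]
        )
    return map_aligned, expr_aligned
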