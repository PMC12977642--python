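"""Row z-scoring, pairwise distances and average-linkage clustering.

The clustering contract mirrors the heatmap analysis of the study: protein
profiles are z-scored row-wise, distances are Euclidean (default) or
Pearson (1 - correlation), and samples/proteins are merged by unweighted
average linkage (UPGMA-style). Merging is fully deterministic: at every
step the pair of clusters with the smallest mean inter-cluster distance is
joined, ties broken by the lowest (row, col) index pair in the current
cluster ordering (original leaf order, merged clusters appended).

The qualitative grouping claims ("the treated line groups with the
reference") become testable assertions via :func:`first_merge_partner`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import (
    MatrixError,
    ShapeError,
    UndefinedCorrelationError,
    UnknownLeafError,
)

__all__ = [
    "LinkageTree",
    "Merge",
    "zscore_rows",
    "pairwise_distance",
    "average_linkage",
    "first_merge_partner",
    "to_newick",
    "merge_table",
    "heatmap",
]


def zscore_rows(m: pd.DataFrame) -> pd.DataFrame:
    """Standardise each row to mean 0 and sample sd 1 (n-1 denominator).

    Constant rows carry no clustering signal and map to all-zeros rather
    than erroring.
    """
    if m.shape[1] < 2:
        raise ShapeError(
            f"z-scoring needs >= 2 columns, got {m.shape[1]}"
        )
    values = m.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    centred = values - mean
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, centred / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(z, index=m.index, columns=m.columns)


def pairwise_distance(
    m: pd.DataFrame,
    metric: Literal["euclidean", "pearson"] = "euclidean",
    axis: Literal["rows", "cols"] = "cols",
) -> pd.DataFrame:
    """Symmetric distance matrix between rows or columns.

    ``pearson`` is the correlation distance 1 - r; it is undefined for a
    zero-variance vector and raises :class:`UndefinedCorrelationError`.
    """
    if m.isna().to_numpy().any():
        raise MatrixError("profile matrix must be complete (no NaN)")
    if axis == "cols":
        vectors = m.to_numpy(dtype=float).T
        labels = list(m.columns)
    elif axis == "rows":
        vectors = m.to_numpy(dtype=float)
        labels = list(m.index)
    else:
        raise ValueError(f"axis must be 'rows' or 'cols', got {axis!r}")
    if metric == "euclidean":
        d = squareform(pdist(vectors, metric="euclidean"))
    elif metric == "pearson":
        sd = vectors.std(axis=1)
        flat = [labels[i] for i in np.nonzero(sd == 0)[0]]
        if flat:
            raise UndefinedCorrelationError(
                f"Pearson distance undefined for zero-variance vectors: {flat}"
            )
        d = squareform(pdist(vectors, metric="correlation"))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return pd.DataFrame(d, index=labels, columns=labels)


@dataclass(frozen=True)
class Merge:
    """One agglomeration step: clusters ``a`` and ``b`` join at ``height``."""

    a: frozenset[str]
    b: frozenset[str]
    height: float

    @property
    def members(self) -> frozenset[str]:
        return self.a | self.b


@dataclass(frozen=True)
class LinkageTree:
    leaves: tuple[str, ...]
    merges: tuple[Merge, ...]

    def __post_init__(self) -> None:
        if len(self.merges) != len(self.leaves) - 1:
            raise MatrixError(
                f"{len(self.leaves)} leaves need {len(self.leaves) - 1} "
                f"merges, got {len(self.merges)}"
            )


def _check_distance_matrix(d: pd.DataFrame) -> np.ndarray:
    values = d.to_numpy(dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise MatrixError(f"distance matrix must be square, got {values.shape}")
    if list(d.index) != list(d.columns):
        raise MatrixError("distance matrix index and columns must agree")
    if not np.allclose(values, values.T, rtol=1e-9, atol=1e-12):
        raise MatrixError("distance matrix is not symmetric")
    if not np.allclose(np.diag(values), 0.0, atol=1e-12):
        raise MatrixError("distance matrix diagonal must be zero")
    if (values < 0).any():
        raise MatrixError("distances must be non-negative")
    return values


def average_linkage(d: pd.DataFrame) -> LinkageTree:
    """Unweighted average-linkage (UPGMA-style) agglomeration.

    Maintains the exact mean of pairwise original distances between
    clusters through the Lance-Williams update
    ``d(a+b, c) = (|a| d(a,c) + |b| d(b,c)) / (|a| + |b|)``.
    """
    values = _check_distance_matrix(d)
    n = values.shape[0]
    if n < 2:
        raise MatrixError("clustering needs at least 2 items")
    labels = [str(x) for x in d.index]
    clusters: list[frozenset[str]] = [frozenset({lab}) for lab in labels]
    sizes = [1] * n
    dist = values.copy()
    merges: list[Merge] = []
    while len(clusters) > 1:
        m = len(clusters)
        best = None
        best_pair = (-1, -1)
        for i in range(m):
            for j in range(i + 1, m):
                if best is None or dist[i, j] < best:
                    best = dist[i, j]
                    best_pair = (i, j)
        i, j = best_pair
        merges.append(Merge(a=clusters[i], b=clusters[j], height=float(best)))
        merged = clusters[i] | clusters[j]
        ni, nj = sizes[i], sizes[j]
        new_row = (ni * dist[i, :] + nj * dist[j, :]) / (ni + nj)
        keep = [k for k in range(m) if k not in (i, j)]
        dist = np.pad(dist[np.ix_(keep, keep)], ((0, 1), (0, 1)))
        dist[-1, :-1] = new_row[keep]
        dist[:-1, -1] = new_row[keep]
        clusters = [clusters[k] for k in keep] + [merged]
        sizes = [sizes[k] for k in keep] + [ni + nj]
    return LinkageTree(leaves=tuple(labels), merges=tuple(merges))


def first_merge_partner(
    tree: LinkageTree, leaf: str
) -> str | frozenset[str]:
    """What the query leaf first joins: a leaf id, or a cluster of leaves.

    Used to assert grouping statements, e.g. that the treated sample's
    first merge partner is the reference sample.
    """
    if leaf not in tree.leaves:
        raise UnknownLeafError(leaf)
    for merge in tree.merges:
        if leaf in merge.members:
            other = merge.b if leaf in merge.a else merge.a
            if len(other) == 1:
                return next(iter(other))
            return other
    raise UnknownLeafError(leaf)  # pragma: no cover - n>=2 guarantees a merge


def merge_table(tree: LinkageTree) -> pd.DataFrame:
    """Flat TSV-ready view of the merge list."""
    rows = [
        {
            "step": i + 1,
            "cluster_a": ";".join(sorted(m.a)),
            "cluster_b": ";".join(sorted(m.b)),
            "height": m.height,
        }
        for i, m in enumerate(tree.merges)
    ]
    return pd.DataFrame(rows, columns=["step", "cluster_a", "cluster_b", "height"])


def to_newick(tree: LinkageTree) -> str:
    """Newick serialization with ultrametric branch lengths (height/2)."""
    node_height: dict[frozenset[str], float] = {
        frozenset({leaf}): 0.0 for leaf in tree.leaves
    }
    node_repr: dict[frozenset[str], str] = {
        frozenset({leaf}): leaf for leaf in tree.leaves
    }
    last: frozenset[str] | None = None
    for merge in tree.merges:
        h = merge.height / 2.0
        parts = []
        for child in (merge.a, merge.b):
            length = h - node_height[child]
            parts.append(f"{node_repr[child]}:{length:.10g}")
        key = merge.members
        node_repr[key] = "(" + ",".join(parts) + ")"
        node_height[key] = h
        last = key
    assert last is not None
    return node_repr[last] + ";"


def heatmap(m: pd.DataFrame, tree: LinkageTree | None = None, ax=None):
    """Thin presentation layer: draw a z-scored profile matrix.

    Rendering only; excluded from any numeric contract.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(
            figsize=(max(4, 0.5 * m.shape[1] + 2), max(3, 0.12 * m.shape[0]))
        )
    im = ax.imshow(m.to_numpy(dtype=float), aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(m.shape[1]), labels=[str(c) for c in m.columns])
    ax.set_yticks(range(m.shape[0]), labels=[str(i) for i in m.index])
    ax.figure.colorbar(im, ax=ax, label="z-score")
    return ax
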