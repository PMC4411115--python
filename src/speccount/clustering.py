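"""Agglomerative hierarchical clustering of runs or proteins.

Distances are euclidean (L2 on expression vectors) or correlation
(1 - Pearson r, with zero-variance vectors flagged and assigned distance 1).
The agglomeration is the classic O(n^3) scheme with single / complete /
average linkage and a deterministic tie-break: among equally close pairs the
one with the lowest (i, j) node indices merges first, so results are
byte-stable across runs.  Node indexing follows the scipy convention
(leaves 0..n-1, the k-th merge creates node n+k).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Tuple

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .errors import ValidationError

__all__ = ["Dendrogram", "distance_matrix", "hierarchical_cluster", "cophenetic_matrix"]

LINKAGES = ("single", "complete", "average")


def distance_matrix(expr, axis: str = "runs", metric: str = "euclidean") -> pd.DataFrame:
    """Symmetric zero-diagonal distance matrix over runs or proteins."""
    if isinstance(expr, ExpressionMatrix):
        df = expr.values
    else:
        df = pd.DataFrame(expr)
    if axis == "runs":
        X = df.to_numpy().T
        labels = list(df.columns)
    elif axis == "proteins":
        X = df.to_numpy()
        labels = list(df.index)
    else:
        raise ValidationError(f"axis must be 'runs' or 'proteins', got {axis!r}")
    n = X.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 items to compute distances")

    if metric == "euclidean":
        diff = X[:, None, :] - X[None, :, :]
        D = np.sqrt((diff**2).sum(axis=2))
    elif metric == "correlation":
        sd = X.std(axis=1)
        flat = sd == 0
        if flat.any():
            warnings.warn(
                f"{int(flat.sum())} zero-variance vector(s); correlation distance set to 1",
                RuntimeWarning,
                stacklevel=2,
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.corrcoef(X)
        D = 1.0 - C
        D[np.isnan(D)] = 1.0
        np.fill_diagonal(D, 0.0)
        D = np.clip(D, 0.0, None)
    else:
        raise ValidationError(f"metric must be 'euclidean' or 'correlation', got {metric!r}")
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=labels, columns=labels)


@dataclass(frozen=True)
class Dendrogram:
    """Binary merge tree: leaves plus n-1 (node_i, node_j, height, size) merges."""

    leaves: tuple
    merges: tuple  # of (int, int, float, int)

    def __post_init__(self):
        if len(self.merges) != max(len(self.leaves) - 1, 0):
            raise ValidationError("a dendrogram over n leaves needs exactly n-1 merges")

    def node_leafsets(self) -> Dict[int, FrozenSet[str]]:
        """Leaf-label set under every node (leaves and internal)."""
        n = len(self.leaves)
        sets: Dict[int, FrozenSet[str]] = {i: frozenset([self.leaves[i]]) for i in range(n)}
        for k, (i, j, _, _) in enumerate(self.merges):
            sets[n + k] = sets[i] | sets[j]
        return sets

    def clades(self) -> List[FrozenSet[str]]:
        """Leaf sets of the internal nodes, in merge order."""
        sets = self.node_leafsets()
        n = len(self.leaves)
        return [sets[n + k] for k in range(len(self.merges))]

    def heights(self) -> List[float]:
        return [h for _, _, h, _ in self.merges]

    def to_linkage_matrix(self) -> np.ndarray:
        """scipy-compatible (n-1) x 4 linkage matrix."""
        return np.array([[i, j, h, s] for i, j, h, s in self.merges], dtype=float)

    def to_newick(self) -> str:
        """Newick string; branch lengths are height differences (leaf height 0)."""
        n = len(self.leaves)
        height: Dict[int, float] = {i: 0.0 for i in range(n)}
        text: Dict[int, str] = {i: self.leaves[i] for i in range(n)}
        for k, (i, j, h, _) in enumerate(self.merges):
            node = n + k
            bi = max(h - height[i], 0.0)
            bj = max(h - height[j], 0.0)
            text[node] = f"({text[i]}:{bi:.10g},{text[j]}:{bj:.10g})"
            height[node] = h
        root = n + len(self.merges) - 1 if self.merges else 0
        return text[root] + ";"


def _update(linkage: str, d_xi: float, d_xj: float, si: int, sj: int) -> float:
    if linkage == "single":
        return min(d_xi, d_xj)
    if linkage == "complete":
        return max(d_xi, d_xj)
    return (si * d_xi + sj * d_xj) / (si + sj)  # average (UPGMA)


def hierarchical_cluster(d, linkage: str = "complete") -> Dendrogram:
    """Agglomerate a distance matrix into a dendrogram.

    Ties at equal merge distance break to the lowest (i, j) node-index pair.
    """
    if linkage not in LINKAGES:
        raise ValidationError(f"linkage must be one of {LINKAGES}, got {linkage!r}")
    if isinstance(d, pd.DataFrame):
        labels = [str(c) for c in d.columns]
        D = d.to_numpy(dtype=float)
    else:
        D = np.asarray(d, dtype=float)
        labels = [str(i) for i in range(D.shape[0])]
    n = D.shape[0]
    if D.shape != (n, n) or n < 2:
        raise ValidationError("distance matrix must be square with n >= 2")
    if not np.allclose(D, D.T) or (np.diag(D) != 0).any() or (D < 0).any():
        raise ValidationError("invalid distance matrix")

    dist: Dict[Tuple[int, int], float] = {
        (i, j): float(D[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    size = {i: 1 for i in range(n)}
    active = set(range(n))
    merges = []
    next_id = n
    while len(active) > 1:
        (bi, bj) = min(dist, key=lambda ij: (dist[ij], ij))
        h = dist[(bi, bj)]
        new = next_id
        next_id += 1
        size[new] = size[bi] + size[bj]
        merges.append((bi, bj, h, size[new]))
        active.discard(bi)
        active.discard(bj)
        for x in active:
            d_xi = dist.pop((min(x, bi), max(x, bi)))
            d_xj = dist.pop((min(x, bj), max(x, bj)))
            dist[(x, new)] = _update(linkage, d_xi, d_xj, size[bi], size[bj])
        del dist[(bi, bj)]
        active.add(new)
    return Dendrogram(tuple(labels), tuple(merges))


def cophenetic_matrix(dend: Dendrogram) -> pd.DataFrame:
    """Pairwise cophenetic distances (height of the lowest common merge)."""
    n = len(dend.leaves)
    sets = dend.node_leafsets()
    M = np.zeros((n, n))
    pos = {lab: i for i, lab in enumerate(dend.leaves)}
    for k, (i, j, h, _) in enumerate(dend.merges):
        for a in sets[i]:
            for b in sets[j]:
                M[pos[a], pos[b]] = M[pos[b], pos[a]] = h
    return pd.DataFrame(M, index=dend.leaves, columns=dend.leaves)
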