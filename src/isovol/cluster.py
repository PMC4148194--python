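"""Jaccard distances between cavity fields and UPGMA dendrograms.

The Jaccard distance 1 - V(A∩B)/V(A∪B) compares two solids without bias from
their total volume; a family of cavity fields is summarised by UPGMA
(unweighted pair-group method with arithmetic mean): iteratively merge the
closest pair of clusters at height d/2 and update distances to the merged
cluster by the size-weighted mean of the members' distances.  Trees are
serialised as Newick with branch lengths equal to height differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .solids import SolidRegion, jaccard_distance

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "pairwise_jaccard",
    "upgma",
    "to_newick",
]


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if np.any(np.isnan(self.d)):
            raise ValueError("distance matrix contains NaN entries")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be nonnegative")


@dataclass
class Merge:
    left: int
    right: int
    height: float
    size: int


@dataclass
class Dendrogram:
    """Merge list over leaves 0..n-1; internal node i is n + merge index."""

    labels: list[str]
    merges: list[Merge]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def cophenetic_matrix(self) -> np.ndarray:
        """Pairwise cophenetic distances (2 x merge height of the join)."""
        n = self.n_leaves
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        out = np.zeros((n, n))
        for m_idx, m in enumerate(self.merges):
            left = members.pop(m.left)
            right = members.pop(m.right)
            for i in left:
                for j in right:
                    out[i, j] = out[j, i] = 2.0 * m.height
            members[n + m_idx] = left + right
        return out


def pairwise_jaccard(
    fields: list[SolidRegion], labels: list[str]
) -> DistanceMatrix:
    """All-pairs Jaccard distances among solids on congruent lattices.

    A pair of empty solids is identically empty and gets distance 0 (with a
    warning); the 0/0 Jaccard ratio is otherwise undefined.
    """
    if len(fields) < 2:
        raise ValueError("need at least two fields to compare")
    if len(labels) != len(fields):
        raise ValueError("labels must match fields")
    for f in fields[1:]:
        fields[0].lattice.require_congruent(f.lattice, "pairwise Jaccard")
    n = len(fields)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if fields[i].is_empty() and fields[j].is_empty():
                logger.warning(
                    "fields %r and %r are both empty; distance set to 0",
                    labels[i], labels[j],
                )
                dij = 0.0
            else:
                dij = jaccard_distance(fields[i], fields[j])
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(labels=list(labels), d=d)


def upgma(dm: DistanceMatrix) -> Dendrogram:
    """UPGMA clustering: merge the closest pair at height d/2; distances to
    the merged cluster are size-weighted arithmetic means.  Ties are broken
    by the smallest (i, j) in original label order (clusters ordered by the
    smallest leaf they contain)."""
    n = len(dm.labels)
    if n < 2:
        raise ValueError("need at least two labels")
    # active clusters: node id -> (size, smallest original leaf)
    size = {i: 1 for i in range(n)}
    rep = {i: i for i in range(n)}  # tie-break representative
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(dm.d[i, j])
    active = list(range(n))
    merges: list[Merge] = []
    next_id = n

    def get(u: int, v: int) -> float:
        return dist[(u, v) if u < v else (v, u)]

    while len(active) > 1:
        best = None
        for ii in range(len(active)):
            for jj in range(ii + 1, len(active)):
                u, v = active[ii], active[jj]
                ru, rv = sorted((rep[u], rep[v]))
                key = (get(u, v), ru, rv)
                if best is None or key < best[0]:
                    best = (key, u, v)
        (dmin, _, _), u, v = best
        if rep[v] < rep[u]:
            u, v = v, u
        new = next_id
        next_id += 1
        merges.append(Merge(left=u, right=v, height=dmin / 2.0,
                            size=size[u] + size[v]))
        for w in active:
            if w in (u, v):
                continue
            duw, dvw = get(u, w), get(v, w)
            dnew = (size[u] * duw + size[v] * dvw) / (size[u] + size[v])
            dist[(min(new, w), max(new, w))] = dnew
        size[new] = size[u] + size[v]
        rep[new] = min(rep[u], rep[v])
        active = [w for w in active if w not in (u, v)] + [new]
    return Dendrogram(labels=list(dm.labels), merges=merges)


def _sanitize(label: str) -> str:
    out = label.replace(" ", "_")
    for ch in "();:,'[]":
        out = out.replace(ch, "")
    return out


def to_newick(t: Dendrogram) -> str:
    """Newick serialisation with branch lengths = height differences."""
    n = t.n_leaves
    height = {i: 0.0 for i in range(n)}
    text: dict[int, str] = {i: _sanitize(t.labels[i]) for i in range(n)}
    node = None
    for m_idx, m in enumerate(t.merges):
        node = n + m_idx
        bl_left = m.height - height[m.left]
        bl_right = m.height - height[m.right]
        text[node] = (
            f"({text[m.left]}:{bl_left:g},{text[m.right]}:{bl_right:g})"
        )
        height[node] = m.height
    if node is None:
        raise ValueError("dendrogram has no merges")
    return text[node] + ";"
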