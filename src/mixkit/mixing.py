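"""Group partitions, edge counts, and (adjusted) mixing matrices.

The mixing matrix **e** is the central object of categorical-attribute
mixing analysis: entry ``e[i, j]`` is the fraction of edges running from
group *i* to group *j*.  For undirected networks the matrix is symmetric,
with intra-group edges on the diagonal (``e_ii = E_ii / E``) and each
inter-group edge split half-and-half across the two off-diagonal cells
(``e_ij = e_ji = E_ij / 2E``), so that the matrix always sums to one.

The *adjusted* mixing matrix divides each entry by the product of group
fractions ``f_i f_j``, removing the purely combinatorial advantage larger
groups have in forming ties ("pool of opportunities"), and renormalizes
so the result is again a proper mixing matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GroupPartition",
    "EdgeCounts",
    "MixingMatrix",
    "build_partition",
    "count_edges",
    "mixing_matrix",
    "adjust",
]

_SUM_TOL = 1e-12


@dataclass(frozen=True)
class GroupPartition:
    """Assignment of every node to exactly one of B groups.

    Attributes
    ----------
    labels : dict
        Node id -> group index in ``0..B-1``.
    categories : tuple
        Original category name for each group index.
    sizes : np.ndarray
        Node count per group.
    fractions : np.ndarray
        Proportional group sizes ``f_i``; positive and summing to 1.
        By default group 0 is the minority (smallest ``f_i``).
    """

    labels: Mapping[Hashable, int]
    categories: tuple
    sizes: np.ndarray = field(repr=False)
    fractions: np.ndarray = field(repr=False)

    @property
    def n_groups(self) -> int:
        return len(self.categories)

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def __post_init__(self) -> None:
        if np.any(self.fractions <= 0):
            raise ValueError("degenerate group: every group must be non-empty")
        if abs(float(self.fractions.sum()) - 1.0) > _SUM_TOL:
            raise ValueError("group fractions must sum to 1")


@dataclass(frozen=True)
class EdgeCounts:
    """B x B integer matrix of group-pair edge counts.

    Undirected counts live in the upper triangle (``E_ij`` with ``i <= j``);
    directed counts fill the full matrix.  ``total`` is the edge count E.
    """

    counts: np.ndarray
    directed: bool

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_groups(self) -> int:
        return self.counts.shape[0]

    def __post_init__(self) -> None:
        if np.any(self.counts < 0):
            raise ValueError("negative edge count")
        if not self.directed and np.any(np.tril(self.counts, -1) != 0):
            raise ValueError("undirected counts must be upper-triangular")


@dataclass(frozen=True)
class MixingMatrix:
    """Normalized edge-fraction matrix with its marginals.

    ``a[i]`` is the fraction of edge ends that *begin* at group i (row sum)
    and ``b[i]`` the fraction that *end* there (column sum).  The two differ
    only for directed or model-expected asymmetric matrices.
    """

    e: np.ndarray
    a: np.ndarray = field(repr=False)
    b: np.ndarray = field(repr=False)
    adjusted: bool = False
    groups: tuple | None = None

    @property
    def n_groups(self) -> int:
        return self.e.shape[0]

    def __post_init__(self) -> None:
        if abs(float(self.e.sum()) - 1.0) > 1e-9:
            raise ValueError("mixing matrix must sum to 1")


def _make_mixing(e: np.ndarray, adjusted: bool = False,
                 groups: tuple | None = None) -> MixingMatrix:
    e = np.asarray(e, dtype=float)
    return MixingMatrix(e=e, a=e.sum(axis=1), b=e.sum(axis=0),
                        adjusted=adjusted, groups=groups)


def build_partition(labels: Mapping[Hashable, Hashable],
                    minority_first: bool = True) -> GroupPartition:
    """Map categorical node labels to a :class:`GroupPartition`.

    Parameters
    ----------
    labels : mapping
        Node id -> category (any hashable).
    minority_first : bool
        If True (default), group index 0 is the smallest group, matching
        the convention that label 0 denotes the minority.  Ties are broken
        lexicographically by category name.

    Raises
    ------
    ValueError
        If the label map is empty.
    """
    if not labels:
        raise ValueError("empty partition")
    counts: dict = {}
    for cat in labels.values():
        counts[cat] = counts.get(cat, 0) + 1
    if minority_first:
        ordered = sorted(counts, key=lambda c: (counts[c], str(c)))
    else:
        ordered = sorted(counts, key=str)
    index = {cat: i for i, cat in enumerate(ordered)}
    sizes = np.array([counts[c] for c in ordered], dtype=int)
    return GroupPartition(
        labels={node: index[cat] for node, cat in labels.items()},
        categories=tuple(ordered),
        sizes=sizes,
        fractions=sizes / sizes.sum(),
    )


def count_edges(edges: Iterable[Sequence[Hashable]],
                partition: GroupPartition,
                directed: bool = False,
                multigraph: bool = False) -> EdgeCounts:
    """Tally edges by group pair.

    Undirected edges are deduplicated — ``(u, v)`` and ``(v, u)`` are the
    same edge — unless ``multigraph`` is set, in which case multiplicity
    counts.  Self-loops are rejected: the mixing formalism has no
    self-loop term.
    """
    B = partition.n_groups
    counts = np.zeros((B, B), dtype=np.int64)
    seen: set = set()
    for u, v in edges:
        if u == v:
            raise ValueError(f"self-loop on node {u!r}")
        for node in (u, v):
            if node not in partition.labels:
                raise ValueError(f"node {node!r} has no group assignment")
        gi, gj = partition.labels[u], partition.labels[v]
        if directed:
            if not multigraph:
                if (u, v) in seen:
                    continue
                seen.add((u, v))
            counts[gi, gj] += 1
        else:
            key = frozenset((u, v))
            if not multigraph:
                if key in seen:
                    continue
                seen.add(key)
            i, j = min(gi, gj), max(gi, gj)
            counts[i, j] += 1
    return EdgeCounts(counts=counts, directed=directed)


def mixing_matrix(counts: EdgeCounts,
                  groups: tuple | None = None) -> MixingMatrix:
    """Normalize edge counts into a mixing matrix.

    Undirected: ``e_ii = E_ii / E`` and ``e_ij = e_ji = E_ij / 2E`` for
    ``i != j``, so each inter-group edge contributes half a unit to each
    of its two symmetric cells.  Directed: ``e_ij = E_ij / E``.
    """
    E = counts.total
    if E == 0:
        raise ValueError("no edges")
    c = counts.counts.astype(float)
    if counts.directed:
        e = c / E
    else:
        upper = np.triu(c, 1)
        e = np.diag(np.diag(c)) / E + (upper + upper.T) / (2.0 * E)
    return _make_mixing(e, adjusted=False, groups=groups)


def adjust(m: MixingMatrix, fractions: Sequence[float],
           normalize: bool = True) -> MixingMatrix:
    """Group-size adjustment: divide each entry by ``f_i f_j``.

    The raw quotients ``e_ij / (f_i f_j)`` are renormalized to sum to one
    (default), yielding a proper mixing matrix whose entries reflect
    mixing tendencies rather than group-size opportunity.  Pass
    ``normalize=False`` to inspect the unnormalized quotients; the result
    then no longer satisfies the sum-to-one invariant and is returned as
    a bare array.

    Raises
    ------
    ValueError
        If any ``f_i`` is zero ("degenerate group") or ``m`` is already
        adjusted.
    """
    f = np.asarray(fractions, dtype=float)
    if m.adjusted:
        raise ValueError("mixing matrix is already adjusted")
    if f.shape != (m.n_groups,):
        raise ValueError("fractions shape does not match matrix")
    if np.any(f <= 0):
        raise ValueError("degenerate group: all fractions must be positive")
    raw = m.e / np.outer(f, f)
    if not normalize:
        return raw
    return _make_mixing(raw / raw.sum(), adjusted=True, groups=m.groups)
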