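"""Nominal and adjusted nominal assortativity.

The nominal (discrete/attribute) assortativity coefficient is

    r = (sum_i e_ii - sum_i a_i b_i) / (1 - sum_i a_i b_i)

with ``a_i = sum_j e_ij`` (edge ends beginning at group i) and
``b_i = sum_j e_ji`` (edge ends arriving there).  It is +1 when all edges
are intra-group, 0 when the diagonal matches the product-of-marginals
expectation, and negative when inter-group ties dominate.

On networks with unequal group sizes r conflates mixing preference with
group-size opportunity; the adjusted coefficient ``r_adj`` applies the
same formula to the group-size-adjusted mixing matrix and removes that
bias.  The row-sum x column-sum accounting is used throughout: for
symmetric (undirected empirical) matrices it coincides with squaring the
row sums, and for asymmetric model-expected matrices it is the form under
which r vanishes exactly on the locus ``h00 = 1 - h11``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np

from .mixing import (
    MixingMatrix,
    adjust,
    build_partition,
    count_edges,
    mixing_matrix,
)

__all__ = [
    "AssortativityResult",
    "nominal_r",
    "adjusted_r",
    "assortativity_from_network",
    "assortativity_from_counts",
]


@dataclass(frozen=True)
class AssortativityResult:
    """Assortativity coefficient together with its two ingredients."""

    r: float
    trace: float
    expected_trace: float
    adjusted: bool = False

    def __float__(self) -> float:
        return self.r


def nominal_r(m: MixingMatrix) -> AssortativityResult:
    """Assortativity coefficient of a mixing matrix.

    Raises
    ------
    ValueError
        If ``sum_i a_i b_i == 1`` (e.g. a single group), where the
        coefficient is undefined.
    """
    trace = float(np.trace(m.e))
    expected = float(m.a @ m.b)
    if 1.0 - expected <= 1e-15:
        raise ValueError("assortativity undefined for a single group")
    r = (trace - expected) / (1.0 - expected)
    return AssortativityResult(r=r, trace=trace, expected_trace=expected,
                               adjusted=m.adjusted)


def adjusted_r(m: MixingMatrix,
               fractions: Sequence[float]) -> AssortativityResult:
    """Assortativity of the group-size-adjusted mixing matrix."""
    return nominal_r(adjust(m, fractions))


def assortativity_from_network(edges: Iterable[Sequence[Hashable]],
                               labels: Mapping[Hashable, Hashable],
                               adjusted: bool = False,
                               directed: bool = False,
                               minority_first: bool = True,
                               ) -> AssortativityResult:
    """One-call pipeline: partition, count, normalize, (adjust), score."""
    part = build_partition(labels, minority_first=minority_first)
    m = mixing_matrix(count_edges(edges, part, directed=directed),
                      groups=part.categories)
    if adjusted:
        return adjusted_r(m, part.fractions)
    return nominal_r(m)


def assortativity_from_counts(E00: int, E01: int, E11: int,
                              f0: float) -> tuple[float, float]:
    """(r, r_adj) from two-group aggregate counts.

    ``E01`` is the inter-group count; the total E is their sum.  This is
    the path used for published summary tables where only aggregate edge
    counts and the minority fraction are available.
    """
    if min(E00, E01, E11) < 0:
        raise ValueError("negative edge count")
    if E00 + E01 + E11 == 0:
        raise ValueError("no edges")
    if not 0.0 < f0 < 1.0:
        raise ValueError("minority fraction must lie in (0, 1)")
    E = E00 + E01 + E11
    e = np.array([[E00 / E, E01 / (2 * E)],
                  [E01 / (2 * E), E11 / E]])
    m = MixingMatrix(e=e, a=e.sum(axis=1), b=e.sum(axis=0))
    f = np.array([f0, 1.0 - f0])
    return nominal_r(m).r, adjusted_r(m, f).r
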