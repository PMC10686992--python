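"""Closed-form mixing expectations under the random homophily model.

In the ER-homophily model each group-*i* node attaches to a group-*j*
node with tendency ``h_ij`` (row-stochastic: for two groups
``h_ij = 1 - h_ii``), so the probability mass of an i->j edge is
``p_ij = f_i f_j h_ij`` and the expected mixing matrix is
``e_ij = p_ij / T`` with ``T = sum_ij p_ij``.  The expected matrix is in
general *asymmetric* whenever ``h00 != h11`` — the directed accounting is
retained on purpose, since it is what makes the zero locus
``h00 = 1 - h11`` exact.

Key closed forms (two groups):

* nominal assortativity of the expected matrix — a function of the
  minority fraction f0, which drives r toward 0 as the minority shrinks
  even at fixed mixing h;
* adjusted assortativity — exactly ``h00 + h11 - 1`` for *every* f0,
  which is the size-independence property that motivates the adjustment;
* at equal group sizes the nominal coefficient reduces to the same
  ``h00 + h11 - 1`` line.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .mixing import MixingMatrix
from .assortativity import nominal_r

__all__ = [
    "HomophilyParams",
    "ModelSpec",
    "expected_mixing",
    "analytic_r",
    "analytic_r_adj",
    "zero_locus",
    "sweep",
]


@dataclass(frozen=True)
class HomophilyParams:
    """Row-stochastic B x B matrix of group mixing tendencies.

    ``h[i, j]`` is the tendency of a group-i node to connect to group j.
    A scalar ``h`` expands to ``h_ii = h`` with the complement split
    evenly over the other groups: ``h_ij = (1 - h) / (B - 1)``.
    """

    h: np.ndarray

    @property
    def n_groups(self) -> int:
        return self.h.shape[0]

    def __post_init__(self) -> None:
        h = np.asarray(self.h, dtype=float)
        if h.ndim != 2 or h.shape[0] != h.shape[1]:
            raise ValueError("h must be a square matrix")
        if np.any(h < 0) or np.any(h > 1):
            raise ValueError("mixing tendencies must lie in [0, 1]")
        if not np.allclose(h.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each row of h must sum to 1")
        object.__setattr__(self, "h", h)

    @classmethod
    def from_scalar(cls, h: float, n_groups: int = 2) -> "HomophilyParams":
        if not 0.0 <= h <= 1.0:
            raise ValueError("scalar h must lie in [0, 1]")
        if n_groups < 2:
            raise ValueError("need at least two groups")
        off = (1.0 - h) / (n_groups - 1)
        mat = np.full((n_groups, n_groups), off)
        np.fill_diagonal(mat, h)
        return cls(h=mat)

    @classmethod
    def two_group(cls, h00: float, h11: float) -> "HomophilyParams":
        for v in (h00, h11):
            if not 0.0 <= v <= 1.0:
                raise ValueError("mixing tendencies must lie in [0, 1]")
        return cls(h=np.array([[h00, 1.0 - h00], [1.0 - h11, h11]]))


@dataclass(frozen=True)
class ModelSpec:
    """Group fractions plus mixing tendencies; T is the edge-mass normalizer."""

    fractions: np.ndarray
    params: HomophilyParams

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if np.any(f <= 0) or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must be positive and sum to 1")
        if f.shape[0] != self.params.n_groups:
            raise ValueError("fractions and h disagree on group count")
        object.__setattr__(self, "fractions", f)

    @property
    def p(self) -> np.ndarray:
        """Unnormalized edge mass p_ij = f_i f_j h_ij."""
        f = self.fractions
        return np.outer(f, f) * self.params.h

    @property
    def normalizer(self) -> float:
        return float(self.p.sum())


def expected_mixing(spec: ModelSpec) -> MixingMatrix:
    """Expected mixing matrix e_ij = f_i f_j h_ij / T.

    Asymmetric whenever ``h_ij != h_ji``; the row marginals a and column
    marginals b then differ, which Eq.-style closed forms must respect.
    """
    T = spec.normalizer
    if T <= 0:
        raise ValueError("degenerate model: total edge mass is zero")
    e = spec.p / T
    return MixingMatrix(e=e, a=e.sum(axis=1), b=e.sum(axis=0))


def analytic_r(f0: float, h00: float, h11: float) -> float:
    """Closed-form nominal assortativity of the two-group expected model.

    Scalar evaluation of the coefficient on the expected mixing matrix,
    written out explicitly:

        trace = (f0^2 h00 + f1^2 h11) / T
        sum_i a_i b_i = (row_0 col_0 + row_1 col_1) / T^2

    with ``row_i`` / ``col_i`` the unnormalized row and column sums of
    p.  Reduces to ``h00 + h11 - 1`` at f0 = 0.5 and vanishes on the
    locus ``h11 = 1 - h00`` for every f0.
    """
    if not 0.0 < f0 < 1.0:
        raise ValueError("minority fraction must lie in (0, 1)")
    for v in (h00, h11):
        if not 0.0 <= v <= 1.0:
            raise ValueError("mixing tendencies must lie in [0, 1]")
    f1 = 1.0 - f0
    h01, h10 = 1.0 - h00, 1.0 - h11
    T = f0 * f0 * h00 + f1 * f1 * h11 + f0 * f1 * (h01 + h10)
    if T <= 0:
        raise ValueError("degenerate model: total edge mass is zero")
    trace = (f0 * f0 * h00 + f1 * f1 * h11) / T
    row0 = f0 * f0 * h00 + f0 * f1 * h01
    row1 = f1 * f1 * h11 + f0 * f1 * h10
    col0 = f0 * f0 * h00 + f0 * f1 * h10
    col1 = f1 * f1 * h11 + f0 * f1 * h01
    expected = (row0 * col0 + row1 * col1) / (T * T)
    return (trace - expected) / (1.0 - expected)


def analytic_r_adj(h00: float, h11: float) -> float:
    """Adjusted assortativity of the expected model: h00 + h11 - 1.

    Group-size adjustment of the expected matrix leaves ``h_ij / 2``,
    whose assortativity is ``h00 + h11 - 1`` independent of f0 — the
    size-independence that the adjustment is designed to deliver.
    """
    for v in (h00, h11):
        if not 0.0 <= v <= 1.0:
            raise ValueError("mixing tendencies must lie in [0, 1]")
    return h00 + h11 - 1.0


def zero_locus(h00: float) -> float:
    """The majority tendency at which assortativity vanishes: 1 - h00.

    On this locus both r and r_adj are zero for every minority fraction,
    even though the two groups may have strongly opposed mixing
    tendencies — the blind spot of single-valued assortativity.
    """
    if not 0.0 <= h00 <= 1.0:
        raise ValueError("mixing tendencies must lie in [0, 1]")
    return 1.0 - h00


def sweep(f0_grid: Sequence[float],
          h00_grid: Sequence[float],
          h11_grid: Sequence[float] | None = None,
          measure: str = "nominal") -> pd.DataFrame:
    """Evaluate a coefficient over a parameter grid.

    Returns a long-format table with columns (f0, h00, h11, value), one
    row per grid point, suitable for plotting heatmaps or curves.  When
    ``h11_grid`` is omitted the symmetric diagonal ``h11 = h00`` is swept.
    """
    if measure not in ("nominal", "adjusted"):
        raise ValueError(f"unknown measure: {measure!r}")
    rows = []
    for f0 in f0_grid:
        for h00 in h00_grid:
            for h11 in ([h00] if h11_grid is None else h11_grid):
                if measure == "nominal":
                    value = analytic_r(f0, h00, h11)
                else:
                    value = analytic_r_adj(h00, h11)
                rows.append((f0, h00, h11, value))
    return pd.DataFrame(rows, columns=["f0", "h00", "h11", "value"])
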