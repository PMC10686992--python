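"""Estimate asymmetric intra-group mixing tendencies from edge counts.

Under the ER-homophily model the diagonal of the expected mixing matrix
is ``e_ii = f_i^2 h_ii / T`` with ``T = sum_ij f_i f_j h_ij``.  Reading
``e_00 = E00/E`` and ``e_11 = E11/E`` off an observed network (raw
intra-group edge fractions — deliberately NOT the half-weight mixing-
matrix entries) and using the two-group complement ``h_ij = 1 - h_ii``,
T solves in closed form:

    T = 2 f0 f1 / (1 - e00 (1 - f1/f0) - e11 (1 - f0/f1))

and the intra-group tendencies follow by inverting the diagonal:

    h00 = e00 * T / f0^2,   h11 = e11 * T / f1^2.

The inversion is exact on expected model fractions; on finite sampled
networks it recovers the generating tendencies up to sampling error.
Estimates that land outside [0, 1] are flagged, not clipped: an
out-of-range value is evidence the ER-homophily model does not fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Sequence

from .mixing import build_partition, count_edges

__all__ = ["HomophilyEstimate", "estimate_h", "estimate_h_from_network"]


@dataclass(frozen=True)
class HomophilyEstimate:
    """Estimated intra-group tendencies and the inputs they came from."""

    h00: float
    h11: float
    normalizer: float  # estimated T = sum_ij p_ij
    E: int
    E00: int
    E11: int
    f0: float
    out_of_range: bool  # True when an estimate falls outside [0, 1]


def estimate_h(E: int, E00: int, E11: int, f0: float,
               model: str = "er") -> HomophilyEstimate:
    """Invert the ER-homophily model on aggregate two-group counts.

    Parameters
    ----------
    E, E00, E11 : int
        Total, minority-intra and majority-intra edge counts.
    f0 : float
        Minority fraction, in (0, 1).
    model : str
        Generative topology assumed by the inversion.  Only ``"er"``
        (random tie formation) is supported; the scale-free variant uses
        a different mixing-mass derivation and is not implemented.

    Raises
    ------
    ValueError
        If the closed-form denominator for T is non-positive — the
        counts are then inconsistent with the ER-homophily model.
    """
    if model != "er":
        raise ValueError(f"unsupported model: {model}")
    if E <= 0:
        raise ValueError("no edges")
    if not 0.0 < f0 < 1.0:
        raise ValueError("minority fraction must lie in (0, 1)")
    if E00 < 0 or E11 < 0 or E00 + E11 > E:
        raise ValueError("intra-group counts must be non-negative and sum to at most E")
    f1 = 1.0 - f0
    intra0 = E00 / E  # raw intra-group edge fractions, normalized by E
    intra1 = E11 / E
    denom = 1.0 - intra0 * (1.0 - f1 / f0) - intra1 * (1.0 - f0 / f1)
    if denom <= 0:
        raise ValueError("counts inconsistent with ER-homophily model")
    T = 2.0 * f0 * f1 / denom
    h00 = intra0 * T / (f0 * f0)
    h11 = intra1 * T / (f1 * f1)
    out = not (0.0 <= h00 <= 1.0 and 0.0 <= h11 <= 1.0)
    return HomophilyEstimate(h00=h00, h11=h11, normalizer=T,
                             E=E, E00=E00, E11=E11, f0=f0, out_of_range=out)


def estimate_h_from_network(edges: Iterable[Sequence[Hashable]],
                            labels: Mapping[Hashable, Hashable],
                            model: str = "er") -> HomophilyEstimate:
    """Estimate (h00, h11) directly from an edge list and node labels."""
    part = build_partition(labels, minority_first=True)
    if part.n_groups != 2:
        raise ValueError("estimator defined for two groups")
    counts = count_edges(edges, part, directed=False)
    c = counts.counts
    return estimate_h(E=counts.total, E00=int(c[0, 0]), E11=int(c[1, 1]),
                      f0=float(part.fractions[0]), model=model)
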