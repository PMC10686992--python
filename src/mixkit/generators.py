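"""Seeded random-network generators with tunable group mixing.

Two generative models:

* :func:`er_homophily` — random tie formation filtered by group mixing:
  source and target are drawn uniformly, and the proposal is accepted
  with probability ``h[g_src, g_tgt]``.  Expected edge mass between
  groups i and j is then proportional to ``p_ij = f_i f_j h_ij``, the
  model whose closed forms live in :mod:`mixkit.analytic`.
* :func:`ba_homophily` — growing scale-free network where each arriving
  node attaches to existing targets with probability proportional to
  homophily x target degree (preferential attachment with mixing).

Both are deterministic given their seed.  :func:`ensemble` runs repeated
simulations, scoring each with nominal/adjusted assortativity and the
tendency estimator, and summarizes means with standard errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .analytic import HomophilyParams
from .assortativity import assortativity_from_network
from .estimation import estimate_h_from_network

__all__ = ["NetworkSample", "er_homophily", "ba_homophily", "ensemble", "EnsembleResult"]


@dataclass(frozen=True)
class NetworkSample:
    """A generated simple network: edges, node groups, and provenance."""

    edges: list
    labels: dict = field(repr=False)
    seed: int
    spec: dict

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def _resolve_h(h) -> HomophilyParams:
    if isinstance(h, HomophilyParams):
        return h
    arr = np.asarray(h, dtype=float)
    if arr.ndim == 0:
        return HomophilyParams.from_scalar(float(arr))
    if arr.shape == (2, 2):
        return HomophilyParams(h=arr)
    raise ValueError("h must be a scalar, a 2x2 matrix, or HomophilyParams")


def _two_group_labels(n: int, f0: float) -> dict:
    if not 0.0 < f0 < 1.0:
        raise ValueError("minority fraction must lie in (0, 1)")
    n0 = int(round(n * f0))
    n0 = max(1, min(n - 1, n0))
    return {v: (0 if v < n0 else 1) for v in range(n)}


def _materialize_block_edges(accepted: dict, n0: int, n: int, rng) -> list:
    """Draw the accepted number of distinct pairs uniformly per group block.

    Minority nodes are 0..n0-1, majority n0..n-1.  Pair identities within
    a block are exchangeable, so sampling them without replacement after
    the acceptance loop is distributionally equivalent to resampling
    duplicates inside it.  Inter-group edges carry their formation
    orientation: the edge tuple is ordered (source, target), so directed
    accounting downstream can recover the asymmetric group-pair counts.
    """
    n1 = n - n0
    edges: list = []
    for block in ((0, 0), (0, 1), (1, 1)):
        count = (accepted[0, 1] + accepted[1, 0] if block == (0, 1)
                 else accepted[block])
        if count == 0:
            continue
        if block == (0, 1):
            codes = rng.choice(n0 * n1, size=count, replace=False)
            for idx, c in enumerate(codes):
                c = int(c)
                u, v = c // n1, n0 + c % n1
                # the random pair sample is exchangeable, so orienting the
                # first accepted[0,1] of them minority->majority is unbiased
                edges.append((u, v) if idx < accepted[0, 1] else (v, u))
        else:
            size, offset = (n0, 0) if block == (0, 0) else (n1, n0)
            codes = rng.choice(size * (size - 1) // 2, size=count, replace=False)
            for c in codes:
                # decode lexicographic upper-triangular index c -> (i, j), i < j
                c = int(c)
                i = int((2 * size - 1 - math.sqrt((2 * size - 1) ** 2 - 8 * c)) // 2)
                while i * (2 * size - i - 1) // 2 > c:  # float-precision guard
                    i -= 1
                while (i + 1) * (2 * size - i - 2) // 2 <= c:
                    i += 1
                j = c - i * (2 * size - i - 1) // 2 + i + 1
                edges.append((offset + i, offset + j))
    return edges


def er_homophily(n: int, f0: float, h, m_edges: int, seed: int) -> NetworkSample:
    """Random network with group mixing (two groups).

    Proposals are drawn as (uniform source, uniform target) and accepted
    with probability ``h[g_src, g_tgt]``, so the probability that a
    proposal lands on the group block (i, j) is exactly ``f_i f_j`` and
    the accepted edge mass is exactly proportional to
    ``p_ij = f_i f_j h_ij`` — the model's defining property — at any
    network size.  An accepted proposal is then materialized as a
    uniformly chosen not-yet-used node pair within its group block
    (within a block all pairs are exchangeable under the model), which
    enforces the simple-graph constraint without biasing the block
    composition even as a block's pair pool fills up.  A proposal whose
    block is exhausted consumes a step without producing an edge.
    Generation stops at ``m_edges`` accepted edges, or fails after a
    bounded number of proposals if the quota is unreachable (e.g. h = 1
    with too few intra-group pairs).
    """
    if n < 2:
        raise ValueError("need at least two nodes")
    if m_edges < 0:
        raise ValueError("negative edge count")
    if m_edges > n * (n - 1) // 2:
        raise ValueError("edge quota exceeds simple-graph capacity")
    params = _resolve_h(h)
    labels = _two_group_labels(n, f0)
    groups = np.fromiter((labels[v] for v in range(n)), dtype=np.int64, count=n)
    hmat = params.h
    n0 = int(np.sum(groups == 0))
    n1 = n - n0

    # unordered-pair capacity per group block; inter-group orientations
    # (0,1) and (1,0) share one pool of pairs
    def block_capacity(b):
        if b in ((0, 1), (1, 0)):
            return n0 * n1
        size = n0 if b == (0, 0) else n1
        return size * (size - 1) // 2

    accepted = {(0, 0): 0, (0, 1): 0, (1, 0): 0, (1, 1): 0}

    def block_used(b):
        if b in ((0, 1), (1, 0)):
            return accepted[0, 1] + accepted[1, 0]
        return accepted[b]

    rng = np.random.default_rng(seed)
    total = 0
    proposals = 0
    max_proposals = max(200_000, 2_000 * max(m_edges, 1))
    batch = max(1024, 4 * m_edges)
    while total < m_edges:
        if proposals >= max_proposals:
            raise RuntimeError(
                f"edge quota unreachable: {total}/{m_edges} edges after "
                f"{proposals} proposals")
        k = min(batch, max_proposals - proposals)
        src = rng.integers(0, n, size=k)
        tgt = rng.integers(0, n, size=k)
        accept = rng.random(size=k)
        for j in range(k):
            proposals += 1
            s, t = int(src[j]), int(tgt[j])
            gi, gj = int(groups[s]), int(groups[t])
            if accept[j] < hmat[gi, gj]:
                block = (gi, gj)
                if block_used(block) == block_capacity(block):
                    continue  # block exhausted; step consumed, no edge
                accepted[block] += 1
                total += 1
                if total == m_edges:
                    break
    edges = _materialize_block_edges(accepted, n0, n, rng)
    return NetworkSample(
        edges=edges, labels=labels, seed=seed,
        spec={"model": "er", "n": n, "f0": f0, "h": hmat.tolist(),
              "m_edges": m_edges})


def ba_homophily(n: int, f0: float, h, m_per_node: int, seed: int) -> NetworkSample:
    """Growing network: preferential attachment weighted by group mixing.

    Each group is seeded with its own (m_per_node + 1)-clique so that
    fully homophilous parameters (h = 1) grow two disconnected
    homophilous components.  Every subsequent node, with group drawn by
    arrival order from the fixed group counts, connects to ``m_per_node``
    distinct existing nodes chosen with probability proportional to
    ``h[g_new, g_target] * degree(target)``; if all such weights vanish
    the degree factor is dropped, and failing that the choice is uniform.
    """
    if m_per_node < 1:
        raise ValueError("m_per_node must be at least 1")
    params = _resolve_h(h)
    hmat = params.h
    labels = _two_group_labels(n, f0)
    n0 = sum(1 for g in labels.values() if g == 0)
    seed_size = m_per_node + 1
    if n0 < seed_size or n - n0 < seed_size:
        raise ValueError("each group needs at least m_per_node + 1 nodes")
    rng = np.random.default_rng(seed)

    group_of = np.fromiter((labels[v] for v in range(n)), dtype=np.int64, count=n)
    minority = [v for v in range(n) if group_of[v] == 0]
    majority = [v for v in range(n) if group_of[v] == 1]

    edges: list = []
    degree = np.zeros(n, dtype=float)
    existing: list = []
    for clique in (minority[:seed_size], majority[:seed_size]):
        for i, u in enumerate(clique):
            for v in clique[i + 1:]:
                edges.append((min(u, v), max(u, v)))
                degree[u] += 1
                degree[v] += 1
        existing.extend(clique)

    arrivals = minority[seed_size:] + majority[seed_size:]
    order = rng.permutation(len(arrivals))
    for idx in order:
        v = arrivals[idx]
        g = group_of[v]
        cand = np.array(existing)
        w = hmat[g, group_of[cand]] * degree[cand]
        if w.sum() == 0:
            w = hmat[g, group_of[cand]].astype(float)
        if w.sum() == 0:
            w = np.ones(len(cand))
        m = min(m_per_node, np.count_nonzero(w))
        targets = rng.choice(cand, size=m, replace=False, p=w / w.sum())
        for t in targets:
            t = int(t)
            edges.append((v, t))  # formation orientation: arrival -> target
            degree[v] += 1
            degree[t] += 1
        existing.append(v)
    return NetworkSample(
        edges=edges, labels=labels, seed=seed,
        spec={"model": "ba", "n": n, "f0": f0, "h": hmat.tolist(),
              "m_per_node": m_per_node})


@dataclass(frozen=True)
class EnsembleResult:
    """Per-run statistics and their ensemble summary."""

    runs: pd.DataFrame
    summary: pd.DataFrame


def ensemble(spec: Mapping, n_runs: int, seed: int = 0,
             estimate: bool = True,
             accounting: str = "undirected") -> EnsembleResult:
    """Repeat a generator spec over derived seeds and score each run.

    ``spec`` holds the generator parameters: ``model`` ("er" or "ba"),
    ``n``, ``f0``, ``h`` (scalar or 2x2), and ``m_edges`` (ER) or
    ``m_per_node`` (BA).  Per-run seeds are drawn once from a stream
    seeded by ``seed``, so the whole ensemble is deterministic.

    Each run records nominal r, adjusted r_adj (adjusting by the
    realized group fractions), and — when ``estimate`` is on and the
    model is ER — the recovered tendencies (h00, h11).

    ``accounting`` chooses how r is measured.  "undirected" (default)
    symmetrizes the mixing matrix, as any observer of the bare network
    must.  "formation" keeps each edge's generative orientation
    (source group -> target group), the accounting under which the
    asymmetric zero locus h00 = 1 - h11 yields r = 0 exactly; a
    symmetrized matrix mixes the two orientations and reports a
    (slightly negative) coefficient on that locus instead.
    """
    if accounting not in ("undirected", "formation"):
        raise ValueError(f"unknown accounting: {accounting!r}")
    if n_runs < 1:
        raise ValueError("need at least one run")
    spec = dict(spec)
    model = spec.pop("model", "er")
    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2**31 - 1, size=n_runs)
    records = []
    for i, s in enumerate(run_seeds):
        s = int(s)
        if model == "er":
            sample = er_homophily(seed=s, **spec)
        elif model == "ba":
            sample = ba_homophily(seed=s, **spec)
        else:
            raise ValueError(f"unknown model: {model!r}")
        directed = accounting == "formation"
        rec = {"run": i, "seed": s, "n_edges": sample.n_edges}
        rec["r"] = assortativity_from_network(
            sample.edges, sample.labels, directed=directed).r
        rec["r_adj"] = assortativity_from_network(
            sample.edges, sample.labels, adjusted=True, directed=directed).r
        if estimate and model == "er":
            est = estimate_h_from_network(sample.edges, sample.labels)
            rec["h00_hat"] = est.h00
            rec["h11_hat"] = est.h11
        records.append(rec)
    runs = pd.DataFrame(records)
    stats = [c for c in ("r", "r_adj", "h00_hat", "h11_hat") if c in runs]
    summary = pd.DataFrame({
        "mean": runs[stats].mean(),
        "std": runs[stats].std(ddof=1),
        "se": runs[stats].std(ddof=1) / math.sqrt(n_runs),
    })
    return EnsembleResult(runs=runs, summary=summary)
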