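"""Stochastic edge-weight node ranking.

Each node ``n`` is scored by its weighted out-degree plus a discounted
second-degree term:

    S_n = sum(e_n1) + w * sum(e_n2)

where ``e_n1`` are the weights of n's outgoing edges, and ``e_n2`` the
weights of the outgoing edges of n's distinct first-degree out-neighbors.
Edge weights depend only on type: a miRNA->target edge weighs ``e_t = 1``
(experimentally verified, most trusted), a TF->miRNA edge ``e_r`` (predicted
but directed), a protein-protein interaction ``e_i`` (undirected, least
informative).  Undirected PPI edges count as outgoing from both endpoints.

Rather than fixing a weighting scheme, the weights are drawn fresh for every
repetition — ``e_r ~ U(0,1)``, then ``e_i ~ U(0, e_r)`` so that
``1 = e_t > e_r > e_i > 0`` always holds, and the second-degree discount
``w ~ U(0,1)`` — the nodes are ranked by score (rank 1 = highest, ties get
the fractional average rank), and each node's final value is its mean rank
over the repetitions (10,000 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import rankdata

from .errors import ConfigError, DataError
from .netmodel import EdgeType, Network

__all__ = [
    "WeightSample",
    "RankingTable",
    "sample_weights",
    "sample_weight_arrays",
    "node_score",
    "rank_once",
    "rank_nodes",
]

_TYPE_COL = {EdgeType.TARGETING: 0, EdgeType.REGULATION: 1, EdgeType.PPI: 2}


@dataclass(frozen=True)
class WeightSample:
    """One draw of the edge-type weight hierarchy; ``e_t`` is pinned at 1."""

    e_r: float
    e_i: float
    w: float
    e_t: float = 1.0

    def __post_init__(self):
        if self.e_t != 1.0:
            raise ConfigError("e_t is fixed at 1")
        if not (self.e_t > self.e_r > self.e_i > 0):
            raise ConfigError(f"weights must satisfy 1 > e_r > e_i > 0, got {self}")
        if not (0 < self.w < 1):
            raise ConfigError(f"w must lie in (0, 1), got {self.w}")

    def as_vector(self) -> np.ndarray:
        """Per-type weight vector ordered (TARGETING, REGULATION, PPI)."""
        return np.array([self.e_t, self.e_r, self.e_i])


def sample_weights(rng: np.random.Generator) -> WeightSample:
    """Draw one weight sample; draw order is (e_r, e_i, w)."""
    u = rng.random(3)
    e_r = u[0]
    return WeightSample(e_r=e_r, e_i=e_r * u[1], w=u[2])


def sample_weight_arrays(rng: np.random.Generator, n: int):
    """Vectorised equivalent of ``n`` successive :func:`sample_weights` calls.

    Returns ``(e_r, e_i, w)`` arrays of length ``n``; consumes the random
    stream in exactly the same order as the scalar sampler.
    """
    u = rng.random((n, 3))
    e_r = u[:, 0]
    return e_r, e_r * u[:, 1], u[:, 2]


# ---------------------------------------------------------------------------
# score machinery


def _score_matrices(network: Network, include_backlinks: bool = True):
    """Precompute (C, A, Corr, index) for vectorised scoring.

    C[i, k]    — number of out-edges of node i with type k;
    A[i, j]    — 1 iff j is a distinct out-neighbor of i (PPI both ways);
    Corr[i, k] — with backlinks excluded, the number of type-k edges from
                 i's out-neighbors that point back at i (subtracted from the
                 second-degree term); zero otherwise.
    """
    index = network.node_index()
    n = len(index)
    counts = np.zeros((n, 3))
    nbr: list[set] = [set() for _ in range(n)]
    directed = [(index[u], index[v], _TYPE_COL[t]) for u, v, t in network.iter_directed()]
    for i, j, k in directed:
        counts[i, k] += 1
        nbr[i].add(j)
    rows = [i for i, s in enumerate(nbr) for _ in s]
    cols = [j for s in nbr for j in sorted(s)]
    adj = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    corr = np.zeros((n, 3))
    if not include_backlinks:
        for i, j, k in directed:
            if i in nbr[j]:
                corr[j, k] += 1
    return counts, adj, corr, index


def _scores_for_weights(counts, adj, corr, wvecs: np.ndarray, wfac: np.ndarray) -> np.ndarray:
    """Scores for a batch of weight draws; wvecs is (R, 3), wfac (R,).
    Returns an (N, R) matrix."""
    s1 = counts @ wvecs.T
    s2 = adj @ s1 - corr @ wvecs.T
    return s1 + wfac[np.newaxis, :] * s2


def node_score(
    network: Network, node: str, weights: WeightSample, include_backlinks: bool = True
) -> float:
    """Score of one node under one weight draw.

    ``include_backlinks`` controls whether second-degree sums keep edges
    pointing back at the scored node (the default; exposed for sensitivity
    analysis).
    """
    w = weights.as_vector()
    s1 = sum(w[_TYPE_COL[t]] for _, t in network.out_edges(node))
    s2 = 0.0
    for m in network.out_neighbors(node):
        for v, t in network.out_edges(m):
            if not include_backlinks and v == node:
                continue
            s2 += w[_TYPE_COL[t]]
    return float(s1 + weights.w * s2)


def rank_once(
    network: Network, weights: WeightSample, include_backlinks: bool = True
) -> pd.Series:
    """Fractional ranks (1 = highest score) for a single weight draw."""
    if len(network) == 0:
        raise DataError("cannot rank an empty network")
    counts, adj, corr, index = _score_matrices(network, include_backlinks)
    scores = _scores_for_weights(
        counts, adj, corr, weights.as_vector()[np.newaxis, :], np.array([weights.w])
    )[:, 0]
    ranks = rankdata(-scores, method="average")
    return pd.Series(ranks, index=list(index), name="rank")


@dataclass(frozen=True)
class RankingTable:
    """Average rank per node over all repetitions (smaller = more influential)."""

    average_rank: pd.Series
    repetitions: int
    seed: int

    def to_frame(self, network: Network | None = None) -> pd.DataFrame:
        """Tabular output: node_id, roles, average_rank, final_rank_position
        (1..N by ascending average rank, ties broken lexicographically),
        repetitions, seed."""
        order = sorted(
            self.average_rank.index, key=lambda nid: (self.average_rank[nid], nid)
        )
        position = {nid: i + 1 for i, nid in enumerate(order)}
        roles = {
            nid: ",".join(sorted(r.value for r in network.nodes[nid].roles))
            if network is not None
            else ""
            for nid in self.average_rank.index
        }
        return pd.DataFrame(
            {
                "node_id": order,
                "roles": [roles[nid] for nid in order],
                "average_rank": [self.average_rank[nid] for nid in order],
                "final_rank_position": [position[nid] for nid in order],
                "repetitions": self.repetitions,
                "seed": self.seed,
            }
        )


def rank_nodes(
    network: Network,
    repetitions: int = 10000,
    seed: int = 0,
    include_backlinks: bool = True,
) -> RankingTable:
    """Average fractional rank of every node over ``repetitions`` weight draws.

    One weight sample is drawn per repetition and shared by all edges of each
    type.  Deterministic given ``seed``.
    """
    if repetitions < 1:
        raise ConfigError(f"repetitions must be >= 1, got {repetitions}")
    if len(network) == 0:
        raise DataError("cannot rank an empty network")
    counts, adj, corr, index = _score_matrices(network, include_backlinks)
    n = len(index)
    rng = np.random.default_rng(seed)
    rank_sum = np.zeros(n)
    # chunk repetitions to bound the (N x chunk) dense score matrix
    chunk = max(1, min(repetitions, int(2e7 // max(n, 1))))
    done = 0
    while done < repetitions:
        m = min(chunk, repetitions - done)
        e_r, e_i, w = sample_weight_arrays(rng, m)
        wvecs = np.column_stack([np.ones(m), e_r, e_i])
        scores = _scores_for_weights(counts, adj, corr, wvecs, w)
        rank_sum += rankdata(-scores, method="average", axis=0).sum(axis=1)
        done += m
    avg = pd.Series(rank_sum / repetitions, index=list(index), name="average_rank")
    return RankingTable(average_rank=avg, repetitions=repetitions, seed=seed)
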