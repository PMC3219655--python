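"""Shared fixtures: toy networks, random role-consistent networks, and
independent brute-force oracles used to cross-check the implementation."""

from __future__ import annotations

import numpy as np
import pytest

from mirnet.netmodel import Edge, EdgeType, Network, Node, Role


@pytest.fixture
def chain_network() -> Network:
    """TF A -> miRNA B -> disease target C."""
    return Network(
        [
            Node("A", frozenset({Role.TF})),
            Node("B", frozenset({Role.MIRNA})),
            Node("C", frozenset({Role.TARGET}), disease_associated=True),
        ],
        [Edge("A", "B", EdgeType.REGULATION), Edge("B", "C", EdgeType.TARGETING)],
    )


@pytest.fixture
def ppi_pair_network() -> Network:
    """Lone undirected PPI pair D -- E."""
    return Network(
        [
            Node("D", frozenset({Role.TF})),
            Node("E", frozenset({Role.TCOF})),
        ],
        [Edge("D", "E", EdgeType.PPI)],
    )


def random_network(rng: np.random.Generator, max_nodes: int = 8) -> Network:
    """A random network respecting the role constraints of every edge type.

    Nodes split into miRNAs and proteins; proteins get random role subsets
    (always at least one role; TARGET implies disease-associated).  Edges are
    sampled among the role-compatible pairs only.
    """
    n = int(rng.integers(2, max_nodes + 1))
    n_mirnas = int(rng.integers(1, n))
    mirnas = [f"m{i}" for i in range(n_mirnas)]
    proteins = [f"p{i}" for i in range(n - n_mirnas)]
    nodes = [Node(m, frozenset({Role.MIRNA})) for m in mirnas]
    roles_of = {}
    for p in proteins:
        roles = {r for r in (Role.TF, Role.TCOF, Role.TARGET) if rng.random() < 0.5}
        if not roles:
            roles = {(Role.TF, Role.TCOF, Role.TARGET)[int(rng.integers(3))]}
        roles_of[p] = roles
        nodes.append(Node(p, frozenset(roles), disease_associated=Role.TARGET in roles))
    edges = []
    for m in mirnas:
        for p in proteins:
            if Role.TARGET in roles_of[p] and rng.random() < 0.35:
                edges.append(Edge(m, p, EdgeType.TARGETING))
            if Role.TF in roles_of[p] and rng.random() < 0.35:
                edges.append(Edge(p, m, EdgeType.REGULATION))
    for i, a in enumerate(proteins):
        for b in proteins[i:]:
            if rng.random() < 0.3:
                edges.append(Edge(a, b, EdgeType.PPI))
    return Network(nodes, edges)


# ---------------------------------------------------------------------------
# independent oracles


def brute_force_node_score(network: Network, node: str, weights, include_backlinks=True):
    """Definition-level score: materialise the first-degree edge list (PPI
    expanded to both directions), then the second-degree edge list of each
    distinct out-neighbor, and sum type weights term by term."""
    wt = {
        EdgeType.TARGETING: weights.e_t,
        EdgeType.REGULATION: weights.e_r,
        EdgeType.PPI: weights.e_i,
    }
    directed = []
    for e in network.edges:
        directed.append((e.source, e.target, e.etype))
        if e.etype is EdgeType.PPI and e.source != e.target:
            directed.append((e.target, e.source, e.etype))
    first = [(u, v, t) for u, v, t in directed if u == node]
    s1 = sum(wt[t] for _, _, t in first)
    neighbors = {v for _, v, _ in first}
    s2 = 0.0
    for m in sorted(neighbors):
        for u, v, t in directed:
            if u != m:
                continue
            if not include_backlinks and v == node:
                continue
            s2 += wt[t]
    return s1 + weights.w * s2


def brute_force_feedback_loops(network: Network):
    """Exhaustive O(N^3) triple scan over all (tf, mirna, target) candidates."""
    reg = set()
    tar = set()
    ppi = set()
    for e in network.edges:
        if e.etype is EdgeType.REGULATION:
            reg.add((e.source, e.target))
        elif e.etype is EdgeType.TARGETING:
            tar.add((e.source, e.target))
        else:
            ppi.add(frozenset((e.source, e.target)) if e.source != e.target else frozenset((e.source,)))
    ids = sorted(network.nodes)
    loops = set()
    for tf in ids:
        for m in ids:
            for t in ids:
                if (
                    t != tf
                    and (tf, m) in reg
                    and (m, t) in tar
                    and frozenset((t, tf)) in ppi
                    and network.nodes[t].disease_associated
                ):
                    loops.add((tf, m, t))
    return loops
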