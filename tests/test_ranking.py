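"""Stochastic edge-weight scoring and rank averaging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_node_score, random_network
from mirnet import ConfigError, DataError
from mirnet.netmodel import Edge, EdgeType, Network, Node, Role
from mirnet.ranking import (
    WeightSample,
    node_score,
    rank_nodes,
    rank_once,
    sample_weight_arrays,
    sample_weights,
)

WS = WeightSample(e_r=0.5, e_i=0.25, w=0.5)


# -- weight sampling ---------------------------------------------------------


def test_weight_sample_invariants_enforced():
    with pytest.raises(ConfigError):
        WeightSample(e_r=0.3, e_i=0.4, w=0.5)  # e_i > e_r
    with pytest.raises(ConfigError):
        WeightSample(e_r=0.5, e_i=0.25, w=1.5)
    with pytest.raises(ConfigError):
        WeightSample(e_r=0.5, e_i=0.25, w=0.5, e_t=2.0)


def test_sampled_weights_always_respect_hierarchy():
    rng = np.random.default_rng(7)
    for _ in range(500):
        ws = sample_weights(rng)
        assert ws.e_t == 1.0
        assert 1.0 > ws.e_r > ws.e_i > 0.0
        assert 0.0 < ws.w < 1.0


def test_vectorised_sampler_matches_scalar_stream():
    e_r, e_i, w = sample_weight_arrays(np.random.default_rng(11), 5)
    rng = np.random.default_rng(11)
    scalars = [sample_weights(rng) for _ in range(5)]
    assert np.allclose(e_r, [s.e_r for s in scalars])
    assert np.allclose(e_i, [s.e_i for s in scalars])
    assert np.allclose(w, [s.w for s in scalars])


def test_e_i_mean_is_quarter_over_many_draws():
    # E[e_i] = E[e_r]/2 = 1/4; sd(e_i) = sqrt(7/144)
    _, e_i, _ = sample_weight_arrays(np.random.default_rng(123), 10_000)
    se = np.sqrt(7 / 144) / np.sqrt(10_000)
    assert abs(e_i.mean() - 0.25) < 3 * se


# -- node_score --------------------------------------------------------------


def test_isolated_node_scores_zero():
    net = Network([Node("x", frozenset({Role.TF}))], [])
    assert node_score(net, "x", WS) == 0.0


def test_chain_scores_hand_computed(chain_network):
    # S_A = e_r + w * e_t = 0.5 + 0.5*1 = 1.0; S_B = e_t = 1.0; S_C = 0
    assert node_score(chain_network, "A", WS) == pytest.approx(1.0)
    assert node_score(chain_network, "B", WS) == pytest.approx(1.0)
    assert node_score(chain_network, "C", WS) == 0.0


def test_ppi_pair_counts_reciprocal_edge_in_second_degree(ppi_pair_network):
    # S_D = e_i + w * e_i = 0.25 + 0.5*0.25 = 0.375 (E's out-edge points back at D)
    assert node_score(ppi_pair_network, "D", WS) == pytest.approx(0.375)
    assert node_score(ppi_pair_network, "D", WS, include_backlinks=False) == pytest.approx(0.25)


def test_unknown_node_errors(chain_network):
    with pytest.raises(DataError):
        node_score(chain_network, "nope", WS)


@pytest.mark.parametrize("include_backlinks", [True, False])
def test_score_agrees_with_brute_force_oracle(include_backlinks):
    rng = np.random.default_rng(2024)
    for _ in range(200):
        net = random_network(rng, max_nodes=8)
        ws = sample_weights(rng)
        for nid in net.nodes:
            assert node_score(net, nid, ws, include_backlinks) == pytest.approx(
                brute_force_node_score(net, nid, ws, include_backlinks)
            )


def test_adding_targeting_out_edge_strictly_increases_score():
    rng = np.random.default_rng(5)
    for _ in range(30):
        net = random_network(rng, max_nodes=6)
        ws = sample_weights(rng)
        mirnas = [n for n, v in net.nodes.items() if Role.MIRNA in v.roles]
        targets = [n for n, v in net.nodes.items() if Role.TARGET in v.roles]
        pairs = [
            (m, t)
            for m in mirnas
            for t in targets
            if Edge(m, t, EdgeType.TARGETING) not in net.edges
        ]
        if not pairs:
            continue
        m, t = pairs[0]
        bigger = Network(
            net.nodes.values(), list(net.edges) + [Edge(m, t, EdgeType.TARGETING)]
        )
        assert node_score(bigger, m, ws) > node_score(net, m, ws)
        for other in net.nodes:
            assert node_score(bigger, other, ws) >= node_score(net, other, ws) - 1e-12


def test_targeting_out_edge_beats_regulation_out_edge():
    # e_t > e_r: swapping a REGULATION out-edge for a TARGETING one never
    # lowers the node's own score (same topology otherwise).
    nodes = [
        Node("p", frozenset({Role.TF, Role.TARGET}), disease_associated=True),
        Node("m", frozenset({Role.MIRNA})),
        Node("g", frozenset({Role.TARGET}), disease_associated=True),
    ]
    with_reg = Network(nodes, [Edge("p", "m", EdgeType.REGULATION)])
    with_tar = Network(nodes, [Edge("m", "p", EdgeType.TARGETING)])
    rng = np.random.default_rng(8)
    for _ in range(50):
        ws = sample_weights(rng)
        assert node_score(with_tar, "m", ws) >= node_score(with_reg, "p", ws)


# -- rank_once ---------------------------------------------------------------


def test_all_isolated_nodes_tie_at_middle_rank():
    net = Network([Node(i, frozenset({Role.TF})) for i in "xyz"], [])
    ranks = rank_once(net, WS)
    assert (ranks == 2.0).all()


def test_chain_ranks_with_fixed_weights(chain_network):
    ranks = rank_once(chain_network, WS)
    assert ranks["A"] == ranks["B"] == 1.5
    assert ranks["C"] == 3.0


def test_rank_mean_conservation_over_random_networks():
    rng = np.random.default_rng(77)
    for _ in range(50):
        net = random_network(rng, max_nodes=8)
        ranks = rank_once(net, sample_weights(rng))
        n = len(net)
        assert ranks.mean() == pytest.approx((n + 1) / 2)
        assert ranks.min() >= 1.0 and ranks.max() <= n


def test_empty_network_rank_errors():
    with pytest.raises(DataError):
        rank_once(Network([], []), WS)
    with pytest.raises(DataError):
        rank_nodes(Network([], []), repetitions=10, seed=0)


# -- rank_nodes --------------------------------------------------------------


def test_chain_average_ranks_analytic(chain_network):
    # C never scores above 0 -> rank 3 in every repetition.
    # P(S_A > S_B) = P(e_r + w > 1) = 1/2 -> A averages 1.5.
    table = rank_nodes(chain_network, repetitions=10_000, seed=13)
    assert table.average_rank["C"] == pytest.approx(3.0)
    assert table.average_rank["A"] == pytest.approx(1.5, abs=0.02)
    assert table.average_rank["B"] == pytest.approx(1.5, abs=0.02)


def test_rank_nodes_deterministic_given_seed(chain_network):
    a = rank_nodes(chain_network, repetitions=200, seed=5)
    b = rank_nodes(chain_network, repetitions=200, seed=5)
    pd.testing.assert_series_equal(a.average_rank, b.average_rank)


def test_rank_nodes_rejects_bad_repetitions(chain_network):
    with pytest.raises(ConfigError):
        rank_nodes(chain_network, repetitions=0, seed=1)


@given(st.integers(0, 100))
@settings(max_examples=10, deadline=None)
def test_relabeling_equivariance(seed):
    rng = np.random.default_rng(seed)
    net = random_network(rng, max_nodes=6)
    mapping = {nid: f"Z{i}_{nid}" for i, nid in enumerate(sorted(net.nodes))}
    relabeled = Network(
        [
            Node(mapping[n.id], n.roles, n.disease_associated)
            for n in net.nodes.values()
        ],
        [Edge(mapping[e.source], mapping[e.target], e.etype) for e in net.edges],
    )
    table = rank_nodes(net, repetitions=50, seed=3)
    table2 = rank_nodes(relabeled, repetitions=50, seed=3)
    for nid in net.nodes:
        assert table.average_rank[nid] == pytest.approx(table2.average_rank[mapping[nid]])


def test_output_frame_layout(chain_network):
    table = rank_nodes(chain_network, repetitions=100, seed=2)
    df = table.to_frame(chain_network)
    assert list(df.columns) == [
        "node_id", "roles", "average_rank", "final_rank_position", "repetitions", "seed",
    ]
    assert df["final_rank_position"].tolist() == [1, 2, 3]
    assert df["average_rank"].is_monotonic_increasing
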