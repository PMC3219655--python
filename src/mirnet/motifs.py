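"""Regulatory network motif census.

Two motif shapes are enumerated:

* **self-loop** — a miRNA that targets one of its own predicted TFs
  (REGULATION tf->mirna together with TARGETING mirna->tf);
* **feedback loop** — a three-element circle: a TF regulates a miRNA, the
  miRNA targets a disease-associated protein, and that protein interacts
  with the TF (PPI edge, which may be a TF-TcoF association).  Depending on
  the unknown signs of the interactions such a circle can be self-promoting
  or self-cancelling; only the topology is enumerated here.

"Different" feedback loops are distinct ordered (tf, mirna, target) triples:
a TF-target pair connected through two miRNAs yields two loops.  The target
may itself carry the TF role, as long as it differs from the loop's TF.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .netmodel import EdgeType, Network, Role

__all__ = [
    "SelfLoop",
    "FeedbackLoop",
    "find_self_loops",
    "find_feedback_loops",
    "loop_participation",
    "node_loop_count",
    "loops_to_frame",
]


@dataclass(frozen=True)
class SelfLoop:
    mirna: str
    tf: str


@dataclass(frozen=True)
class FeedbackLoop:
    tf: str
    mirna: str
    target: str
    target_is_tcof: bool = False


def _edge_sets(network: Network):
    regulation = set()
    targeting = set()
    ppi = set()
    for e in network.edges:
        if e.etype is EdgeType.REGULATION:
            regulation.add((e.source, e.target))
        elif e.etype is EdgeType.TARGETING:
            targeting.add((e.source, e.target))
        else:
            ppi.add((e.source, e.target))
            ppi.add((e.target, e.source))
    return regulation, targeting, ppi


def find_self_loops(network: Network) -> list[SelfLoop]:
    """All (mirna, tf) pairs where the miRNA targets one of its own TFs,
    in lexicographic order."""
    regulation, targeting, _ = _edge_sets(network)
    pairs = {(m, tf) for tf, m in regulation if (m, tf) in targeting}
    return [SelfLoop(m, tf) for m, tf in sorted(pairs)]


def find_feedback_loops(network: Network) -> list[FeedbackLoop]:
    """All (tf, mirna, target) triples closing a regulatory circle, in
    lexicographic order.

    Conditions: REGULATION tf->mirna, TARGETING mirna->target, a PPI edge
    between target and tf, target != tf, and the target disease-associated.
    ``target_is_tcof`` annotates whether the closing protein also carries the
    TCOF role (a TcoF-mediated loop); it does not affect loop identity.
    """
    regulation, targeting, ppi = _edge_sets(network)
    out_targets: dict[str, list] = {}
    for m, t in targeting:
        out_targets.setdefault(m, []).append(t)
    loops = set()
    for tf, m in regulation:
        for t in out_targets.get(m, ()):
            if t != tf and (t, tf) in ppi and network.nodes[t].disease_associated:
                loops.add((tf, m, t))
    return [
        FeedbackLoop(tf, m, t, target_is_tcof=Role.TCOF in network.nodes[t].roles)
        for tf, m, t in sorted(loops)
    ]


def loop_participation(loops: list[FeedbackLoop]) -> tuple[int, int, int]:
    """(distinct TFs, distinct miRNAs, distinct targets) across the loops."""
    return (
        len({lp.tf for lp in loops}),
        len({lp.mirna for lp in loops}),
        len({lp.target for lp in loops}),
    )


def node_loop_count(loops: list[FeedbackLoop], node: str) -> int:
    """Number of loops in which ``node`` appears in any position."""
    return sum(1 for lp in loops if node in (lp.tf, lp.mirna, lp.target))


def loops_to_frame(loops: list[FeedbackLoop]) -> pd.DataFrame:
    """Tabular loop list: tf, mirna, target, target_is_tcof (0/1)."""
    return pd.DataFrame(
        {
            "tf": [lp.tf for lp in loops],
            "mirna": [lp.mirna for lp in loops],
            "target": [lp.target for lp in loops],
            "target_is_tcof": [int(lp.target_is_tcof) for lp in loops],
        }
    )
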