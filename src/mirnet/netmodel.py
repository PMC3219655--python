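"""Heterogeneous miRNA-centred regulatory network model.

The network mixes three biological relationship classes around a set of
disease-associated miRNAs:

* ``TARGETING`` — a miRNA represses a protein-coding gene (directed,
  experimentally verified miRNA->target pairs);
* ``REGULATION`` — a transcription factor (TF) has a predicted binding site
  in a miRNA gene's promoter window (directed, TF->miRNA);
* ``PPI`` — an undirected protein-protein interaction, which also carries
  TF-TcoF (transcription co-factor) associations.

Nodes are biological entities that may hold several roles at once (a protein
can be both a TF and a disease-associated miRNA target).  :func:`build_network`
assembles a network from five association tables using the retention rules of
the pipeline: miRNAs with at least one disease-associated verified target,
those targets, TFs with at least one binding-site hit in a retained miRNA's
promoter, high-confidence TcoFs of retained TFs, and PPIs induced on the
retained protein set.
"""

from __future__ import annotations

import enum
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import pandas as pd

from .errors import DataError, UnknownIdentifierError

__all__ = [
    "Role",
    "EdgeType",
    "Node",
    "Edge",
    "Network",
    "NetworkCensus",
    "build_network",
    "census",
    "tf_regulon",
    "tf_downstream_targets",
    "mirna_in_degree",
]


class Role(str, enum.Enum):
    """Node role. A node may carry several, but MIRNA never mixes with
    protein roles: miRNA names and gene symbols live in distinct namespaces."""

    MIRNA = "MIRNA"
    TF = "TF"
    TCOF = "TCOF"
    TARGET = "TARGET"


#: Roles a protein-class node may carry.
PROTEIN_ROLES = frozenset({Role.TF, Role.TCOF, Role.TARGET})


class EdgeType(str, enum.Enum):
    TARGETING = "TARGETING"  # miRNA -> target protein
    REGULATION = "REGULATION"  # TF -> miRNA
    PPI = "PPI"  # protein -- protein, undirected

    @property
    def directed(self) -> bool:
        return self is not EdgeType.PPI


@dataclass(frozen=True)
class Node:
    """A biological entity with one or more roles.

    ``disease_associated`` records membership in the disease gene list; the
    TARGET role implies it (only disease genes count as retained targets).
    """

    id: str
    roles: frozenset
    disease_associated: bool = False

    def __post_init__(self):
        roles = frozenset(Role(r) for r in self.roles)
        object.__setattr__(self, "roles", roles)
        if not roles:
            raise DataError(f"node {self.id!r} has no roles")
        if Role.MIRNA in roles and roles & PROTEIN_ROLES:
            raise DataError(
                f"node {self.id!r} mixes MIRNA with protein roles {sorted(r.value for r in roles)}"
            )
        if Role.TARGET in roles and not self.disease_associated:
            raise DataError(f"TARGET node {self.id!r} must be disease_associated")

    @property
    def is_protein(self) -> bool:
        return bool(self.roles & PROTEIN_ROLES)


@dataclass(frozen=True)
class Edge:
    """A typed link. PPI edges are stored once, in canonical endpoint order."""

    source: str
    target: str
    etype: EdgeType

    def __post_init__(self):
        object.__setattr__(self, "etype", EdgeType(self.etype))
        if self.etype is EdgeType.PPI and self.target < self.source:
            s, t = self.source, self.target
            object.__setattr__(self, "source", t)
            object.__setattr__(self, "target", s)

    def sort_key(self):
        return (self.etype.value, self.source, self.target)


@dataclass(frozen=True)
class NetworkCensus:
    """Per-role node counts (a node is counted once per role it carries),
    per-type edge counts, and distinct-node / total-edge tallies."""

    n_mirnas: int
    n_targets: int
    n_tfs: int
    n_tcofs: int
    n_targeting: int
    n_regulation: int
    n_ppi: int
    total_nodes: int
    total_edges: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


class Network:
    """An immutable-by-convention container of typed nodes and edges.

    Parameters
    ----------
    nodes
        Iterable of :class:`Node` (ids must be unique).
    edges
        Iterable of :class:`Edge`; duplicates (same source, target, type
        after PPI canonicalisation) collapse to one edge.
    promoter_window
        The promoter window length (nt) the REGULATION edges were filtered
        to; metadata only.
    validate
        Check edge-endpoint existence and role constraints on construction.
    """

    def __init__(
        self,
        nodes: Iterable[Node],
        edges: Iterable[Edge],
        promoter_window: int = 1000,
        validate: bool = True,
    ):
        self.nodes: dict[str, Node] = {}
        for n in nodes:
            if n.id in self.nodes:
                raise DataError(f"duplicate node id {n.id!r}")
            self.nodes[n.id] = n
        self.edges: tuple[Edge, ...] = tuple(sorted(set(edges), key=Edge.sort_key))
        self.promoter_window = int(promoter_window)
        self._adj: dict | None = None
        if validate:
            self.validate()

    # -- structural checks -------------------------------------------------

    def validate(self) -> None:
        for e in self.edges:
            for endpoint in (e.source, e.target):
                if endpoint not in self.nodes:
                    raise UnknownIdentifierError(endpoint, "edge endpoint not in node set")
            src, dst = self.nodes[e.source], self.nodes[e.target]
            if e.etype is EdgeType.TARGETING:
                if Role.MIRNA not in src.roles or Role.TARGET not in dst.roles:
                    raise DataError(f"TARGETING edge {e.source}->{e.target} violates role constraints")
            elif e.etype is EdgeType.REGULATION:
                if Role.TF not in src.roles or Role.MIRNA not in dst.roles:
                    raise DataError(f"REGULATION edge {e.source}->{e.target} violates role constraints")
            else:
                if not (src.is_protein and dst.is_protein):
                    raise DataError(f"PPI edge {e.source}--{e.target} joins a non-protein node")

    # -- adjacency ---------------------------------------------------------

    def iter_directed(self):
        """Yield (source, target, etype) with each undirected PPI edge
        expanded into both directions (a PPI self-edge is yielded once)."""
        for e in self.edges:
            yield e.source, e.target, e.etype
            if e.etype is EdgeType.PPI and e.source != e.target:
                yield e.target, e.source, e.etype

    def _ensure_adj(self):
        if self._adj is None:
            adj: dict[str, list] = {nid: [] for nid in self.nodes}
            for u, v, t in self.iter_directed():
                adj[u].append((v, t))
            self._adj = adj
        return self._adj

    def out_edges(self, node_id: str) -> list:
        """Directed out-edges of ``node_id`` as (neighbor, type) pairs; PPI
        edges count as outgoing from both endpoints."""
        if node_id not in self.nodes:
            raise UnknownIdentifierError(node_id)
        return list(self._ensure_adj()[node_id])

    def out_neighbors(self, node_id: str) -> set:
        return {v for v, _ in self.out_edges(node_id)}

    def node_index(self) -> dict[str, int]:
        """Stable id -> position mapping (lexicographic by id)."""
        return {nid: i for i, nid in enumerate(sorted(self.nodes))}

    # -- conveniences ------------------------------------------------------

    def __len__(self) -> int:
        return len(self.nodes)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Network)
            and self.nodes == other.nodes
            and set(self.edges) == set(other.edges)
        )

    def to_networkx(self):
        """Export as a ``networkx.MultiDiGraph`` (PPI edges expanded to two
        antiparallel arcs) for interoperability with generic graph tooling."""
        import networkx as nx

        g = nx.MultiDiGraph(promoter_window=self.promoter_window)
        for n in self.nodes.values():
            g.add_node(
                n.id,
                roles=sorted(r.value for r in n.roles),
                disease_associated=n.disease_associated,
            )
        for u, v, t in self.iter_directed():
            g.add_edge(u, v, etype=t.value)
        return g


# ---------------------------------------------------------------------------
# construction


def _as_id_set(disease_genes) -> set:
    if isinstance(disease_genes, pd.DataFrame):
        return set(disease_genes["gene_id"].astype(str))
    return {str(g) for g in disease_genes}


def build_network(
    mirna_targets: pd.DataFrame,
    disease_genes,
    tf_hits: pd.DataFrame,
    tcof_pairs: pd.DataFrame,
    ppi_pairs: pd.DataFrame,
    promoter_window: int = 1000,
) -> Network:
    """Assemble the disease-centred regulatory network from association tables.

    ``tf_hits`` must already be filtered to the requested promoter window and
    binding-score threshold (see :func:`mirnet.tabio.filter_tfbs_hits`).

    Retention rules
    ---------------
    1. miRNAs with >= 1 verified target in ``disease_genes`` (and those targets);
    2. TFs with >= 1 hit in a retained miRNA's promoter;
    3. TcoFs with a high-confidence interaction with a retained TF (entering
       as PPI-type edges; TcoF identity is kept as a node role);
    4. PPI edges induced on the retained protein set only — no new partner
       proteins are pulled in.

    Multiple binding-site hits of one TF in one miRNA promoter collapse to a
    single REGULATION edge. Raises :class:`DataError` when no miRNA survives.
    """
    disease = _as_id_set(disease_genes)

    hit_rows = mirna_targets[mirna_targets["target_id"].isin(disease)]
    mirnas = set(hit_rows["mirna_id"])
    if not mirnas:
        raise DataError("no miRNA has a disease-associated verified target; nothing to analyse")
    targets = set(hit_rows["target_id"])
    targeting = {(m, t) for m, t in zip(hit_rows["mirna_id"], hit_rows["target_id"])}

    reg_rows = tf_hits[tf_hits["mirna_id"].isin(mirnas)]
    tfs = set(reg_rows["tf_id"])
    regulation = {(f, m) for f, m in zip(reg_rows["tf_id"], reg_rows["mirna_id"])}

    conf = tcof_pairs["confidence"].astype(str).str.lower()
    tc_rows = tcof_pairs[(conf == "high") & tcof_pairs["tf_id"].isin(tfs)]
    tcofs = set(tc_rows["tcof_id"])
    tcof_links = {tuple(sorted((f, c))) for f, c in zip(tc_rows["tf_id"], tc_rows["tcof_id"])}

    proteins = targets | tfs | tcofs
    clash = mirnas & proteins
    if clash:
        raise DataError(f"identifier(s) used as both miRNA and protein: {sorted(clash)[:5]}")

    ppi_keep = ppi_pairs[
        ppi_pairs["protein_a"].isin(proteins) & ppi_pairs["protein_b"].isin(proteins)
    ]
    ppi = {tuple(sorted((a, b))) for a, b in zip(ppi_keep["protein_a"], ppi_keep["protein_b"])}
    ppi |= tcof_links

    nodes = []
    for m in sorted(mirnas):
        nodes.append(Node(m, frozenset({Role.MIRNA})))
    for p in sorted(proteins):
        roles = set()
        if p in tfs:
            roles.add(Role.TF)
        if p in tcofs:
            roles.add(Role.TCOF)
        if p in disease:
            roles.add(Role.TARGET)
        nodes.append(Node(p, frozenset(roles), disease_associated=p in disease))

    edges = (
        [Edge(m, t, EdgeType.TARGETING) for m, t in targeting]
        + [Edge(f, m, EdgeType.REGULATION) for f, m in regulation]
        + [Edge(a, b, EdgeType.PPI) for a, b in ppi]
    )
    return Network(nodes, edges, promoter_window=promoter_window)


# ---------------------------------------------------------------------------
# census and neighborhood queries


def census(network: Network) -> NetworkCensus:
    """Count nodes per role, edges per type, and totals.

    Nodes are counted once per role they carry, so role counts may sum to
    more than ``total_nodes``; ``total_edges`` is always the sum of the three
    per-type edge counts.
    """
    role_counts = {r: 0 for r in Role}
    for n in network.nodes.values():
        for r in n.roles:
            role_counts[r] += 1
    type_counts = {t: 0 for t in EdgeType}
    for e in network.edges:
        type_counts[e.etype] += 1
    return NetworkCensus(
        n_mirnas=role_counts[Role.MIRNA],
        n_targets=role_counts[Role.TARGET],
        n_tfs=role_counts[Role.TF],
        n_tcofs=role_counts[Role.TCOF],
        n_targeting=type_counts[EdgeType.TARGETING],
        n_regulation=type_counts[EdgeType.REGULATION],
        n_ppi=type_counts[EdgeType.PPI],
        total_nodes=len(network.nodes),
        total_edges=len(network.edges),
    )


def _require_role(network: Network, node_id: str, role: Role) -> Node:
    node = network.nodes.get(node_id)
    if node is None:
        raise UnknownIdentifierError(node_id)
    if role not in node.roles:
        raise DataError(f"node {node_id!r} does not carry the {role.value} role")
    return node


def tf_regulon(network: Network, tf: str) -> set:
    """miRNAs regulated by ``tf``: targets of its REGULATION out-edges."""
    _require_role(network, tf, Role.TF)
    return {v for v, t in network.out_edges(tf) if t is EdgeType.REGULATION}


def tf_downstream_targets(network: Network, tf: str) -> set:
    """Proteins reachable from ``tf`` through one regulated miRNA: the union
    of TARGETING-edge targets over the TF's regulon."""
    out = set()
    for m in tf_regulon(network, tf):
        out |= {v for v, t in network.out_edges(m) if t is EdgeType.TARGETING}
    return out


def mirna_in_degree(network: Network, protein: str) -> int:
    """Number of distinct miRNAs with a TARGETING edge into ``protein``."""
    _require_role(network, protein, Role.TARGET)
    return sum(
        1 for e in network.edges if e.etype is EdgeType.TARGETING and e.target == protein
    )
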