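"""Tab-separated readers/writers for association tables and network files.

Dialect: literal tab separators, UTF-8, Unix newlines, mandatory header row,
``#`` comment lines and blank lines skipped.  Third-party layouts (including
published supplementary network files) are adapted with a column-mapping
``{file_column: schema_column}`` supplied either inline or via a YAML/JSON
file.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import DataError, UnknownIdentifierError
from .netmodel import Edge, EdgeType, Network, Node, Role

__all__ = [
    "TableSchema",
    "MIRNA_TARGETS",
    "DISEASE_GENES",
    "TF_HITS",
    "TCOF_PAIRS",
    "PPI_PAIRS",
    "PATHWAYS",
    "read_table",
    "write_table",
    "filter_tfbs_hits",
    "write_network",
    "read_network",
    "load_column_map",
]


@dataclass(frozen=True)
class TableSchema:
    """Named table layout: required column -> dtype ('str' | 'float' | 'int')."""

    name: str
    columns: dict


MIRNA_TARGETS = TableSchema("mirna_targets", {"mirna_id": "str", "target_id": "str"})
DISEASE_GENES = TableSchema("disease_genes", {"gene_id": "str"})
TF_HITS = TableSchema(
    "tf_hits",
    {
        "tf_id": "str",
        "mirna_id": "str",
        "core_score": "float",
        "matrix_score": "float",
        "window_nt": "int",
    },
)
TCOF_PAIRS = TableSchema("tcof_pairs", {"tf_id": "str", "tcof_id": "str", "confidence": "str"})
PPI_PAIRS = TableSchema("ppi_pairs", {"protein_a": "str", "protein_b": "str"})
PATHWAYS = TableSchema("pathways", {"pathway_id": "str", "gene_id": "str"})

_CASTERS = {"str": str, "float": float, "int": int}


def load_column_map(path) -> dict:
    """Read a ``{file_column: schema_column}`` mapping from YAML or JSON."""
    import yaml

    with open(path) as fh:
        mapping = yaml.safe_load(fh)
    if not isinstance(mapping, dict):
        raise DataError(f"column map {path} must be a flat mapping")
    return {str(k): str(v) for k, v in mapping.items()}


def read_table(path, schema: TableSchema, column_map: dict | None = None) -> pd.DataFrame:
    """Read a headered TSV into a typed DataFrame.

    Blank lines and lines starting with ``#`` are skipped.  A missing schema
    column raises :class:`DataError` naming it; a value that fails type
    coercion raises :class:`DataError` with the 1-based file line number.
    """
    path = Path(path)
    raw_lines = path.read_text(encoding="utf-8").splitlines()
    kept: list[tuple[int, str]] = [
        (lineno, line)
        for lineno, line in enumerate(raw_lines, start=1)
        if line.strip() and not line.lstrip().startswith("#")
    ]
    if not kept:
        raise DataError(f"{path}: no header row found")
    header = kept[0][1].rstrip("\n").split("\t")
    if column_map:
        header = [column_map.get(c, c) for c in header]
    missing = [c for c in schema.columns if c not in header]
    if missing:
        raise DataError(f"{path}: missing column(s) {missing} for schema {schema.name!r}")

    body = "\t".join(header) + "\n" + "\n".join(line for _, line in kept[1:])
    df = pd.read_csv(io.StringIO(body), sep="\t", dtype=str, keep_default_na=False)
    df = df[list(schema.columns)]

    line_numbers = [lineno for lineno, _ in kept[1:]]
    for col, kind in schema.columns.items():
        if kind == "str":
            continue
        caster = _CASTERS[kind]
        converted = []
        for i, value in enumerate(df[col]):
            try:
                converted.append(caster(value))
            except (TypeError, ValueError):
                raise DataError(
                    f"{path}:{line_numbers[i]}: cannot parse {value!r} in column {col!r} as {kind}"
                ) from None
        df[col] = converted
    return df.reset_index(drop=True)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# TFBS hit filter


def filter_tfbs_hits(
    hits: pd.DataFrame,
    min_core: float = 0.9,
    min_matrix: float = 0.9,
    window_nt: int | None = None,
) -> pd.DataFrame:
    """Row-wise, order-preserving binding-site hit filter.

    Retains hits with ``core_score >= min_core`` and ``matrix_score >=
    min_matrix`` (both thresholds inclusive) and, when ``window_nt`` is given,
    a matching promoter window.  Scores outside [0, 1] are a hard error.
    """
    for col in ("core_score", "matrix_score"):
        bad = hits[(hits[col] < 0) | (hits[col] > 1)]
        if len(bad):
            raise DataError(f"{col} outside [0, 1] in {len(bad)} row(s), e.g. {bad[col].iloc[0]}")
    mask = (hits["core_score"] >= min_core) & (hits["matrix_score"] >= min_matrix)
    if window_nt is not None:
        mask &= hits["window_nt"] == window_nt
    return hits[mask].reset_index(drop=True)


# ---------------------------------------------------------------------------
# network serialisation


def write_network(network: Network, nodes_path, edges_path) -> None:
    """Write a network as two TSVs.

    Nodes file: ``id``, ``roles`` (comma-joined sorted tokens),
    ``disease_associated`` (0/1).  Edges file: ``source``, ``target``,
    ``edge_type``; PPI edges in canonical endpoint order.  Reading the pair
    back reconstructs an identical network.
    """
    nodes = pd.DataFrame(
        {
            "id": [n.id for n in network.nodes.values()],
            "roles": [",".join(sorted(r.value for r in n.roles)) for n in network.nodes.values()],
            "disease_associated": [int(n.disease_associated) for n in network.nodes.values()],
        }
    ).sort_values("id")
    edges = pd.DataFrame(
        {
            "source": [e.source for e in network.edges],
            "target": [e.target for e in network.edges],
            "edge_type": [e.etype.value for e in network.edges],
        }
    )
    write_table(nodes, nodes_path)
    write_table(edges, edges_path)


_NODES_SCHEMA = TableSchema("nodes", {"id": "str", "roles": "str", "disease_associated": "int"})
_EDGES_SCHEMA = TableSchema("edges", {"source": "str", "target": "str", "edge_type": "str"})


def read_network(
    nodes_path,
    edges_path,
    promoter_window: int = 1000,
    nodes_column_map: dict | None = None,
    edges_column_map: dict | None = None,
) -> Network:
    """Read a network written by :func:`write_network`.

    Column maps adapt externally published layouts whose headers differ.  An
    edge endpoint absent from the nodes file raises
    :class:`UnknownIdentifierError` naming the id.
    """
    ndf = read_table(nodes_path, _NODES_SCHEMA, column_map=nodes_column_map)
    edf = read_table(edges_path, _EDGES_SCHEMA, column_map=edges_column_map)
    nodes = [
        Node(
            row.id,
            frozenset(Role(tok) for tok in row.roles.split(",") if tok),
            disease_associated=bool(row.disease_associated),
        )
        for row in ndf.itertuples()
    ]
    ids = {n.id for n in nodes}
    edges = []
    for row in edf.itertuples():
        for endpoint in (row.source, row.target):
            if endpoint not in ids:
                raise UnknownIdentifierError(endpoint, f"edge file {edges_path}")
        try:
            etype = EdgeType(row.edge_type)
        except ValueError:
            raise DataError(f"{edges_path}: unknown edge type {row.edge_type!r}") from None
        edges.append(Edge(row.source, row.target, etype))
    return Network(nodes, edges, promoter_window=promoter_window)
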