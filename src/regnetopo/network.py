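"""Core data types for directed gene regulatory networks.

A regulatory network is a directed graph over three molecular species:
transcription factors (TFs), microRNAs (miRNAs), and non-TF protein-coding
genes.  Edges run regulator -> target.  The edge-type matrix is fixed by
transcriptional biology: TFs may regulate TFs, non-TF genes and miRNAs
(transcriptional activation/repression of the miRNA gene), while miRNAs
regulate TFs and non-TF genes post-transcriptionally and never other
miRNAs.  Non-TF genes never regulate.

Nodes carry the annotations used throughout the analysis:

* ``is_hk`` — housekeeping, i.e. widely expressed across tissues;
* ``ts_tissues`` — the tissues a gene is specific to (empty = not
  tissue-specific); housekeeping and tissue-specific are mutually
  exclusive, and genes that are neither are called *trivial*;
* ``is_disease`` — disease-associated;
* ``expressed_tissues`` — binary expression presence, used to cut
  per-tissue networks out of a reference network.

The canonical on-disk representation is a pair of TSV files (nodes +
edges); SIF and GraphML are export-only formats for visualization.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "NodeType",
    "GeneClass",
    "GeneNode",
    "GeneClassPartition",
    "RegulatoryNetwork",
    "NetworkValidationError",
    "read_network",
    "read_network_dir",
    "write_network",
    "classify_nodes",
]


class NodeType(str, enum.Enum):
    """Molecular species of a network vertex."""

    MIRNA = "MIRNA"
    TF = "TF"
    NONTF = "NONTF"


#: Allowed regulator -> target type pairs.  Non-TF genes are absent as
#: regulators; miRNA -> miRNA regulation does not exist transcriptionally.
ALLOWED_TARGETS: Mapping[NodeType, frozenset[NodeType]] = {
    NodeType.TF: frozenset({NodeType.TF, NodeType.NONTF, NodeType.MIRNA}),
    NodeType.MIRNA: frozenset({NodeType.TF, NodeType.NONTF}),
}


class GeneClass(str, enum.Enum):
    """Gene classes compared in the topological analysis.

    TFs split three ways (tissue-specific / housekeeping / trivial),
    miRNAs two ways (no housekeeping miRNAs exist).  Disease classes cut
    across the expression-based classes.
    """

    TS_TF = "TS_TF"
    HK_TF = "HK_TF"
    TRIVIAL_TF = "TRIVIAL_TF"
    TS_MIRNA = "TS_MIRNA"
    TRIVIAL_MIRNA = "TRIVIAL_MIRNA"
    DISEASE_TF = "DISEASE_TF"
    NONDISEASE_TF = "NONDISEASE_TF"
    DISEASE_MIRNA = "DISEASE_MIRNA"
    NONDISEASE_MIRNA = "NONDISEASE_MIRNA"


#: node_type implied by each class.
CLASS_NODE_TYPE: Mapping[GeneClass, NodeType] = {
    GeneClass.TS_TF: NodeType.TF,
    GeneClass.HK_TF: NodeType.TF,
    GeneClass.TRIVIAL_TF: NodeType.TF,
    GeneClass.DISEASE_TF: NodeType.TF,
    GeneClass.NONDISEASE_TF: NodeType.TF,
    GeneClass.TS_MIRNA: NodeType.MIRNA,
    GeneClass.TRIVIAL_MIRNA: NodeType.MIRNA,
    GeneClass.DISEASE_MIRNA: NodeType.MIRNA,
    GeneClass.NONDISEASE_MIRNA: NodeType.MIRNA,
}


class NetworkValidationError(ValueError):
    """An input violates a network invariant (types, duplicates, loops)."""


@dataclass(frozen=True)
class GeneNode:
    """A network vertex with molecular type and class annotations."""

    node_id: str
    node_type: NodeType
    is_hk: bool = False
    ts_tissues: frozenset = frozenset()
    is_disease: bool = False
    expressed_tissues: frozenset = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "node_type", NodeType(self.node_type))
        object.__setattr__(self, "ts_tissues", frozenset(self.ts_tissues))
        object.__setattr__(
            self, "expressed_tissues", frozenset(self.expressed_tissues)
        )
        if self.is_hk and self.ts_tissues:
            raise NetworkValidationError(
                f"node {self.node_id!r}: housekeeping and tissue-specific "
                "are mutually exclusive"
            )
        if self.node_type is NodeType.MIRNA and self.is_hk:
            raise NetworkValidationError(
                f"node {self.node_id!r}: there are no housekeeping miRNAs"
            )

    @property
    def is_ts(self) -> bool:
        return bool(self.ts_tissues)


@dataclass(frozen=True)
class GeneClassPartition:
    """One gene class and its member node ids within a network."""

    class_name: GeneClass
    member_ids: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "class_name", GeneClass(self.class_name))
        object.__setattr__(self, "member_ids", frozenset(self.member_ids))

    def __len__(self) -> int:
        return len(self.member_ids)


class RegulatoryNetwork:
    """Directed graph over :class:`GeneNode` with type-constrained edges.

    All invariants are enforced at construction time: unique node ids,
    edge endpoints declared, regulator types in {TF, MIRNA}, target types
    allowed by the regulator, no self-loops, no duplicate edges.
    """

    def __init__(
        self,
        nodes: Iterable[GeneNode],
        edges: Iterable[tuple[str, str]],
        tissue: str | None = None,
    ) -> None:
        self.tissue = tissue
        self._nodes: dict[str, GeneNode] = {}
        for node in nodes:
            if node.node_id in self._nodes:
                raise NetworkValidationError(
                    f"duplicate node id {node.node_id!r}"
                )
            self._nodes[node.node_id] = node

        self._out: dict[str, set[str]] = {nid: set() for nid in self._nodes}
        self._in: dict[str, set[str]] = {nid: set() for nid in self._nodes}
        seen: set[tuple[str, str]] = set()
        for reg, targ in edges:
            self._validate_edge(reg, targ)
            if (reg, targ) in seen:
                raise NetworkValidationError(
                    f"duplicate edge ({reg!r}, {targ!r})"
                )
            seen.add((reg, targ))
            self._out[reg].add(targ)
            self._in[targ].add(reg)
        self._edges: tuple[tuple[str, str], ...] = tuple(sorted(seen))

    def _validate_edge(self, reg: str, targ: str) -> None:
        for endpoint in (reg, targ):
            if endpoint not in self._nodes:
                raise NetworkValidationError(
                    f"edge ({reg!r}, {targ!r}) references unknown node "
                    f"{endpoint!r}"
                )
        if reg == targ:
            raise NetworkValidationError(f"self-loop on node {reg!r}")
        rtype = self._nodes[reg].node_type
        ttype = self._nodes[targ].node_type
        if rtype not in ALLOWED_TARGETS:
            raise NetworkValidationError(
                f"edge ({reg!r}, {targ!r}): {rtype.value} nodes cannot "
                "regulate"
            )
        if ttype not in ALLOWED_TARGETS[rtype]:
            raise NetworkValidationError(
                f"edge ({reg!r}, {targ!r}): {rtype.value} -> {ttype.value} "
                "regulation is invalid"
            )

    # -- inspection ------------------------------------------------------

    @property
    def node_ids(self) -> list[str]:
        return sorted(self._nodes)

    @property
    def nodes(self) -> list[GeneNode]:
        return [self._nodes[nid] for nid in self.node_ids]

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self._edges)

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._nodes

    def node(self, node_id: str) -> GeneNode:
        return self._nodes[node_id]

    def nodes_of_type(self, node_type: NodeType) -> list[str]:
        node_type = NodeType(node_type)
        return [
            nid for nid in self.node_ids
            if self._nodes[nid].node_type is node_type
        ]

    def out_neighbors(self, node_id: str) -> set[str]:
        return set(self._out[node_id])

    def in_neighbors(self, node_id: str) -> set[str]:
        return set(self._in[node_id])

    def neighbors(self, node_id: str) -> set[str]:
        """Union of in- and out-neighbors (direction ignored)."""
        return self._out[node_id] | self._in[node_id]

    def tissues(self) -> set[str]:
        """All tissue names appearing in any node's expression profile."""
        out: set[str] = set()
        for node in self._nodes.values():
            out |= node.expressed_tissues
        return out

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for nid in self.node_ids:
            g.add_node(nid, node_type=self._nodes[nid].node_type.value)
        g.add_edges_from(self._edges)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegulatoryNetwork):
            return NotImplemented
        return (
            self._nodes == other._nodes
            and self._edges == other._edges
            and self.tissue == other.tissue
        )

    def __repr__(self) -> str:
        tissue = f", tissue={self.tissue!r}" if self.tissue else ""
        return (
            f"RegulatoryNetwork({self.n_nodes} nodes, "
            f"{self.n_edges} edges{tissue})"
        )


# -- node classification -------------------------------------------------


def classify_nodes(
    net: RegulatoryNetwork, tissue: str
) -> list[GeneClassPartition]:
    """Partition a network's TFs and miRNAs into the nine gene classes.

    Classification is relative to ``tissue``: a gene specific to another
    tissue counts as trivial here.  TFs split into tissue-specific (TS),
    housekeeping (HK) and trivial; miRNAs into TS and trivial; disease
    partitions cut across those.  The three TF classes (two miRNA
    classes) are pairwise disjoint and cover all TFs (miRNAs).
    """
    if tissue not in net.tissues():
        raise ValueError(f"unknown tissue {tissue!r}: no node expresses it")

    members: dict[GeneClass, set[str]] = {cls: set() for cls in GeneClass}
    for node in net.nodes:
        if node.node_type is NodeType.TF:
            if tissue in node.ts_tissues:
                members[GeneClass.TS_TF].add(node.node_id)
            elif node.is_hk:
                members[GeneClass.HK_TF].add(node.node_id)
            else:
                members[GeneClass.TRIVIAL_TF].add(node.node_id)
            key = (
                GeneClass.DISEASE_TF
                if node.is_disease
                else GeneClass.NONDISEASE_TF
            )
            members[key].add(node.node_id)
        elif node.node_type is NodeType.MIRNA:
            if tissue in node.ts_tissues:
                members[GeneClass.TS_MIRNA].add(node.node_id)
            else:
                members[GeneClass.TRIVIAL_MIRNA].add(node.node_id)
            key = (
                GeneClass.DISEASE_MIRNA
                if node.is_disease
                else GeneClass.NONDISEASE_MIRNA
            )
            members[key].add(node.node_id)
    return [
        GeneClassPartition(cls, frozenset(members[cls])) for cls in GeneClass
    ]


def partition_map(
    partitions: Sequence[GeneClassPartition],
) -> dict[GeneClass, frozenset]:
    """Index a partition list by class name."""
    return {p.class_name: p.member_ids for p in partitions}


# -- I/O -----------------------------------------------------------------

NODE_COLUMNS = [
    "node_id",
    "node_type",
    "is_hk",
    "ts_tissues",
    "is_disease",
    "expressed_tissues",
]
EDGE_COLUMNS = ["regulator", "target"]


def _join_set(values: frozenset) -> str:
    return ",".join(sorted(values))


def _split_set(value: str) -> frozenset:
    value = value.strip()
    if not value:
        return frozenset()
    return frozenset(value.split(","))


def _parse_bool(value: str, context: str) -> bool:
    if value not in {"0", "1"}:
        raise NetworkValidationError(
            f"{context}: boolean column must be 0 or 1, got {value!r}"
        )
    return value == "1"


def read_network(
    edge_path: str | Path,
    node_path: str | Path,
    tissue: str | None = None,
) -> RegulatoryNetwork:
    """Load a network from the canonical TSV pair and validate it.

    The node file has columns ``node_id, node_type, is_hk, ts_tissues,
    is_disease, expressed_tissues`` (booleans as 0/1, set-valued columns
    comma-joined, empty string = empty set); the edge file has columns
    ``regulator, target``.
    """
    node_df = pd.read_csv(
        node_path, sep="\t", dtype=str, keep_default_na=False
    )
    missing = [c for c in NODE_COLUMNS if c not in node_df.columns]
    if missing:
        raise NetworkValidationError(
            f"node file {node_path}: missing columns {missing}"
        )
    nodes = [
        GeneNode(
            node_id=row.node_id,
            node_type=NodeType(row.node_type),
            is_hk=_parse_bool(row.is_hk, f"node {row.node_id!r} is_hk"),
            ts_tissues=_split_set(row.ts_tissues),
            is_disease=_parse_bool(
                row.is_disease, f"node {row.node_id!r} is_disease"
            ),
            expressed_tissues=_split_set(row.expressed_tissues),
        )
        for row in node_df.itertuples(index=False)
    ]
    edge_df = pd.read_csv(
        edge_path, sep="\t", dtype=str, keep_default_na=False
    )
    missing = [c for c in EDGE_COLUMNS if c not in edge_df.columns]
    if missing:
        raise NetworkValidationError(
            f"edge file {edge_path}: missing columns {missing}"
        )
    edges = list(
        zip(edge_df["regulator"].tolist(), edge_df["target"].tolist())
    )
    return RegulatoryNetwork(nodes, edges, tissue=tissue)


def read_network_dir(
    path: str | Path, tissue: str | None = None
) -> RegulatoryNetwork:
    """Load ``<path>/edges.tsv`` + ``<path>/nodes.tsv``."""
    path = Path(path)
    return read_network(path / "edges.tsv", path / "nodes.tsv", tissue=tissue)


def _node_table(net: RegulatoryNetwork) -> pd.DataFrame:
    rows = [
        {
            "node_id": n.node_id,
            "node_type": n.node_type.value,
            "is_hk": int(n.is_hk),
            "ts_tissues": _join_set(n.ts_tissues),
            "is_disease": int(n.is_disease),
            "expressed_tissues": _join_set(n.expressed_tissues),
        }
        for n in net.nodes
    ]
    return pd.DataFrame(rows, columns=NODE_COLUMNS)


def write_network(
    net: RegulatoryNetwork, path: str | Path, format: str = "tsv"
) -> None:
    """Write a network to disk.

    ``tsv`` (canonical, round-trippable) writes ``nodes.tsv`` and
    ``edges.tsv`` under ``path`` treated as a directory.  ``sif`` writes
    one ``<source>\\tregulates\\t<target>`` line per edge; ``graphml``
    exports with node attributes for visualization.  Rows are sorted so
    output bytes are stable across runs.
    """
    format = format.lower()
    path = Path(path)
    if format == "tsv":
        path.mkdir(parents=True, exist_ok=True)
        _node_table(net).to_csv(path / "nodes.tsv", sep="\t", index=False)
        pd.DataFrame(net.edges, columns=EDGE_COLUMNS).to_csv(
            path / "edges.tsv", sep="\t", index=False
        )
    elif format == "sif":
        lines = [f"{u}\tregulates\t{v}" for u, v in net.edges]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif format == "graphml":
        g = nx.DiGraph()
        for n in net.nodes:
            g.add_node(
                n.node_id,
                node_type=n.node_type.value,
                is_hk=int(n.is_hk),
                is_disease=int(n.is_disease),
                ts_tissues=_join_set(n.ts_tissues),
                expressed_tissues=_join_set(n.expressed_tissues),
            )
        g.add_edges_from(net.edges)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unsupported format {format!r}")
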