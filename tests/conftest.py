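from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from regnetopo import GeneNode, NodeType, RegulatoryNetwork

TYPE_ABBREV = {
    "TF": NodeType.TF,
    "NONTF": NodeType.NONTF,
    "MIRNA": NodeType.MIRNA,
}


def build_net(
    nodes: dict[str, str],
    edges: list[tuple[str, str]],
    tissue: str | None = None,
    annotations: dict[str, dict] | None = None,
) -> RegulatoryNetwork:
    """Compact network factory: nodes maps id -> type name; optional
    per-node annotation overrides (is_hk, ts_tissues, ...)."""
    annotations = annotations or {}
    gene_nodes = [
        GeneNode(
            node_id=nid,
            node_type=TYPE_ABBREV[type_name],
            **annotations.get(nid, {}),
        )
        for nid, type_name in nodes.items()
    ]
    return RegulatoryNetwork(gene_nodes, edges, tissue=tissue)


def random_valid_network(
    rng: np.random.Generator,
    n_tf: int = 4,
    n_nontf: int = 5,
    n_mirna: int = 3,
    p_edge: float = 0.3,
) -> RegulatoryNetwork:
    """Random network honoring the regulator/target type matrix."""
    nodes = {}
    for i in range(n_tf):
        nodes[f"tf{i}"] = "TF"
    for i in range(n_nontf):
        nodes[f"g{i}"] = "NONTF"
    for i in range(n_mirna):
        nodes[f"m{i}"] = "MIRNA"
    edges = []
    for reg, rtype in nodes.items():
        if rtype == "NONTF":
            continue
        for targ, ttype in nodes.items():
            if targ == reg:
                continue
            if rtype == "MIRNA" and ttype == "MIRNA":
                continue
            if rng.random() < p_edge:
                edges.append((reg, targ))
    return build_net(nodes, edges)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def path_net() -> RegulatoryNetwork:
    """Directed path a -> b -> c (all TFs)."""
    return build_net(
        {"a": "TF", "b": "TF", "c": "NONTF"}, [("a", "b"), ("b", "c")]
    )


@pytest.fixture
def mixed_net() -> RegulatoryNetwork:
    """Small mixed network with every edge type."""
    return build_net(
        {
            "tf1": "TF",
            "tf2": "TF",
            "g1": "NONTF",
            "g2": "NONTF",
            "m1": "MIRNA",
            "m2": "MIRNA",
        },
        [
            ("tf1", "tf2"),
            ("tf1", "g1"),
            ("tf1", "m1"),
            ("tf2", "g2"),
            ("m1", "tf2"),
            ("m1", "g1"),
            ("m2", "g2"),
        ],
    )
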