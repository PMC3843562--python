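"""Tissue-network extraction.

A reference network covers the whole genome; the network active in one
tissue is the induced subgraph over the genes expressed there.  Nodes
that become isolated after induction are retained — they are expressed
genes with no predicted regulation among expressed partners, and
dropping them would bias random background sets drawn from the tissue
network.
"""

from __future__ import annotations

from .network import RegulatoryNetwork

__all__ = ["extract_tissue_network"]


def extract_tissue_network(
    ref: RegulatoryNetwork, tissue: str
) -> RegulatoryNetwork:
    """Induce the subgraph of ``ref`` over nodes expressed in ``tissue``.

    The node set is every node whose ``expressed_tissues`` contains the
    tissue; the edge set keeps edges with both endpoints expressed.
    Extraction is idempotent and monotone in expression: adding a tissue
    to a node's profile can only add nodes/edges to that tissue's
    extraction.

    Raises ``ValueError`` if no node is expressed in the tissue.
    """
    nodes = [n for n in ref.nodes if tissue in n.expressed_tissues]
    if not nodes:
        raise ValueError(f"no node is expressed in tissue {tissue!r}")
    kept = {n.node_id for n in nodes}
    edges = [(u, v) for u, v in ref.edges if u in kept and v in kept]
    return RegulatoryNetwork(nodes, edges, tissue=tissue)
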