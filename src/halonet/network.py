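"""Molecular network construction, cluster lookup and export.

Nodes are MS2 spectra (labeled by nominal parent mass), edges connect
spectra whose modified-cosine score clears a floor (default 0.7) with
enough matched peaks.  Connected components are the compound-family
clusters interrogated during dereplication.  Exports are plain TSV
(nodes + edges) and GraphML, both importable into Cytoscape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import networkx as nx

from .similarity import FRAG_TOL, SimilarityResult, pairwise_scores
from .spectra import MIN_PEAKS, Dataset

__all__ = [
    "Node",
    "Edge",
    "SpectralNetwork",
    "build_network",
    "find_cluster",
    "export_network",
    "COS_MIN",
]

#: Minimum cosine for an edge to enter the network.
COS_MIN: float = 0.7


@dataclass(frozen=True)
class Node:
    """A network node: one retained MS2 spectrum."""

    id: str
    precursor_mz: float
    rt: float | None = None
    annotations: dict = field(default_factory=dict, compare=False)

    @property
    def nominal(self) -> int:
        """Nominal parent-mass label, as displayed on the network."""
        return round(self.precursor_mz)


@dataclass(frozen=True)
class Edge:
    """An undirected scored edge between two nodes."""

    source: str
    target: str
    cosine: float
    n_matched: int
    precursor_delta: float


@dataclass
class SpectralNetwork:
    """Nodes, edges and connected components of a molecular network."""

    nodes: list[Node]
    edges: list[Edge]
    graph: nx.Graph = field(repr=False, default_factory=nx.Graph)

    @property
    def components(self) -> list[list[Node]]:
        """Connected components (clusters), each sorted by precursor m/z,
        ordered by their lightest member."""
        by_id = {n.id: n for n in self.nodes}
        comps = [
            sorted((by_id[i] for i in comp), key=lambda n: (n.precursor_mz, n.id))
            for comp in nx.connected_components(self.graph)
        ]
        comps.sort(key=lambda c: (c[0].precursor_mz, c[0].id))
        return comps

    def node(self, node_id: str) -> Node:
        by_id = {n.id: n for n in self.nodes}
        return by_id[node_id]


def build_network(
    d: Dataset,
    cos_min: float = COS_MIN,
    min_matched: int = MIN_PEAKS,
    frag_tol: float = FRAG_TOL,
    allow_shift: bool = True,
    scaling: Literal["sqrt", "raw"] = "sqrt",
    min_peaks: int = MIN_PEAKS,
) -> SpectralNetwork:
    """Build the molecular network of an MS2 dataset.

    Spectra with fewer than ``min_peaks`` fragments are dropped first;
    an edge is kept exactly when the (modified) cosine is >= ``cos_min``
    and at least ``min_matched`` peak pairs were matched.  Deterministic
    for a fixed dataset and parameters.
    """
    retained = d.filtered(min_peaks)
    nodes = [
        Node(id=s.id, precursor_mz=s.precursor_mz, rt=s.rt)
        for s in retained.spectra
    ]
    graph = nx.Graph()
    for n in nodes:
        graph.add_node(n.id, precursor_mz=n.precursor_mz, nominal=n.nominal,
                       rt=-1.0 if n.rt is None else n.rt)
    edges: list[Edge] = []
    scores = pairwise_scores(
        retained, frag_tol=frag_tol, allow_shift=allow_shift,
        scaling=scaling, min_peaks=min_peaks,
    )
    for i, j, res in scores:
        if res.score >= cos_min and res.n_matched >= min_matched:
            e = Edge(
                source=retained.spectra[i].id,
                target=retained.spectra[j].id,
                cosine=res.score,
                n_matched=res.n_matched,
                precursor_delta=res.precursor_delta,
            )
            edges.append(e)
            graph.add_edge(
                e.source, e.target, cosine=e.cosine,
                matched_peaks=e.n_matched, precursor_delta=e.precursor_delta,
            )
    return SpectralNetwork(nodes=nodes, edges=edges, graph=graph)


def find_cluster(
    net: SpectralNetwork, seed_mz: float, tol: float = 0.5
) -> list[Node]:
    """The connected component containing the node nearest a seed mass.

    The best-matching node minimizes |precursor − seed| (ties: smaller
    m/z, then id); an empty list is returned when no node lies within
    ``tol`` Da of the seed.
    """
    best: Node | None = None
    best_key: tuple | None = None
    for n in net.nodes:
        d = abs(n.precursor_mz - seed_mz)
        if d > tol:
            continue
        key = (d, n.precursor_mz, n.id)
        if best_key is None or key < best_key:
            best, best_key = n, key
    if best is None:
        return []
    comp_ids = nx.node_connected_component(net.graph, best.id)
    by_id = {n.id: n for n in net.nodes}
    return sorted((by_id[i] for i in comp_ids), key=lambda n: (n.precursor_mz, n.id))


def export_network(
    net: SpectralNetwork,
    path: str | Path,
    format: Literal["edges-tsv", "nodes-tsv", "graphml"] = "edges-tsv",
) -> Path:
    """Export the network for Cytoscape.

    ``edges-tsv``: source_id, target_id, cosine, matched_peaks,
    precursor_delta.  ``nodes-tsv``: id, precursor_mz, nominal, rt,
    annotations.  ``graphml``: same attributes on a GraphML graph.
    """
    path = Path(path)
    if format == "edges-tsv":
        lines = ["source_id\ttarget_id\tcosine\tmatched_peaks\tprecursor_delta"]
        for e in sorted(net.edges, key=lambda e: (e.source, e.target)):
            lines.append(
                f"{e.source}\t{e.target}\t{e.cosine:.4f}"
                f"\t{e.n_matched}\t{e.precursor_delta:.4f}"
            )
        path.write_text("\n".join(lines) + "\n")
    elif format == "nodes-tsv":
        lines = ["id\tprecursor_mz\tnominal\trt\tannotations"]
        for n in sorted(net.nodes, key=lambda n: n.id):
            rt = "" if n.rt is None else f"{n.rt:.2f}"
            ann = ";".join(f"{k}={v}" for k, v in sorted(n.annotations.items()))
            lines.append(f"{n.id}\t{n.precursor_mz:.4f}\t{n.nominal}\t{rt}\t{ann}")
        path.write_text("\n".join(lines) + "\n")
    elif format == "graphml":
        nx.write_graphml(net.graph, str(path))
    else:
        raise ValueError(f"unknown export format {format!r}")
    return path
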