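"""Bipartite interview network: block adjacency, degrees, summaries, export.

The network N has one node per code and one node per interviewee, with a link
whenever the interviewee responded to the code.  Its adjacency matrix is the
(M+N) x (M+N) symmetric block matrix

    A = [[0, B], [B^T, 0]]

with the M code nodes first.  A node's degree k_l is its row (= column) sum
of A: for a code, the number of interviewees addressing it; for an
interviewee, the number of codes they addressed.

Internally the graph is held as a :class:`networkx.Graph` with node
attributes ``partition`` (code|interviewee), ``theme`` (codes) and
``role``/``subgroup`` (interviewees); the dense A is materialized on demand.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Literal, Sequence

import networkx as nx
import numpy as np

from .coding_data import (
    Codebook,
    IncidenceMatrix,
    Interviewee,
    round_half_away,
)
from .errors import ValidationError

__all__ = [
    "InterviewNetwork",
    "NodeDegrees",
    "DegreeDistribution",
    "NetworkSummary",
    "build_network",
    "degrees",
    "degree_distribution",
    "summarize",
    "export_graph",
]


@dataclass(frozen=True)
class InterviewNetwork:
    graph: nx.Graph
    code_order: tuple[str, ...]
    interviewee_order: tuple[str, ...]

    @property
    def node_order(self) -> tuple[str, ...]:
        """Code nodes 1..M first, then interviewee nodes M+1..M+N."""
        return self.code_order + self.interviewee_order

    def adjacency(self) -> np.ndarray:
        """Materialize the dense block matrix A in node_order."""
        return nx.to_numpy_array(self.graph, nodelist=self.node_order, dtype=int)

    @property
    def num_links(self) -> int:
        return self.graph.number_of_edges()


@dataclass(frozen=True)
class NodeDegrees:
    k: dict[str, int]


@dataclass(frozen=True)
class DegreeDistribution:
    partition: Literal["code", "interviewee"]
    histogram: dict[int, int]  # degree value -> number of nodes


@dataclass(frozen=True)
class NetworkSummary:
    num_links: int
    max_code_degree: tuple[int, tuple[str, ...]]
    max_interviewee_degree: tuple[int, tuple[str, ...]]
    mean_code_degree_rounded: int
    mean_interviewee_degree_rounded: int


def build_network(
    incidence: IncidenceMatrix,
    codebook: Codebook,
    roster: Sequence[Interviewee],
) -> InterviewNetwork:
    """Assemble the bipartite network from the incidence matrix.

    Node ids are the string ids ("7.8", "E_4"); numeric indices never leak.
    """
    if tuple(codebook.code_ids) != tuple(incidence.code_index):
        raise ValidationError("incidence rows disagree with codebook order")
    roster_ids = tuple(iv.interviewee_id for iv in roster)
    if roster_ids != tuple(incidence.interviewee_index):
        raise ValidationError("incidence columns disagree with roster order")

    G = nx.Graph()
    theme = {cid: tid for cid, tid, _ in codebook.codes}
    for cid in incidence.code_index:
        G.add_node(cid, partition="code", theme=theme[cid])
    for iv in roster:
        G.add_node(
            iv.interviewee_id,
            partition="interviewee",
            role=iv.role.value,
            subgroup=iv.subgroup.value,
        )
    rows, cols = np.nonzero(incidence.B)
    for i, j in zip(rows, cols):
        G.add_edge(incidence.code_index[i], incidence.interviewee_index[j])
    return InterviewNetwork(
        graph=G,
        code_order=tuple(incidence.code_index),
        interviewee_order=roster_ids,
    )


def degrees(network: InterviewNetwork) -> NodeDegrees:
    """Degree of every node, k_l = row sum of A at l."""
    return NodeDegrees(k={n: int(d) for n, d in network.graph.degree()})


def degree_distribution(
    network_degrees: NodeDegrees,
    network: InterviewNetwork,
    partition: Literal["code", "interviewee"],
) -> DegreeDistribution:
    """Histogram of degrees over one partition only."""
    if partition not in ("code", "interviewee"):
        raise ValidationError(f"unknown partition {partition!r}")
    nodes = network.code_order if partition == "code" else network.interviewee_order
    hist = Counter(network_degrees.k[n] for n in nodes)
    return DegreeDistribution(partition=partition, histogram=dict(sorted(hist.items())))


def summarize(network: InterviewNetwork, network_degrees: NodeDegrees) -> NetworkSummary:
    """Link count, per-partition degree maxima (ties as full id lists in input
    order) and means rounded half away from zero."""
    k = network_degrees.k
    code_deg = [k[c] for c in network.code_order]
    iv_deg = [k[v] for v in network.interviewee_order]

    def _argmax(order: tuple[str, ...], vals: list[int]) -> tuple[int, tuple[str, ...]]:
        if not vals:
            return 0, ()
        m = max(vals)
        return m, tuple(n for n, v in zip(order, vals) if v == m)

    return NetworkSummary(
        num_links=network.num_links,
        max_code_degree=_argmax(network.code_order, code_deg),
        max_interviewee_degree=_argmax(network.interviewee_order, iv_deg),
        mean_code_degree_rounded=round_half_away(float(np.mean(code_deg))) if code_deg else 0,
        mean_interviewee_degree_rounded=round_half_away(float(np.mean(iv_deg))) if iv_deg else 0,
    )


def export_graph(network: InterviewNetwork, fmt: str, path) -> None:
    """Write the network as GraphML or GEXF with degree as a node attribute."""
    G = network.graph.copy()
    for n, d in G.degree():
        G.nodes[n]["degree"] = int(d)
    if fmt == "graphml":
        nx.write_graphml(G, path)
    elif fmt == "gexf":
        nx.write_gexf(G, path)
    else:
        raise ValidationError(f"unsupported export format {fmt!r}")
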