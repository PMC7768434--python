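"""Dichotomized "concern" analysis: the weighted yes/no multigraph.

Each response to a code is checked for a key statement on whether the
interviewee voiced a concern; responses dichotomize into ``yes`` (concern
present — the negatively connoted option) or ``no``.  Responses where no such
statement occurs are excluded, and a code with no classifiable response left
is excluded entirely.  The surviving counts form the M' x 2 incidence

    B'[i] = (#y_i, #n_i)

linking each code to a "yes" node and a "no" node with integer link weights,
giving a small weighted multigraph with the same block-adjacency structure as
the interview network.  Codes then partition into no-concern (#y = 0),
all-concern (#n = 0) and controversial (both positive).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .coding_data import Codebook, ConcernLabel, ResponseTable
from .errors import ValidationError

__all__ = [
    "ConcernClassification",
    "ConcernIncidence",
    "ConcernMultigraph",
    "ControversyReport",
    "classify_responses",
    "build_concern_incidence",
    "build_concern_network",
    "controversy_report",
    "export_concern_graph",
]

YES_NODE = "yes"
NO_NODE = "no"


@dataclass(frozen=True)
class ConcernClassification:
    """Outcome of dichotomizing a response table.

    ``labels`` maps (code_id, interviewee_id) to yes/no for every kept
    response; ``excluded_responses`` counts responses dropped for carrying no
    usable key statement; ``excluded_codes`` are codes retaining no labeled
    response at all.
    """

    labels: dict[tuple[str, str], ConcernLabel]
    excluded_responses: int
    excluded_codes: frozenset[str]


@dataclass(frozen=True)
class ConcernIncidence:
    Bp: np.ndarray  # M' x 2, column 0 = #y_i, column 1 = #n_i
    code_index: tuple[str, ...]

    def __post_init__(self) -> None:
        Bp = np.asarray(self.Bp, dtype=int)
        if Bp.ndim != 2 or Bp.shape != (len(self.code_index), 2):
            raise ValidationError("concern incidence must be M' x 2")
        if (Bp < 0).any():
            raise ValidationError("concern counts must be non-negative")
        if len(self.code_index) and (Bp.sum(axis=1) < 1).any():
            raise ValidationError("every included code needs >= 1 labeled response")
        object.__setattr__(self, "Bp", Bp)

    @property
    def M(self) -> int:
        return len(self.code_index)


@dataclass(frozen=True)
class ConcernMultigraph:
    Ap: np.ndarray  # (M'+2) x (M'+2) symmetric integer weights
    node_order: tuple[str, ...]  # codes, then the yes node, then the no node
    graph: nx.Graph


@dataclass(frozen=True)
class ControversyReport:
    no_concern: frozenset[str]  # #y = 0
    all_concern: frozenset[str]  # #n = 0
    controversial: frozenset[str]  # both > 0


def classify_responses(responses: ResponseTable) -> ConcernClassification:
    """Keep yes/no labeled responses; tally and drop the rest.

    A code appearing in the responses but retaining zero labeled responses
    joins ``excluded_codes``.
    """
    labels: dict[tuple[str, str], ConcernLabel] = {}
    excluded = 0
    seen_codes: set[str] = set()
    for rec in responses.records:
        seen_codes.add(rec.code_id)
        if rec.concern_label in (ConcernLabel.yes, ConcernLabel.no):
            labels[(rec.code_id, rec.interviewee_id)] = rec.concern_label
        else:
            excluded += 1
    labeled_codes = {c for c, _ in labels}
    return ConcernClassification(
        labels=labels,
        excluded_responses=excluded,
        excluded_codes=frozenset(seen_codes - labeled_codes),
    )


def build_concern_incidence(
    classification: ConcernClassification, codebook: Codebook
) -> ConcernIncidence:
    """Count yes/no answers per code, rows in codebook order over included codes."""
    if not classification.labels:
        raise ValidationError("no classified responses: nothing to build")
    labeled_codes = {c for c, _ in classification.labels}
    code_index = tuple(c for c in codebook.code_ids if c in labeled_codes)
    unknown = labeled_codes - set(code_index)
    if unknown:
        raise ValidationError(f"labeled codes missing from codebook: {sorted(unknown)}")
    row = {c: i for i, c in enumerate(code_index)}
    Bp = np.zeros((len(code_index), 2), dtype=int)
    for (code_id, _), label in classification.labels.items():
        Bp[row[code_id], 0 if label is ConcernLabel.yes else 1] += 1
    return ConcernIncidence(Bp=Bp, code_index=code_index)


def build_concern_network(incidence: ConcernIncidence) -> ConcernMultigraph:
    """Assemble A' = [[0, B'], [B'^T, 0]] and its weighted graph view."""
    Mp = incidence.M
    Ap = np.zeros((Mp + 2, Mp + 2), dtype=int)
    Ap[:Mp, Mp:] = incidence.Bp
    Ap[Mp:, :Mp] = incidence.Bp.T
    G = nx.Graph()
    for cid in incidence.code_index:
        G.add_node(cid, partition="code")
    G.add_node(YES_NODE, partition="answer", answer="yes")
    G.add_node(NO_NODE, partition="answer", answer="no")
    for i, cid in enumerate(incidence.code_index):
        y, n = int(incidence.Bp[i, 0]), int(incidence.Bp[i, 1])
        if y:
            G.add_edge(cid, YES_NODE, weight=y)
        if n:
            G.add_edge(cid, NO_NODE, weight=n)
    return ConcernMultigraph(
        Ap=Ap,
        node_order=incidence.code_index + (YES_NODE, NO_NODE),
        graph=G,
    )


def controversy_report(incidence: ConcernIncidence) -> ControversyReport:
    """Partition included codes by the sign pattern of (#y, #n)."""
    no_c, all_c, contro = [], [], []
    for cid, (y, n) in zip(incidence.code_index, incidence.Bp):
        if y == 0:
            no_c.append(cid)
        elif n == 0:
            all_c.append(cid)
        else:
            contro.append(cid)
    return ControversyReport(
        no_concern=frozenset(no_c),
        all_concern=frozenset(all_c),
        controversial=frozenset(contro),
    )


def export_concern_graph(multigraph: ConcernMultigraph, fmt: str, path) -> None:
    """Write the weighted multigraph as GraphML or GEXF."""
    if fmt == "graphml":
        nx.write_graphml(multigraph.graph, path)
    elif fmt == "gexf":
        nx.write_gexf(multigraph.graph, path)
    else:
        raise ValidationError(f"unsupported export format {fmt!r}")
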