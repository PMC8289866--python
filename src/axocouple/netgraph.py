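"""Directed connectivity graphs over propagation signals.

Nodes are propagation-signal neurons (including isolated ones); directed
edges are accepted signal→signal couplings carrying the coupling
probability and latency.  Graphs from different experimental conditions of
the same culture are compared by partitioning the union of their edge sets
into retained / lost / gained edges, after matching signal identities
across conditions by electrode-cohort overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .coupling import Coupling
from .propagation import PropagationSignal

__all__ = [
    "ConnectivityGraph",
    "GraphDiff",
    "build_graph",
    "diff_graphs",
    "match_signals",
    "save_edge_list",
    "load_edge_list",
    "save_graphml",
    "load_graphml",
]

Edge = tuple[str, str]


@dataclass
class ConnectivityGraph:
    graph: nx.DiGraph
    condition_label: str = ""

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[Edge]:
        return set(self.graph.edges)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def recurrent_pairs(self) -> set[frozenset]:
        """Node pairs coupled in both directions (A→B and B→A)."""
        return {
            frozenset((u, v))
            for u, v in self.graph.edges
            if self.graph.has_edge(v, u)
        }


@dataclass(frozen=True)
class GraphDiff:
    retained: frozenset
    lost: frozenset
    gained: frozenset

    def __post_init__(self) -> None:
        if self.retained & self.lost or self.retained & self.gained or self.lost & self.gained:
            raise ValueError("retained/lost/gained must be disjoint")


def build_graph(
    signals: Sequence[PropagationSignal],
    couplings: Sequence[Coupling],
    condition_label: str = "",
) -> ConnectivityGraph:
    """Graph over all signals (isolated ones included) with signal→signal
    couplings as directed edges.  Couplings targeting single electrodes are
    ignored; a coupling referencing an unknown signal is an error."""
    g = nx.DiGraph()
    ids = {s.signal_id for s in signals}
    for s in signals:
        g.add_node(s.signal_id, n_spikes=int(s.n_spikes))
    for c in couplings:
        if c.target_kind != "signal":
            continue
        if c.reference_id not in ids or c.target_id not in ids:
            raise ValueError(
                f"coupling {c.reference_id}->{c.target_id} references a signal "
                f"not in the signal list"
            )
        if c.reference_id == c.target_id:
            raise ValueError(f"self-coupling on {c.reference_id}")
        g.add_edge(
            c.reference_id,
            c.target_id,
            probability=float(c.coupling_probability),
            latency_ms=float(c.mean_latency_ms),
        )
    return ConnectivityGraph(g, condition_label)


def match_signals(
    signals_a: Sequence[PropagationSignal],
    signals_b: Sequence[PropagationSignal],
    min_shared: int = 2,
    delay_tol_ms: float = 0.2,
) -> dict[str, str]:
    """Identify signals across two recordings of the same culture.

    A signal in B matches a signal in A when their electrode cohorts share
    ≥ ``min_shared`` electrodes with delay profiles agreeing within
    ``delay_tol_ms`` after offsetting.  Ambiguous matches raise an error
    listing the candidates; unmatched signals stay as new nodes.
    Returns a mapping B-id → A-id.
    """
    mapping: dict[str, str] = {}
    for sb in signals_b:
        candidates = []
        for sa in signals_a:
            common = set(sb.electrode_labels) & set(sa.electrode_labels)
            if len(common) < min_shared:
                continue
            offs = [sb.delay_of(e) - sa.delay_of(e) for e in common]
            if max(offs) - min(offs) <= delay_tol_ms:
                candidates.append(sa.signal_id)
        if len(candidates) > 1:
            raise ValueError(
                f"ambiguous match for {sb.signal_id}: candidates {candidates}"
            )
        if candidates:
            mapping[sb.signal_id] = candidates[0]
    return mapping


def diff_graphs(
    a: ConnectivityGraph,
    b: ConnectivityGraph,
    node_matching: Mapping[str, str] | None = None,
) -> GraphDiff:
    """Partition the union of edge sets into retained / lost / gained.

    ``node_matching`` maps B's node ids onto A's namespace (identity for
    ids not listed); edges are compared in A's namespace.
    """
    matching = dict(node_matching or {})
    edges_a = a.edges
    edges_b = {
        (matching.get(u, u), matching.get(v, v)) for u, v in b.edges
    }
    retained = frozenset(edges_a & edges_b)
    lost = frozenset(edges_a - edges_b)
    gained = frozenset(edges_b - edges_a)
    return GraphDiff(retained, lost, gained)


# ---------------------------------------------------------------------------
# persistence


def save_edge_list(g: ConnectivityGraph, path: str | Path) -> None:
    rows = [
        {
            "source": u,
            "target": v,
            "probability": d.get("probability", float("nan")),
            "latency_ms": d.get("latency_ms", float("nan")),
        }
        for u, v, d in g.graph.edges(data=True)
    ]
    df = pd.DataFrame(rows, columns=["source", "target", "probability", "latency_ms"])
    df.to_csv(path, index=False)


def load_edge_list(
    path: str | Path, nodes: Sequence[str] | None = None, condition_label: str = ""
) -> ConnectivityGraph:
    df = pd.read_csv(path)
    g = nx.DiGraph()
    for n in nodes or []:
        g.add_node(n)
    for row in df.itertuples(index=False):
        g.add_edge(
            str(row.source), str(row.target),
            probability=float(row.probability), latency_ms=float(row.latency_ms),
        )
    return ConnectivityGraph(g, condition_label)


def save_graphml(g: ConnectivityGraph, path: str | Path) -> None:
    out = g.graph.copy()
    out.graph["condition_label"] = g.condition_label
    nx.write_graphml(out, path)


def load_graphml(path: str | Path) -> ConnectivityGraph:
    g = nx.read_graphml(path)
    return ConnectivityGraph(nx.DiGraph(g), str(g.graph.get("condition_label", "")))
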