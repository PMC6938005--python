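"""Transition-graph summaries of clusters.

Each cluster of trajectories is condensed into a directed graph: nodes
are the state symbols seen in the cluster, and an edge A -> B summarizes
all observed A-to-B switches by (i) the median time between those two
states and (ii) the empirical switch probability — the number of A -> B
switches divided by the total number of transitions in the cluster, so
edge probabilities over the whole graph sum to 1.  The probability also
sets an edge's grey shade in DOT output (frequent switches draw darker).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pe import PESequence


@dataclass(frozen=True)
class GraphEdge:
    source: str
    target: str
    count: int
    probability: float
    median_time: float
    times: tuple[float, ...]


@dataclass(frozen=True)
class TransitionGraph:
    nodes: tuple[str, ...]
    edges: tuple[GraphEdge, ...]

    def edge(self, source: str, target: str) -> GraphEdge:
        for e in self.edges:
            if e.source == source and e.target == target:
                return e
        raise KeyError(f"no edge {source}->{target}")


def shade(probability: float) -> float:
    """Grey level in [0, 1] for an edge: 0.9 (near white) as p -> 0,
    0.0 (black) at p = 1, linear in between."""
    return 0.9 * (1.0 - probability)


def build_graph(cluster_sequences: list[PESequence]) -> TransitionGraph:
    """Summarize a cluster's switches into a TransitionGraph.

    Every consecutive event pair (s_i, s_{i+1}) contributes its
    inter-event duration to the edge s_i -> s_{i+1}.  Single-event
    sequences carry no transition and are skipped.  Self-loops (possible
    in generic data, not in switch-only trajectories) are supported.
    """
    if not cluster_sequences:
        raise ValueError("empty cluster")
    times: dict[tuple[str, str], list[float]] = {}
    nodes: list[str] = []
    for seq in cluster_sequences:
        if len(seq) < 2:
            continue
        for prev, cur in zip(seq.events, seq.events[1:]):
            key = (prev.symbol, cur.symbol)
            times.setdefault(key, []).append(cur.preceding_duration)
            for s in key:
                if s not in nodes:
                    nodes.append(s)
    total = sum(len(v) for v in times.values())
    edges = tuple(
        GraphEdge(src, dst, len(ts), len(ts) / total, float(np.median(ts)), tuple(ts))
        for (src, dst), ts in times.items()
    )
    return TransitionGraph(tuple(nodes), edges)


def _grey_hex(level: float) -> str:
    v = int(round(level * 255))
    return f"#{v:02x}{v:02x}{v:02x}"


def to_dot(g: TransitionGraph) -> str:
    lines = ["digraph cluster {", "  rankdir=LR;"]
    for node in g.nodes:
        lines.append(f'  "{node}";')
    for e in g.edges:
        col = _grey_hex(shade(e.probability))
        lines.append(
            f'  "{e.source}" -> "{e.target}" '
            f'[label="{e.median_time:g}", color="{col}", '
            f'penwidth={1 + 3 * e.probability:.2f}, '
            f'tooltip="p={e.probability:.3f}"];'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"


def to_edge_table(g: TransitionGraph) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"from": e.source, "to": e.target, "count": e.count,
             "probability": e.probability, "median_time": e.median_time}
            for e in g.edges
        ]
    )


def export_graph(g: TransitionGraph, path, format: str = "DOT") -> None:
    """Write the graph as DOT, GraphML or a CSV edge table."""
    fmt = format.upper()
    if fmt == "DOT":
        with open(path, "w") as fh:
            fh.write(to_dot(g))
    elif fmt == "GRAPHML":
        import networkx as nx

        G = nx.DiGraph()
        G.add_nodes_from(g.nodes)
        for e in g.edges:
            G.add_edge(e.source, e.target, count=e.count,
                       probability=e.probability, median_time=e.median_time,
                       shade=shade(e.probability))
        nx.write_graphml(G, path)
    elif fmt == "CSV":
        to_edge_table(g).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def import_edge_table(path) -> TransitionGraph:
    """Rebuild a graph from a CSV edge table (median times survive; the
    raw per-switch durations do not)."""
    df = pd.read_csv(path)
    nodes: list[str] = []
    edges = []
    for _, row in df.iterrows():
        for s in (row["from"], row["to"]):
            if s not in nodes:
                nodes.append(str(s))
        edges.append(
            GraphEdge(str(row["from"]), str(row["to"]), int(row["count"]),
                      float(row["probability"]), float(row["median_time"]), ())
        )
    return TransitionGraph(tuple(nodes), tuple(edges))
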