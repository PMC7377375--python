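"""Directed word graphs and their connectedness measures.

A transcript (or any token slice) maps to a directed graph with one node per
distinct word and one edge per observed word-to-word transition.  Repeated
transitions collapse to a single edge; immediate word repetition yields a
self-loop; transitions are never created across paragraph breaks.

Three connectedness measures are computed:

- ``edges``: number of distinct directed edges;
- ``lcc``: node count of the largest weakly connected component
  (reachability ignoring edge direction);
- ``lsc``: node count of the largest strongly connected component
  (mutual reachability respecting direction; an isolated node counts as 1).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx


@dataclass(frozen=True)
class GraphMeasures:
    n_nodes: int
    edges: int
    lcc: int
    lsc: int

    def to_dict(self) -> dict:
        return asdict(self)


def build_graph(
    tokens: Sequence[str], break_positions: Iterable[int] = ()
) -> nx.DiGraph:
    """Build the directed word graph of a token sequence.

    ``break_positions`` holds indices ``i`` for which the transition
    ``tokens[i] -> tokens[i+1]`` is suppressed (paragraph boundaries).
    A single token yields a valid one-node, zero-edge graph.
    """
    if not tokens:
        raise ValueError("cannot build a word graph from an empty token sequence")
    g = nx.DiGraph()
    g.add_nodes_from(tokens)
    breaks = set(break_positions)
    g.add_edges_from(
        (tokens[i], tokens[i + 1])
        for i in range(len(tokens) - 1)
        if i not in breaks
    )
    return g


def graph_measures(g: nx.DiGraph) -> GraphMeasures:
    """Connectedness measures of a directed word graph."""
    if g.number_of_nodes() == 0:
        raise ValueError("graph has no nodes")
    lcc = max(len(c) for c in nx.weakly_connected_components(g))
    lsc = max(len(c) for c in nx.strongly_connected_components(g))
    return GraphMeasures(
        n_nodes=g.number_of_nodes(),
        edges=g.number_of_edges(),
        lcc=lcc,
        lsc=lsc,
    )


def write_edgelist(g: nx.DiGraph, path: str | Path) -> None:
    """Export a graph as tab-separated ``source<TAB>target`` lines."""
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in g.edges():
            fh.write(f"{a}\t{b}\n")


def write_measures_json(measures: GraphMeasures, path: str | Path) -> None:
    Path(path).write_text(json.dumps(measures.to_dict(), sort_keys=True) + "\n")
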