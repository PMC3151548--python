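"""Shortest non-covalent communication paths over protein structure networks.

Paths between two residues of interest are found per frame with Dijkstra's
algorithm over the PSN edge set.  Edges cost one hop by default, so
"shortest" counts nodes, and all tied shortest paths are enumerated; a
strength-weighted mode (cost = 1 / I_ij) is available as an extension.
Candidate paths are then filtered by motion correlation — a path is kept
only if at least one internal residue is correlated (DCC or LMI, whole-
trajectory statistic) with either endpoint above a cutoff — and ranked by
frequency: the fraction of frames whose PSN contains every edge of the path.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .corr import CorrelationMatrix
from .errors import TrajscopeError
from .psn import PSNGraph


@dataclass
class PathConfig:
    i_min: float = 0.0
    corr_cutoff: float = 0.0
    min_length: int = 2          # nodes, endpoints included
    min_frequency: float = 0.0
    corr_source: str = "LMI"     # "DCC" | "LMI"
    weighted: bool = False       # cost = 1/I_ij extension
    keep_two_node_paths: bool = False


@dataclass
class Path:
    nodes: tuple[int, ...]
    frequency: float = 0.0

    @property
    def length(self) -> int:
        return len(self.nodes)

    def canonical(self) -> tuple[int, ...]:
        """Direction-independent identity: a path equals its reversal."""
        rev = tuple(reversed(self.nodes))
        return min(self.nodes, rev)


def shortest_paths(graph: PSNGraph, source: int, target: int,
                   weighted: bool = False) -> list[tuple[int, ...]]:
    """All tied shortest paths between two nodes of one frame's PSN.

    Returns an empty list when the endpoints are disconnected.
    """
    if source == target:
        raise TrajscopeError("source and target must differ")
    if not (0 <= source < graph.n_nodes and 0 <= target < graph.n_nodes):
        raise TrajscopeError("endpoint is not a node of the graph")
    g = graph.to_networkx()
    if weighted:
        for _, _, data in g.edges(data=True):
            data["cost"] = 1.0 / data["weight"] if data["weight"] > 0 else np.inf
        weight = "cost"
    else:
        weight = None
    try:
        return [tuple(p) for p in
                nx.all_shortest_paths(g, source, target, weight=weight)]
    except nx.NetworkXNoPath:
        return []


def correlation_filter(paths: list[tuple[int, ...]], corr: CorrelationMatrix,
                       cutoff: float,
                       keep_two_node_paths: bool = False) -> list[tuple[int, ...]]:
    """Keep paths with an internal residue correlated with an endpoint.

    A path survives iff some internal node's correlation with the first OR
    last node is >= cutoff.  Two-node paths have no interior and are dropped
    unless ``keep_two_node_paths`` waives the rule.
    """
    values = corr.values
    kept = []
    for p in paths:
        for node in p:
            if node >= values.shape[0]:
                raise TrajscopeError(
                    f"correlation matrix has no entry for path node {node}")
        interior = p[1:-1]
        if not interior:
            if keep_two_node_paths:
                kept.append(p)
            continue
        first, last = p[0], p[-1]
        if any(values[m, first] >= cutoff or values[m, last] >= cutoff
               for m in interior):
            kept.append(p)
    return kept


def _contains_path(graph: PSNGraph, nodes: tuple[int, ...]) -> bool:
    return all((min(a, b), max(a, b)) in graph.edges
               for a, b in zip(nodes, nodes[1:]))


def path_frequencies(frame_graphs: list[PSNGraph], source: int, target: int,
                     corr: CorrelationMatrix | None = None,
                     config: PathConfig | None = None) -> list[Path]:
    """Ranked communication paths between two residues over a trajectory.

    Candidates are the union over frames of all tied shortest paths; each
    candidate's frequency is the fraction of frames whose PSN contains all
    of its edges (node-sequence identity up to reversal).  The correlation
    filter and the minimum length / frequency cuts are applied before
    ranking by descending frequency.
    """
    if not frame_graphs:
        raise TrajscopeError("need at least one frame graph")
    config = config or PathConfig()
    candidates: dict[tuple[int, ...], tuple[int, ...]] = {}
    for graph in frame_graphs:
        for p in shortest_paths(graph, source, target, config.weighted):
            candidates.setdefault(Path(p).canonical(), p)
    paths = list(candidates.values())
    if corr is not None:
        paths = correlation_filter(paths, corr, config.corr_cutoff,
                                   config.keep_two_node_paths)
    n_frames = len(frame_graphs)
    out = []
    for p in paths:
        if len(p) < config.min_length:
            continue
        freq = sum(_contains_path(g, p) for g in frame_graphs) / n_frames
        if freq >= config.min_frequency:
            out.append(Path(tuple(p), freq))
    out.sort(key=lambda path: (-path.frequency, path.length, path.nodes))
    return out
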