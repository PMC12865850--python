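"""Graph-based toxicity-penalty metrics on a protein-protein interaction network.

Average shortest-path distance between two drugs' target sets (unit edge
weights, so Dijkstra reduces to breadth-first distances) and the Jaccard
overlap of two-hop target neighborhoods.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Set

import networkx as nx

logger = logging.getLogger(__name__)

#: sentinel for "no path exists"
UNREACHABLE = math.inf


@dataclass
class InteractionNetwork:
    """Undirected simple protein graph plus an external-ID -> node mapping.

    ``id_map`` projects UniProt accessions onto graph node IDs; accessions
    without a mapping (or mapping to nodes absent from the graph) simply
    contribute nothing to the metrics, with counts surfaced by the loaders.
    """

    graph: nx.Graph
    id_map: dict[str, str] = field(default_factory=dict)

    def project(self, proteins: Set[str]) -> frozenset[str]:
        """Map protein IDs to graph nodes, dropping unmappable/absent ones."""
        nodes = set()
        for p in proteins:
            node = self.id_map.get(p)
            if node is not None and node in self.graph:
                nodes.add(node)
        return frozenset(nodes)


def shortest_path_length(network: InteractionNetwork, u: str, v: str) -> float:
    """Minimum hop count between nodes u and v; UNREACHABLE if no path.

    Nodes absent from the graph also yield UNREACHABLE (with a warning)
    rather than an exception, so bulk pair loops degrade gracefully.
    """
    g = network.graph
    if u not in g or v not in g:
        logger.warning("node %r or %r absent from graph", u, v)
        return UNREACHABLE
    try:
        return float(nx.shortest_path_length(g, u, v))
    except nx.NetworkXNoPath:
        return UNREACHABLE


def _multi_source_distances(g: nx.Graph, sources: frozenset[str]) -> dict[str, dict[str, int]]:
    return {s: nx.single_source_shortest_path_length(g, s) for s in sorted(sources)}


def avg_target_distance(
    targets_a: Set[str],
    targets_b: Set[str],
    network: InteractionNetwork,
    unreachable: str = "exclude",
) -> Optional[float]:
    """Mean shortest-path distance over the cross product of mapped targets.

    ``unreachable`` policy: "exclude" drops disconnected/unmappable pairs
    from the average (default; an imputation constant would dominate the
    mean), or "impute:<value>" substitutes a fixed distance. Returns None
    (absent) when no pair contributes.
    """
    na = network.project(targets_a)
    nb = network.project(targets_b)
    if not na or not nb:
        return None
    impute_val: Optional[float] = None
    if unreachable.startswith("impute:"):
        impute_val = float(unreachable.split(":", 1)[1])
    elif unreachable != "exclude":
        raise ValueError(f"unknown unreachable policy: {unreachable!r}")

    dists = _multi_source_distances(network.graph, na)
    total, count = 0.0, 0
    for a in sorted(na):
        da = dists[a]
        for b in sorted(nb):
            d = da.get(b)
            if d is None:
                if impute_val is not None:
                    total += impute_val
                    count += 1
            else:
                total += d
                count += 1
    if count == 0:
        return None
    return total / count


def k_hop_neighborhood(targets: Set[str], network: InteractionNetwork, k: int) -> frozenset[str]:
    """All nodes within k hops of any mapped target, the targets included.

    k = 0 returns the mapped target nodes themselves; unmappable targets
    contribute nothing.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    nodes = network.project(targets)
    if k == 0:
        return nodes
    out: set[str] = set()
    for t in sorted(nodes):
        out.update(nx.single_source_shortest_path_length(network.graph, t, cutoff=k))
    return frozenset(out)


def neighbor_jaccard(
    targets_a: Set[str],
    targets_b: Set[str],
    network: InteractionNetwork,
    k: int = 2,
) -> Optional[float]:
    """Jaccard overlap of the two drugs' k-hop target neighborhoods; None if either is empty."""
    na = k_hop_neighborhood(targets_a, network, k)
    nb = k_hop_neighborhood(targets_b, network, k)
    if not na or not nb:
        return None
    return len(na & nb) / len(na | nb)
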