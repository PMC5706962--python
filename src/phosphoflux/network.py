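"""Density-based clustering of hits on a weighted protein-interaction network.

Implements greedy cohesiveness-driven cluster growth in the style of
ClusterONE: the cohesiveness of a candidate group is

    w_in / (w_in + w_bound + penalty_term)

where ``w_in`` sums edge weights inside the group, ``w_bound`` sums weights
of edges crossing the boundary, and the penalty term models interactions
missed by the screen.  :func:`cohesiveness` takes the penalty term as an
additive value; :func:`find_clusters` follows ClusterONE in scaling it with
cluster size (``penalty`` per member, default 2), which is what stops greedy
growth from absorbing weakly attached peripheral nodes.  Clusters are grown
from high-degree seeds by the single add/remove move that most increases
cohesiveness, filtered by size and density, and overlapping clusters are
merged.  Determinism is guaranteed by a lexicographic tie-break on node
identifiers.

Edge lists are read from 2- or 3-column TSV files (STRING exports work
directly; combined scores on the 0-1000 scale are rescaled to (0, 1]).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .errors import EmptyInputError, SchemaError

logger = logging.getLogger(__name__)

__all__ = [
    "Cluster",
    "read_edge_list",
    "network_from_edges",
    "cohesiveness",
    "find_clusters",
    "write_clusters",
]


@dataclass
class Cluster:
    """A candidate protein complex: member set plus its cohesiveness terms."""

    members: frozenset[str]
    cohesiveness: float
    internal_weight: float
    boundary_weight: float

    def __len__(self) -> int:
        return len(self.members)


def read_edge_list(path, sep: str = "\t") -> nx.Graph:
    """Read a weighted undirected edge list into a networkx graph.

    Accepts two columns (weight defaults to 1.0) or three.  Node identifiers
    are upper-cased, duplicate edges keep the maximum weight, self-loops are
    dropped with a warning, and STRING-style integer scores (max > 1) are
    rescaled by 1/1000 into (0, 1].
    """
    table = pd.read_csv(path, sep=sep, header=None, comment="#", dtype=str)
    if table.shape[1] == 2:
        table[2] = "1.0"
    elif table.shape[1] < 2:
        raise SchemaError(f"edge list {path} needs at least two columns")
    # tolerate a header row on STRING exports
    first = table.iloc[0, 2]
    try:
        float(first)
    except (TypeError, ValueError):
        table = table.iloc[1:]
    try:
        weights = table[2].astype(float)
    except ValueError as exc:
        raise SchemaError(f"malformed weight in edge list {path}: {exc}") from exc
    if weights.max() > 1.0:
        weights = weights / 1000.0
    g = nx.Graph()
    for (a, b, _), w in zip(table.itertuples(index=False), weights):
        a, b = str(a).upper(), str(b).upper()
        if a == b:
            logger.warning("dropping self-loop on %s", a)
            continue
        if w <= 0:
            raise SchemaError(f"non-positive edge weight {w} on {a}-{b}")
        if g.has_edge(a, b):
            g[a][b]["weight"] = max(g[a][b]["weight"], float(w))
        else:
            g.add_edge(a, b, weight=float(w))
    return g


def network_from_edges(edges: pd.DataFrame) -> nx.Graph:
    """Build a graph from a (node_a, node_b, weight) DataFrame."""
    g = nx.Graph()
    for a, b, w in edges.itertuples(index=False):
        a, b = str(a).upper(), str(b).upper()
        if a == b:
            continue
        if g.has_edge(a, b):
            g[a][b]["weight"] = max(g[a][b]["weight"], float(w))
        else:
            g.add_edge(a, b, weight=float(w))
    return g


def _weights(graph: nx.Graph, members: set[str]) -> tuple[float, float]:
    w_in = 0.0
    w_bound = 0.0
    for node in members:
        for nbr, data in graph[node].items():
            w = data.get("weight", 1.0)
            if nbr in members:
                w_in += 0.5 * w  # each internal edge visited from both ends
            else:
                w_bound += w
    return w_in, w_bound


def cohesiveness(members, graph: nx.Graph, penalty: float = 2.0) -> float:
    """Cohesiveness w_in / (w_in + w_bound + penalty) of a member set.

    ``penalty`` is the additive penalty term itself (pass ``rate *
    len(members)`` for the ClusterONE size-scaled form used during growth).
    """
    members = set(members)
    if not members:
        raise EmptyInputError("cohesiveness of an empty member set is undefined")
    w_in, w_bound = _weights(graph, members)
    denom = w_in + w_bound + penalty
    return w_in / denom if denom > 0 else 0.0


def _grow(graph: nx.Graph, seed: str, penalty_rate: float) -> set[str]:
    """Greedy local optimisation of size-penalised cohesiveness from a seed."""

    def score_of(m: set[str]) -> float:
        return cohesiveness(m, graph, penalty_rate * len(m))

    members = {seed}
    current = score_of(members)
    while True:
        best_score, best_move = current, None
        # candidate additions: external neighbours of the cluster
        frontier = sorted(
            {n for m in members for n in graph[m] if n not in members}
        )
        for node in frontier:
            score = score_of(members | {node})
            if score > best_score:
                best_score, best_move = score, ("add", node)
        if len(members) > 1:
            for node in sorted(members):
                score = score_of(members - {node})
                if score > best_score:
                    best_score, best_move = score, ("remove", node)
        if best_move is None:
            return members
        op, node = best_move
        members = members | {node} if op == "add" else members - {node}
        current = best_score


def _density(graph: nx.Graph, members: set[str]) -> float:
    n = len(members)
    if n < 2:
        return 0.0
    w_in, _ = _weights(graph, members)
    return 2.0 * w_in / (n * (n - 1))


def _overlap(a: frozenset, b: frozenset) -> float:
    inter = len(a & b)
    return inter * inter / (len(a) * len(b))


def find_clusters(
    graph: nx.Graph,
    penalty: float = 2.0,
    min_size: int = 3,
    min_density: float = 0.3,
    overlap_merge: float = 0.8,
    seed_order=None,
) -> list[Cluster]:
    """Find densely connected clusters by greedy cohesiveness growth.

    ``penalty`` is the per-member penalty rate; a candidate group of size n
    is scored with penalty term ``penalty * n``.  Seeds are taken in
    descending weighted-degree order (ties broken by node identifier) among
    nodes not yet claimed by an earlier cluster; each seed is grown to a
    local optimum of size-penalised cohesiveness by single add/remove
    moves.  Groups smaller than ``min_size`` or with weighted edge density
    below ``min_density`` are discarded; cluster pairs with overlap score
    ``|A∩B|² / (|A|·|B|) >= overlap_merge`` are merged transitively.
    Deterministic for a fixed graph.
    """
    if graph.number_of_nodes() == 0:
        return []
    if seed_order is None:
        degree = dict(graph.degree(weight="weight"))
        seed_order = sorted(graph.nodes, key=lambda n: (-degree[n], n))
    claimed: set[str] = set()
    raw: list[set[str]] = []
    for seed in seed_order:
        if seed in claimed:
            continue
        members = _grow(graph, seed, penalty)
        claimed |= members
        if len(members) >= min_size and _density(graph, members) >= min_density:
            raw.append(members)

    # transitive merge of heavily overlapping clusters
    merged = [frozenset(m) for m in raw]
    changed = True
    while changed:
        changed = False
        for i in range(len(merged)):
            for j in range(i + 1, len(merged)):
                if _overlap(merged[i], merged[j]) >= overlap_merge:
                    merged[i] = merged[i] | merged[j]
                    del merged[j]
                    changed = True
                    break
            if changed:
                break

    clusters = []
    for members in merged:
        w_in, w_bound = _weights(graph, set(members))
        denom = w_in + w_bound + penalty * len(members)
        clusters.append(
            Cluster(
                members=members,
                cohesiveness=w_in / denom if denom > 0 else 0.0,
                internal_weight=w_in,
                boundary_weight=w_bound,
            )
        )
    clusters.sort(key=lambda c: (-c.cohesiveness, sorted(c.members)))
    return clusters


def write_clusters(clusters: list[Cluster], path, graphml_path=None, graph=None) -> None:
    """Write clusters as long-format TSV (cluster_id, member, cohesiveness).

    Optionally also writes a GraphML file annotating each node of ``graph``
    with its cluster id, for visualization tools.
    """
    rows = [
        {"cluster_id": i, "member": m, "cohesiveness": c.cohesiveness}
        for i, c in enumerate(clusters, start=1)
        for m in sorted(c.members)
    ]
    pd.DataFrame(rows, columns=["cluster_id", "member", "cohesiveness"]).to_csv(
        path, sep="\t", index=False
    )
    if graphml_path is not None and graph is not None:
        annotated = graph.copy()
        assignment: dict[str, int] = {}
        for i, c in enumerate(clusters, start=1):
            for m in c.members:
                assignment.setdefault(m, i)
        nx.set_node_attributes(
            annotated, {n: assignment.get(n, 0) for n in annotated.nodes}, "cluster"
        )
        nx.write_graphml(annotated, graphml_path)
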