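#!/usr/bin/env python
"""Cluster the simulated interaction network by cohesiveness growth.

Finds densely connected groups with the ClusterONE-style greedy grower and
scores them against the planted complexes written by 01_simulate_inputs.
Outputs results/clusters.tsv.
"""

import argparse
import json
from pathlib import Path

from phosphoflux import network as net


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--edges", type=Path, default=Path("results/data/network.tsv"))
    parser.add_argument(
        "--planted", type=Path, default=Path("results/data/planted_clusters.json")
    )
    parser.add_argument("--out", type=Path, default=Path("results/clusters.tsv"))
    args = parser.parse_args()

    graph = net.read_edge_list(args.edges)
    clusters = net.find_clusters(graph)
    net.write_clusters(clusters, args.out)
    print(f"{graph.number_of_nodes()} nodes, {graph.number_of_edges()} edges")
    for i, c in enumerate(clusters, 1):
        print(f"  cluster {i}: {len(c.members)} members, cohesiveness {c.cohesiveness:.3f}")

    if args.planted.exists():
        planted = [frozenset(m) for m in json.loads(args.planted.read_text())]
        for i, p in enumerate(planted, 1):
            best = max(
                (len(p & c.members) / len(p | c.members) for c in clusters), default=0.0
            )
            print(f"planted complex {i}: best Jaccard {best:.3f}")


if __name__ == "__main__":
    main()
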