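"""Minimum spanning forest over the candidate-edge graph.

Kruskal's algorithm over a union-by-rank/path-compressed disjoint set; the
edge stream must already be sorted by weight (the accumulator emits it that
way).  Every connected component becomes a tree rooted at its
smallest-index read, with edges oriented away from the root so each child
carries the alignment record against its parent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .graph import Edge

__all__ = ["DisjointSet", "Forest", "kruskal_msf"]

ROOT = -1


class DisjointSet:
    """Union-find with union by rank and path compression."""

    def __init__(self, n: int):
        self.parent = list(range(n))
        self.rank = [0] * n
        self.n_components = n

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        if self.rank[ra] < self.rank[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        if self.rank[ra] == self.rank[rb]:
            self.rank[ra] += 1
        self.n_components -= 1
        return True


@dataclass
class Forest:
    """MSF as parent/children arrays with per-edge alignment records.

    ``parent_of[i]`` is the parent read index or -1 for roots; ``edge_of[i]``
    is the Edge linking i to its parent (None for roots).
    """

    parent_of: np.ndarray
    edge_of: list[Optional[Edge]]
    children: list[list[int]]
    roots: list[int]
    total_weight: int

    @property
    def n_nodes(self) -> int:
        return len(self.edge_of)

    @property
    def n_edges(self) -> int:
        return self.n_nodes - len(self.roots)

    def is_singleton(self, i: int) -> bool:
        """A read isolated in the forest: its own root with no children."""
        return self.parent_of[i] == ROOT and not self.children[i]


def kruskal_msf(num_nodes: int, edges: Sequence[Edge]) -> Forest:
    """Build the minimum spanning forest from a weight-sorted edge stream.

    Nodes untouched by any accepted edge become singleton roots.  Raises if
    the stream is not nondecreasing in weight (the caller's contract).
    """
    dsu = DisjointSet(num_nodes)
    adjacency: list[list[tuple[int, Edge]]] = [[] for _ in range(num_nodes)]
    total_weight = 0
    last_w = -1
    n_accepted = 0
    for edge in edges:
        w = edge.weight
        if w < last_w:
            raise ValueError(
                f"edge stream out of order: weight {w} after {last_w}"
            )
        last_w = w
        if dsu.union(edge.u, edge.v):
            adjacency[edge.u].append((edge.v, edge))
            adjacency[edge.v].append((edge.u, edge))
            total_weight += w
            n_accepted += 1

    parent_of = np.full(num_nodes, ROOT, dtype=np.int64)
    edge_of: list[Optional[Edge]] = [None] * num_nodes
    children: list[list[int]] = [[] for _ in range(num_nodes)]
    roots: list[int] = []
    visited = np.zeros(num_nodes, dtype=bool)

    for start in range(num_nodes):  # smallest index in a component is root
        if visited[start]:
            continue
        roots.append(start)
        visited[start] = True
        stack = [start]
        while stack:
            node = stack.pop()
            for other, edge in adjacency[node]:
                if visited[other]:
                    continue
                visited[other] = True
                parent_of[other] = node
                edge_of[other] = edge
                children[node].append(other)
                stack.append(other)

    for kids in children:
        kids.sort()

    return Forest(
        parent_of=parent_of,
        edge_of=edge_of,
        children=children,
        roots=roots,
        total_weight=total_weight,
    )
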