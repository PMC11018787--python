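"""Minimum spanning haplotype networks over major gcHaps.

Edge weights are mutation counts (Hamming distances between allele
vectors).  Edges are added greedily in ascending distance order
(Kruskal), so the most closely related haplotypes are connected first;
besides the minimum spanning tree, every non-tree edge whose length
equals the largest tree edge on the path between its endpoints is kept
as an alternative connection (minimum-spanning-network convention).
All tie-breaks are deterministic, so the network is byte-identical
across runs on the same input.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx

from .gchap_core import GcHap

__all__ = ["Edge", "HapNetwork", "hamming", "build_msn"]


@dataclass(frozen=True)
class Edge:
    hap_a: str
    hap_b: str
    mutations: int
    in_mst: bool


@dataclass(frozen=True)
class HapNetwork:
    nodes: tuple[GcHap, ...]
    edges: tuple[Edge, ...]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for h in self.nodes:
            g.add_node(h.hap_name, count=h.count, alleles=h.allele_string)
        for e in self.edges:
            g.add_edge(e.hap_a, e.hap_b, mutations=e.mutations, in_mst=e.in_mst)
        return g

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), str(path))

    def write_edges_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("hap_a\thap_b\tmutations\tin_mst\n")
            for e in self.edges:
                fh.write(
                    f"{e.hap_a}\t{e.hap_b}\t{e.mutations}\t"
                    f"{str(e.in_mst).lower()}\n"
                )

    @property
    def mst_weight(self) -> int:
        return sum(e.mutations for e in self.edges if e.in_mst)


def hamming(hap_a: Sequence[int], hap_b: Sequence[int]) -> int:
    """Number of positions at which two allele vectors differ."""
    if len(hap_a) != len(hap_b):
        raise ValueError(
            f"length mismatch: {len(hap_a)} vs {len(hap_b)}"
        )
    return sum(1 for x, y in zip(hap_a, hap_b) if x != y)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> bool:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return False
        self.parent[rj] = ri
        return True


def build_msn(
    major: Sequence[GcHap], max_distance: int | None = None
) -> HapNetwork:
    """Build the minimum spanning network over major haplotypes.

    Kruskal tie-breaks: shorter distance first, then larger combined
    carrier count, then Hap-name (input) order.  ``max_distance``, when
    given, severs every edge longer than the limit, emulating a
    connection cutoff; this may disconnect the network.
    """
    haps = list(major)
    if not haps:
        raise ValueError("need at least one haplotype")
    n = len(haps)
    if len({h.alleles for h in haps}) != n:
        raise ValueError("duplicate haplotypes (distance 0) are not allowed")

    cand = []
    for i in range(n):
        for j in range(i + 1, n):
            d = hamming(haps[i].alleles, haps[j].alleles)
            cand.append((d, -(haps[i].count + haps[j].count), i, j))
    cand.sort()

    uf = _UnionFind(n)
    mst_pairs: set[tuple[int, int]] = set()
    tree = nx.Graph()
    tree.add_nodes_from(range(n))
    for d, _negw, i, j in cand:
        if uf.union(i, j):
            mst_pairs.add((i, j))
            tree.add_edge(i, j, weight=d)

    edges: list[Edge] = []
    for d, _negw, i, j in cand:
        if (i, j) in mst_pairs:
            in_mst = True
        else:
            # keep the alternative connection iff it is as short as the
            # longest tree edge on the i-j path (equal-length detour)
            path = nx.shortest_path(tree, i, j)
            path_max = max(
                tree[u][v]["weight"] for u, v in zip(path, path[1:])
            )
            if d != path_max:
                continue
            in_mst = False
        if max_distance is not None and d > max_distance:
            continue
        edges.append(Edge(haps[i].hap_name, haps[j].hap_name, d, in_mst))
    return HapNetwork(tuple(haps), tuple(edges))
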