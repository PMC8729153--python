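"""Bipartite graph construction and h-hop enclosing-subgraph extraction.

A candidate pair (l, d) is judged from the local neighbourhood around the
two target nodes: the enclosing subgraph contains the targets plus every
node whose minimum BFS distance to either target is at most h, with the
induced edges. Node roles are encoded as integer labels: 0 for the target
lncRNA, 1 for the target disease, 2i for an i-hop lncRNA neighbour and
2i + 1 for an i-hop disease neighbour.

By default the target edge itself (when present) is removed before BFS and
excluded from the induced edges, so that the class label never leaks into
the classifier input.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .data_io import AssociationMatrix

__all__ = [
    "BipartiteGraph",
    "EnclosingSubgraph",
    "build_bipartite_graph",
    "extract_enclosing_subgraph",
    "label_nodes",
]

LNCRNA = "l"
DISEASE = "d"


@dataclass
class BipartiteGraph:
    """lncRNA-disease bipartite graph with adjacency sets both ways."""

    n_lncrnas: int
    n_diseases: int
    lnc_nbrs: list[set]  # lnc index -> set of disease indices
    dis_nbrs: list[set]  # disease index -> set of lnc indices

    @property
    def n_edges(self) -> int:
        return sum(len(s) for s in self.lnc_nbrs)

    def has_edge(self, l: int, d: int) -> bool:
        return d in self.lnc_nbrs[l]

    def copy(self) -> "BipartiteGraph":
        return BipartiteGraph(
            self.n_lncrnas,
            self.n_diseases,
            [set(s) for s in self.lnc_nbrs],
            [set(s) for s in self.dis_nbrs],
        )


@dataclass
class EnclosingSubgraph:
    """Labeled h-hop enclosing subgraph of one (lncRNA, disease) pair.

    ``nodes`` lists (partition, original index, hop, label); the two targets
    occupy local positions ``target_positions`` with labels 0 and 1. ``edges``
    are induced edges in local indices. ``y`` is the class (1 = known
    association, 0 = sampled negative), when assigned.
    """

    target_pair: tuple[int, int]
    h: int
    nodes: list[tuple]  # (partition, index, hop, label)
    edges: list[tuple[int, int]]
    target_positions: tuple[int, int] = (0, 1)
    y: int | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def node_set(self) -> set:
        return {(p, i) for p, i, _h, _lab in self.nodes}


def build_bipartite_graph(A: AssociationMatrix) -> BipartiteGraph:
    """Bipartite graph with one edge per known association."""
    lnc_nbrs = [set(np.flatnonzero(row).tolist()) for row in A.values]
    dis_nbrs = [set(np.flatnonzero(col).tolist()) for col in A.values.T]
    return BipartiteGraph(A.n_lncrnas, A.n_diseases, lnc_nbrs, dis_nbrs)


def _bfs_limited(G: BipartiteGraph, start: tuple, h: int, skip_edge=None) -> dict:
    """BFS distances (<= h) from ``start`` = (partition, index).

    ``skip_edge``: (l, d) pair whose edge is ignored in both directions.
    """
    dist = {start: 0}
    queue = deque([start])
    while queue:
        part, idx = node = queue.popleft()
        du = dist[node]
        if du == h:
            continue
        nbr_part = DISEASE if part == LNCRNA else LNCRNA
        nbrs = G.lnc_nbrs[idx] if part == LNCRNA else G.dis_nbrs[idx]
        for j in nbrs:
            if skip_edge is not None:
                l, d = skip_edge
                if (part == LNCRNA and idx == l and j == d) or (
                    part == DISEASE and idx == d and j == l
                ):
                    continue
            nxt = (nbr_part, j)
            if nxt not in dist:
                dist[nxt] = du + 1
                queue.append(nxt)
    return dist


def extract_enclosing_subgraph(
    G: BipartiteGraph,
    l: int,
    d: int,
    h: int = 1,
    remove_target_edge: bool = True,
) -> EnclosingSubgraph:
    """Extract the labeled h-hop enclosing subgraph of pair (l, d).

    The node set is {l, d} plus every node whose minimum BFS distance to
    either target is <= h; a node's hop is that minimum distance. With
    ``remove_target_edge`` the edge l-d (if present) is ignored during BFS
    and left out of the induced edges.
    """
    if h < 1:
        raise ValueError(f"hop count must be >= 1, got {h}")
    if not (0 <= l < G.n_lncrnas and 0 <= d < G.n_diseases):
        raise IndexError(f"pair ({l}, {d}) out of range")

    skip = (l, d) if remove_target_edge else None
    dist_l = _bfs_limited(G, (LNCRNA, l), h, skip_edge=skip)
    dist_d = _bfs_limited(G, (DISEASE, d), h, skip_edge=skip)

    hop: dict[tuple, int] = {}
    for node in set(dist_l) | set(dist_d):
        hop[node] = min(dist_l.get(node, h + 1), dist_d.get(node, h + 1))
    hop[(LNCRNA, l)] = 0
    hop[(DISEASE, d)] = 0
    members = {n for n, i in hop.items() if i <= h}
    members |= {(LNCRNA, l), (DISEASE, d)}

    # deterministic local order: targets first, then by (hop, partition, index)
    others = sorted(
        (n for n in members if n not in ((LNCRNA, l), (DISEASE, d))),
        key=lambda n: (hop[n], n[0], n[1]),
    )
    ordered = [(LNCRNA, l), (DISEASE, d)] + others
    local = {n: i for i, n in enumerate(ordered)}

    nodes = []
    for part, idx in ordered:
        i = hop[(part, idx)]
        if (part, idx) == (LNCRNA, l):
            label = 0
        elif (part, idx) == (DISEASE, d):
            label = 1
        else:
            label = 2 * i if part == LNCRNA else 2 * i + 1
        nodes.append((part, idx, i, label))

    edges = []
    for part, idx in ordered:
        if part != LNCRNA:
            continue
        for j in G.lnc_nbrs[idx]:
            if (DISEASE, j) not in local:
                continue
            if remove_target_edge and idx == l and j == d:
                continue
            edges.append((local[(LNCRNA, idx)], local[(DISEASE, j)]))
    edges.sort()

    return EnclosingSubgraph((l, d), h, nodes, edges, (local[(LNCRNA, l)], local[(DISEASE, d)]))


def label_nodes(sub: EnclosingSubgraph) -> list[int]:
    """Role labels: targets 0/1; i-hop neighbours 2i (lncRNA) / 2i+1 (disease)."""
    tl, td = sub.target_positions
    labels = []
    for pos, (part, _idx, hop, _lab) in enumerate(sub.nodes):
        if pos == tl:
            labels.append(0)
        elif pos == td:
            labels.append(1)
        elif hop is None:
            raise RuntimeError("node without hop assignment")
        else:
            labels.append(2 * hop if part == LNCRNA else 2 * hop + 1)
    return labels
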