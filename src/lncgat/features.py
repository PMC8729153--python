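"""Node attribute vectors for enclosing subgraphs.

Every node gets a fixed-length vector of dimension L + D + K: an lncRNA
node carries its lncRNA-similarity row in the first L positions (zeros in
the D disease positions); a disease node carries its disease-similarity row
in the middle D positions (zeros in the first L); the final K positions are
a one-hot code of the node's role label. K = 2h + 2 covers the label range
0..2h+1 of an h-hop subgraph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .similarity import SimilarityMatrix
from .subgraph import EnclosingSubgraph, LNCRNA

__all__ = ["AttributedSubgraph", "label_code_width", "build_node_vector", "attach_features"]


@dataclass
class AttributedSubgraph:
    """Enclosing subgraph plus its (n_nodes, L + D + K) attribute matrix."""

    sub: EnclosingSubgraph
    x: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.sub.n_nodes

    @property
    def edges(self):
        return self.sub.edges

    @property
    def target_positions(self):
        return self.sub.target_positions

    @property
    def y(self):
        return self.sub.y


def label_code_width(h: int) -> int:
    """One-hot width K = 2h + 2 (labels 0..2h+1 each get one bit)."""
    if h < 1:
        raise ValueError(f"hop count must be >= 1, got {h}")
    return 2 * h + 2


def build_node_vector(
    node: tuple,
    S_lnc: SimilarityMatrix,
    S_dis: SimilarityMatrix,
    K: int,
) -> np.ndarray:
    """Attribute vector [sim row | zero block | one-hot(label)] for one node.

    ``node`` is (partition, original index, label).
    """
    part, idx, label = node
    L, D = S_lnc.n, S_dis.n
    if not 0 <= label < K:
        raise ValueError(f"label {label} does not fit one-hot width K={K}")
    vec = np.zeros(L + D + K)
    if part == LNCRNA:
        vec[:L] = S_lnc.row(idx)
    else:
        vec[L : L + D] = S_dis.row(idx)
    vec[L + D + label] = 1.0
    return vec


def attach_features(
    sub: EnclosingSubgraph,
    S_lnc: SimilarityMatrix,
    S_dis: SimilarityMatrix,
    lncrna_ids: list[str] | None = None,
    disease_ids: list[str] | None = None,
) -> AttributedSubgraph:
    """Attach per-node attribute vectors to a subgraph.

    If the association-matrix id lists are supplied, similarity ids are
    checked against them position by position.
    """
    for want, sim, what in (
        (lncrna_ids, S_lnc, "lncRNA"),
        (disease_ids, S_dis, "disease"),
    ):
        if want is not None and list(want) != list(sim.ids):
            for a, b in zip(want, sim.ids):
                if a != b:
                    raise ValueError(
                        f"{what} similarity ids misaligned: expected {a!r}, got {b!r}"
                    )
            raise ValueError(f"{what} similarity id list has wrong length")

    K = label_code_width(sub.h)
    x = np.empty((sub.n_nodes, S_lnc.n + S_dis.n + K))
    for pos, (part, idx, _hop, label) in enumerate(sub.nodes):
        x[pos] = build_node_vector((part, idx, label), S_lnc, S_dis, K)
    return AttributedSubgraph(sub, x)
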