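"""lncRNA and disease similarity.

Two similarity notions feed the node features:

* **GIP kernel** (Gaussian interaction profile): for entities with binary
  interaction profiles ``IP`` taken from the rows (lncRNAs) or columns
  (diseases) of the association matrix,
  ``S(i, j) = exp(-beta * ||IP(i) - IP(j)||^2)`` with a bandwidth ``beta``
  normalised by the mean squared profile norm.

* **Disease module separation**: each disease owns a module (gene set) in a
  gene-gene interaction network; the network-based separation
  ``S_AB = d_AB - (d_AA + d_BB) / 2`` between two modules (negative when the
  modules overlap topologically) is mapped to a similarity in [0, 1] by
  min-max normalisation over all disease pairs, so the most overlapping
  pair scores 1 and the most separated pair scores 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path
from scipy.spatial.distance import squareform, pdist

from .data_io import AssociationMatrix, DiseaseGeneMap, GeneInteractionNetwork

logger = logging.getLogger("lncgat")

__all__ = [
    "SimilarityMatrix",
    "Separation",
    "gip_bandwidth",
    "gip_similarity",
    "PairExcludingGip",
    "module_separation",
    "disease_similarity",
    "identity_similarity",
]


@dataclass
class SimilarityMatrix:
    """Symmetric n x n similarity with unit diagonal and row/column ids."""

    ids: list[str]
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"similarity shape {self.values.shape} != ({n}, {n})")
        if np.abs(self.values - self.values.T).max(initial=0.0) > 1e-9:
            raise ValueError("similarity matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def row(self, index: int) -> np.ndarray:
        return self.values[index]


@dataclass
class Separation:
    """Module-separation statistic S_AB and its distance components."""

    s_ab: float
    d_aa: float
    d_bb: float
    d_ab: float


# ---------------------------------------------------------------------------
# GIP kernel
# ---------------------------------------------------------------------------


def _profiles(A: AssociationMatrix, axis: str) -> np.ndarray:
    if axis == "lncrna":
        return A.values.astype(float)
    if axis == "disease":
        return A.values.T.astype(float)
    raise ValueError(f"axis must be 'lncrna' or 'disease', got {axis!r}")


def gip_bandwidth(A: AssociationMatrix, axis: str = "lncrna", literal_eq3: bool = False) -> float:
    """Kernel bandwidth normalised by the mean squared profile norm.

    The default returns ``1 / mean_i ||IP(i)||^2`` (the standard GIP
    normalisation). ``literal_eq3=True`` returns the mean squared norm itself.
    """
    profiles = _profiles(A, axis)
    mean_sq = float((profiles**2).sum(axis=1).mean())
    if mean_sq == 0.0:
        raise ValueError("bandwidth undefined: association matrix is all zero")
    return mean_sq if literal_eq3 else 1.0 / mean_sq


def gip_similarity(A: AssociationMatrix, axis: str = "lncrna", literal_eq3: bool = False) -> SimilarityMatrix:
    """Gaussian interaction profile kernel similarity between profiles."""
    beta = gip_bandwidth(A, axis, literal_eq3=literal_eq3)
    profiles = _profiles(A, axis)
    sq = squareform(pdist(profiles, metric="sqeuclidean")) if len(profiles) > 1 else np.zeros((1, 1))
    values = np.exp(-beta * sq)
    np.fill_diagonal(values, 1.0)
    values = (values + values.T) / 2.0  # exact symmetry
    ids = A.lncrna_ids if axis == "lncrna" else A.disease_ids
    return SimilarityMatrix(list(ids), values, kind=f"{axis}_gip")


class PairExcludingGip:
    """GIP similarity with one designated association excluded on demand.

    When a pair (l, d) is scored, its own association — if present — is the
    class label and must not reach the classifier through the similarity
    features, mirroring the removal of the target edge from the enclosing
    subgraph. ``without(i, j)`` returns the GIP matrix recomputed as if
    entry (i, j) of the association matrix were 0, using a cached squared-
    distance matrix so each call costs O(n^2) instead of a full rebuild.
    """

    def __init__(self, A: AssociationMatrix, axis: str = "lncrna", literal_eq3: bool = False):
        self.axis = axis
        self.literal_eq3 = literal_eq3
        self.ids = list(A.lncrna_ids if axis == "lncrna" else A.disease_ids)
        self.profiles = _profiles(A, axis)
        n = len(self.profiles)
        self._sq = (
            squareform(pdist(self.profiles, metric="sqeuclidean"))
            if n > 1
            else np.zeros((1, 1))
        )
        self._mean_sq = float((self.profiles**2).sum(axis=1).mean())
        if self._mean_sq == 0.0:
            raise ValueError("bandwidth undefined: association matrix is all zero")
        self._kind = f"{axis}_gip"

    def _matrix(self, sq: np.ndarray, mean_sq: float) -> SimilarityMatrix:
        beta = mean_sq if self.literal_eq3 else 1.0 / mean_sq
        values = np.exp(-beta * sq)
        np.fill_diagonal(values, 1.0)
        values = (values + values.T) / 2.0
        return SimilarityMatrix(list(self.ids), values, self._kind)

    def base(self) -> SimilarityMatrix:
        return self._matrix(self._sq, self._mean_sq)

    def without(self, entity: int, component: int) -> SimilarityMatrix:
        """Similarity as if profile ``entity`` had a 0 at ``component``."""
        if self.profiles[entity, component] == 0:
            return self.base()
        n = len(self.profiles)
        # flipping bit c of profile e from 1 to 0 changes the squared distance
        # to profile k by (0 - p_kc)^2 - (1 - p_kc)^2 = 2 p_kc - 1
        delta = 2.0 * self.profiles[:, component] - 1.0
        sq = self._sq.copy()
        sq[entity, :] += delta
        sq[:, entity] += delta
        sq[entity, entity] = 0.0
        mean_sq = self._mean_sq - 1.0 / n
        if mean_sq <= 0.0:
            raise ValueError("bandwidth undefined after excluding the only association")
        return self._matrix(sq, mean_sq)


# ---------------------------------------------------------------------------
# gene-network disease similarity
# ---------------------------------------------------------------------------


def _network_distances(net: GeneInteractionNetwork, sources: list[str]):
    """Unweighted shortest-path distances from ``sources`` to every gene.

    Returns (dist array |sources| x |genes|, gene->column index, replacement
    distance used for unreachable pairs: largest finite distance + 1).
    """
    genes = list(net.gene_ids)
    col = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    rows, cols = [], []
    for e in net.edges:
        a, b = tuple(e)
        rows += [col[a], col[b]]
        cols += [col[b], col[a]]
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    all_dist = shortest_path(adj, method="D", unweighted=True)
    finite = all_dist[np.isfinite(all_dist)]
    # unreachable pairs fall back to the network's largest finite distance + 1
    far = float(finite.max()) + 1.0 if finite.size else 1.0
    src_idx = np.array([col[g] for g in sources], dtype=int)
    dist = all_dist[src_idx]
    return dist, col, far


def _nearest(dist_rows: np.ndarray, own_pos: np.ndarray, other_cols: np.ndarray, far: float) -> float:
    """Mean over the genes indexing ``dist_rows`` of the min distance to
    ``other_cols``; unreachable genes contribute ``far``."""
    if len(other_cols) == 0:
        return 0.0
    mins = dist_rows[:, other_cols].min(axis=1)
    mins = np.where(np.isfinite(mins), mins, far)
    return float(mins.mean())


def module_separation(
    net: GeneInteractionNetwork,
    genes_a,
    genes_b,
    convention: str = "nearest",
    _dist_cache=None,
) -> Separation:
    """Network separation S_AB = d_AB - (d_AA + d_BB)/2 of two gene sets.

    ``convention='nearest'`` (default) uses nearest-neighbour means: d_AA is
    the mean over genes of A of the shortest distance to another gene of A
    (0 for singletons), and d_AB is the mean over all genes of A and B of the
    shortest distance to the opposite set (genes shared by both sets
    contribute 0). ``convention='all_pairs'`` uses plain all-pairs means.
    Negative S_AB marks topologically overlapping modules.
    """
    genes_a = sorted(set(genes_a))
    genes_b = sorted(set(genes_b))
    if not genes_a or not genes_b:
        raise ValueError("gene sets must be non-empty")
    net_genes = set(net.gene_ids)
    for g in genes_a + genes_b:
        if g not in net_genes:
            raise ValueError(f"gene {g!r} absent from network")

    if _dist_cache is None:
        sources = sorted(set(genes_a) | set(genes_b))
        dist, col, far = _network_distances(net, sources)
        row = {g: i for i, g in enumerate(sources)}
    else:
        dist, col, far, row = _dist_cache

    a_rows = np.array([row[g] for g in genes_a])
    b_rows = np.array([row[g] for g in genes_b])
    a_cols = np.array([col[g] for g in genes_a])
    b_cols = np.array([col[g] for g in genes_b])

    def within(rows_idx, cols_idx, ids):
        if len(ids) < 2:
            return 0.0
        sub = dist[np.ix_(rows_idx, cols_idx)].copy()
        np.fill_diagonal(sub, np.inf)  # exclude self-distance
        if convention == "nearest":
            mins = sub.min(axis=1)
            mins = np.where(np.isfinite(mins), mins, far)
            return float(mins.mean())
        off = sub[~np.eye(len(ids), dtype=bool)]
        off = np.where(np.isfinite(off), off, far)
        return float(off.mean())

    if convention == "nearest":
        d_aa = within(a_rows, a_cols, genes_a)
        d_bb = within(b_rows, b_cols, genes_b)
        d_ab = (
            _nearest(dist[a_rows], a_cols, b_cols, far) * len(genes_a)
            + _nearest(dist[b_rows], b_cols, a_cols, far) * len(genes_b)
        ) / (len(genes_a) + len(genes_b))
    elif convention == "all_pairs":
        d_aa = within(a_rows, a_cols, genes_a)
        d_bb = within(b_rows, b_cols, genes_b)
        cross = dist[np.ix_(a_rows, b_cols)].copy()
        shared = np.array([[ga == gb for gb in genes_b] for ga in genes_a])
        cross[shared] = 0.0
        cross = np.where(np.isfinite(cross), cross, far)
        d_ab = float(cross.mean())
    else:
        raise ValueError(f"unknown convention {convention!r}")

    return Separation(d_ab - (d_aa + d_bb) / 2.0, d_aa, d_bb, d_ab)


def disease_similarity(
    net: GeneInteractionNetwork,
    dgmap: DiseaseGeneMap,
    disease_ids: list[str],
    convention: str = "nearest",
    normalization: str = "minmax",
    lcc: bool = False,
) -> tuple[SimilarityMatrix, pd.DataFrame]:
    """Disease similarity from disease-module separation in the gene network.

    S_AB is computed for every unordered pair of diseases with gene data and
    mapped to a similarity: ``minmax`` (default) uses
    ``1 - (S_AB - min) / (max - min)`` so output lies in [0, 1];
    ``literal`` uses ``1 - (S_AB - min) / max`` (can leave [0, 1]; logged).
    Pairs involving a disease without gene data get similarity 0; the
    diagonal is 1. Also returns the per-pair separation table.
    """
    if lcc:
        net = _largest_component(net)
        dgmap = DiseaseGeneMap(
            {
                d: gs & set(net.gene_ids)
                for d, gs in dgmap.modules.items()
                if gs & set(net.gene_ids)
            },
            list(dgmap.no_gene_data),
        )
    with_data = [d for d in disease_ids if dgmap.has_data(d)]
    if len(with_data) < 2:
        raise ValueError("need at least two diseases with gene data")

    all_genes = sorted(set().union(*(dgmap.genes(d) for d in with_data)))
    dist, col, far = _network_distances(net, all_genes)
    row = {g: i for i, g in enumerate(all_genes)}
    cache = (dist, col, far, row)

    records = []
    sep = {}
    for ai in range(len(with_data)):
        for bi in range(ai + 1, len(with_data)):
            da, db = with_data[ai], with_data[bi]
            s = module_separation(
                net, dgmap.genes(da), dgmap.genes(db), convention, _dist_cache=cache
            )
            sep[(da, db)] = s.s_ab
            records.append(
                {
                    "disease_a": da,
                    "disease_b": db,
                    "s_ab": s.s_ab,
                    "d_aa": s.d_aa,
                    "d_bb": s.d_bb,
                    "d_ab": s.d_ab,
                }
            )
    table = pd.DataFrame.from_records(
        records, columns=["disease_a", "disease_b", "s_ab", "d_aa", "d_bb", "d_ab"]
    )

    s_vals = np.array(list(sep.values()))
    s_min, s_max = float(s_vals.min()), float(s_vals.max())

    n = len(disease_ids)
    values = np.zeros((n, n))
    pos = {d: i for i, d in enumerate(disease_ids)}
    if s_max == s_min:
        logger.warning("all disease pairs have identical S_AB; similarities set to 0.5")
        for (da, db) in sep:
            values[pos[da], pos[db]] = values[pos[db], pos[da]] = 0.5
    elif normalization == "minmax":
        for (da, db), s in sep.items():
            v = 1.0 - (s - s_min) / (s_max - s_min)
            values[pos[da], pos[db]] = values[pos[db], pos[da]] = v
    elif normalization == "literal":
        if s_max <= 0:
            raise ValueError("printed normalization undefined: max(S_AB) <= 0")
        escaped = 0
        for (da, db), s in sep.items():
            v = 1.0 - (s - s_min) / s_max
            if not 0.0 <= v <= 1.0:
                escaped += 1
            values[pos[da], pos[db]] = values[pos[db], pos[da]] = v
        if escaped:
            logger.warning(
                "literal normalization produced %d similarity value(s) outside [0, 1]",
                escaped,
            )
    else:
        raise ValueError(f"unknown normalization {normalization!r}")

    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(list(disease_ids), values, "disease_gene_network"), table


def identity_similarity(ids: list[str], kind: str = "identity") -> SimilarityMatrix:
    """Fallback similarity: zeros off-diagonal, 1 on the diagonal."""
    return SimilarityMatrix(list(ids), np.eye(len(ids)), kind)


def _largest_component(net: GeneInteractionNetwork) -> GeneInteractionNetwork:
    import networkx as nx

    g = net.to_networkx()
    comp = max(nx.connected_components(g), key=len)
    genes = [x for x in net.gene_ids if x in comp]
    edges = {e for e in net.edges if set(e) <= comp}
    return GeneInteractionNetwork(genes, edges)
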