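"""Input/output for lncRNA-disease association data.

Three kinds of input feed the pipeline:

* an lncRNA-disease association list (tab-separated edge list, or a binary
  matrix CSV with id headers), turned into an :class:`AssociationMatrix`;
* an undirected gene-gene interaction network (tab-separated edge list);
* a disease -> gene annotation map (tab-separated two-column table).

Similarity matrices computed downstream are cached as CSV with an id header
row and index column so they round-trip losslessly (within 1e-12).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("lncgat")

__all__ = [
    "AssociationMatrix",
    "GeneInteractionNetwork",
    "DiseaseGeneMap",
    "read_association_table",
    "write_association_table",
    "merge_association_matrices",
    "read_gene_network",
    "write_gene_network",
    "read_disease_gene_map",
    "write_disease_gene_map",
    "read_alias_map",
    "apply_alias_map",
    "read_similarity",
    "write_similarity",
]


def normalize_id(name: str) -> str:
    """Canonical form used when matching ids across datasets."""
    return name.strip().casefold()


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class AssociationMatrix:
    """Binary L x D matrix A with A[l, d] = 1 for a verified association.

    Row ``i`` is the interaction profile ``IP(l_i)`` of lncRNA ``i``; column
    ``j`` is the interaction profile of disease ``j``.
    """

    lncrna_ids: list[str]
    disease_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        L, D = len(self.lncrna_ids), len(self.disease_ids)
        if L < 1 or D < 1:
            raise ValueError("association matrix needs at least one lncRNA and one disease")
        if self.values.shape != (L, D):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match ids ({L}, {D})"
            )
        if len(set(self.lncrna_ids)) != L:
            raise ValueError("duplicate lncRNA ids")
        if len(set(self.disease_ids)) != D:
            raise ValueError("duplicate disease ids")
        if not np.isin(self.values, (0, 1)).all():
            bad = self.values[~np.isin(self.values, (0, 1))].flat[0]
            raise ValueError(f"association matrix entries must be 0/1, found {bad!r}")
        self.values = self.values.astype(np.int8)

    @property
    def n_lncrnas(self) -> int:
        return len(self.lncrna_ids)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    @property
    def n_associations(self) -> int:
        return int(self.values.sum())

    @property
    def density(self) -> float:
        return self.n_associations / self.values.size

    def pairs(self) -> list[tuple[int, int]]:
        """Index pairs (i, j) of all known associations."""
        return [tuple(p) for p in np.argwhere(self.values == 1)]

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(
            list(self.lncrna_ids), list(self.disease_ids), self.values.copy()
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.lncrna_ids, columns=self.disease_ids
        )


@dataclass
class GeneInteractionNetwork:
    """Undirected gene-gene interaction network without self-loops."""

    gene_ids: list[str]
    edges: set[frozenset]

    def __post_init__(self) -> None:
        genes = set(self.gene_ids)
        for e in self.edges:
            if len(e) != 2:
                raise ValueError(f"self-loop or malformed edge {set(e)}")
            if not e <= genes:
                raise ValueError(f"edge {set(e)} references unknown gene")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def has_gene(self, g: str) -> bool:
        return g in set(self.gene_ids)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.gene_ids)
        g.add_edges_from(tuple(e) for e in self.edges)
        return g


@dataclass
class DiseaseGeneMap:
    """disease id -> set of genes (the disease module), plus the diseases
    for which no usable gene annotation survived filtering."""

    modules: dict[str, set]
    no_gene_data: list[str] = field(default_factory=list)

    def genes(self, disease_id: str) -> set:
        return self.modules[disease_id]

    def has_data(self, disease_id: str) -> bool:
        return disease_id in self.modules


# ---------------------------------------------------------------------------
# association tables
# ---------------------------------------------------------------------------


def _parse_tsv_rows(path, min_cols: int, max_cols: int):
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if not (min_cols <= len(parts) <= max_cols):
                raise ValueError(
                    f"{path}: line {lineno}: expected {min_cols}-{max_cols} "
                    f"tab-separated fields, got {len(parts)}"
                )
            rows.append((lineno, [p.strip() for p in parts]))
    return rows


def read_association_table(path, format: str = "edge_list") -> AssociationMatrix:
    """Read an association table.

    ``edge_list``: tab-separated rows ``lncrna_id<TAB>disease_id[<TAB>value]``
    ('#' comments ignored). Duplicate edges collapse to a single 1; ids keep
    first-seen order. ``matrix``: CSV with lncRNA ids as the index column and
    disease ids as the header; entries must be 0/1.
    """
    if format == "edge_list":
        rows = _parse_tsv_rows(path, 2, 3)
        lnc_ids: list[str] = []
        dis_ids: list[str] = []
        lnc_pos: dict[str, int] = {}
        dis_pos: dict[str, int] = {}
        edges: set[tuple[int, int]] = set()
        for lineno, parts in rows:
            lnc, dis = parts[0], parts[1]
            if not lnc or not dis:
                raise ValueError(f"{path}: line {lineno}: empty id field")
            val = 1.0
            if len(parts) == 3:
                try:
                    val = float(parts[2])
                except ValueError:
                    raise ValueError(
                        f"{path}: line {lineno}: non-numeric value {parts[2]!r}"
                    ) from None
                if val not in (0.0, 1.0):
                    raise ValueError(
                        f"{path}: line {lineno}: association value must be 0/1, got {val}"
                    )
            if lnc not in lnc_pos:
                lnc_pos[lnc] = len(lnc_ids)
                lnc_ids.append(lnc)
            if dis not in dis_pos:
                dis_pos[dis] = len(dis_ids)
                dis_ids.append(dis)
            if val == 1.0:
                edges.add((lnc_pos[lnc], dis_pos[dis]))
        if not edges:
            raise ValueError(f"{path}: no associations")
        values = np.zeros((len(lnc_ids), len(dis_ids)), dtype=np.int8)
        for i, j in edges:
            values[i, j] = 1
        return AssociationMatrix(lnc_ids, dis_ids, values)

    if format == "matrix":
        frame = pd.read_csv(path, index_col=0)
        if frame.empty:
            raise ValueError(f"{path}: no associations")
        values = frame.to_numpy(dtype=float)
        if not np.isin(values, (0.0, 1.0)).all():
            raise ValueError(f"{path}: matrix entries must be binary 0/1")
        return AssociationMatrix(
            [str(i) for i in frame.index],
            [str(c) for c in frame.columns],
            values.astype(np.int8),
        )

    raise ValueError(f"unknown format {format!r}")


def write_association_table(A: AssociationMatrix, path, format: str = "edge_list") -> None:
    if format == "edge_list":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# lncrna_id\tdisease_id\n")
            for i, j in A.pairs():
                fh.write(f"{A.lncrna_ids[i]}\t{A.disease_ids[j]}\n")
    elif format == "matrix":
        A.to_frame().to_csv(path)
    else:
        raise ValueError(f"unknown format {format!r}")


def merge_association_matrices(
    A1: AssociationMatrix, A2: AssociationMatrix
) -> AssociationMatrix:
    """Union of two association datasets.

    Ids are matched by whitespace-trimmed, case-folded exact string equality
    (no ontology mapping); the merged entry is 1 iff it is 1 in either input.
    First-seen spelling of an id is kept.
    """
    lnc_ids: list[str] = []
    dis_ids: list[str] = []
    lnc_pos: dict[str, int] = {}
    dis_pos: dict[str, int] = {}

    def intern(ids, pos, name):
        key = normalize_id(name)
        if key not in pos:
            pos[key] = len(ids)
            ids.append(name.strip())
        return pos[key]

    edges = set()
    for A in (A1, A2):
        rows = [intern(lnc_ids, lnc_pos, n) for n in A.lncrna_ids]
        cols = [intern(dis_ids, dis_pos, n) for n in A.disease_ids]
        for i, j in A.pairs():
            edges.add((rows[i], cols[j]))
    values = np.zeros((len(lnc_ids), len(dis_ids)), dtype=np.int8)
    for i, j in edges:
        values[i, j] = 1
    return AssociationMatrix(lnc_ids, dis_ids, values)


# ---------------------------------------------------------------------------
# gene network / disease modules
# ---------------------------------------------------------------------------


def read_gene_network(path) -> GeneInteractionNetwork:
    """Two-column tab-separated gene-gene edge list; self-loops dropped."""
    rows = _parse_tsv_rows(path, 2, 2)
    genes: list[str] = []
    seen: set[str] = set()
    edges: set[frozenset] = set()
    n_loops = 0
    for _lineno, (g1, g2) in rows:
        for g in (g1, g2):
            if g not in seen:
                seen.add(g)
                genes.append(g)
        if g1 == g2:
            n_loops += 1
            continue
        edges.add(frozenset((g1, g2)))
    if n_loops:
        logger.warning("dropped %d self-loop(s) while reading %s", n_loops, path)
    return GeneInteractionNetwork(genes, edges)


def write_gene_network(net: GeneInteractionNetwork, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# gene_a\tgene_b\n")
        for e in sorted(tuple(sorted(e)) for e in net.edges):
            fh.write(f"{e[0]}\t{e[1]}\n")
        connected = {g for e in net.edges for g in e}
        for g in net.gene_ids:  # keep isolated genes recoverable
            if g not in connected:
                fh.write(f"{g}\t{g}\n")


def read_disease_gene_map(path, network: GeneInteractionNetwork) -> DiseaseGeneMap:
    """Two-column (disease, gene) table filtered to genes present in the
    network; diseases left with no mapped genes land in ``no_gene_data``."""
    rows = _parse_tsv_rows(path, 2, 2)
    net_genes = set(network.gene_ids)
    raw: dict[str, set] = {}
    n_dropped = 0
    for _lineno, (dis, gene) in rows:
        raw.setdefault(dis, set())
        if gene in net_genes:
            raw[dis].add(gene)
        else:
            n_dropped += 1
    if n_dropped:
        logger.info(
            "dropped %d disease-gene row(s) whose gene is absent from the network",
            n_dropped,
        )
    modules = {d: gs for d, gs in raw.items() if gs}
    no_data = [d for d, gs in raw.items() if not gs]
    if no_data:
        logger.info("%d disease(s) have no usable gene data", len(no_data))
    return DiseaseGeneMap(modules, no_data)


def write_disease_gene_map(dgmap: DiseaseGeneMap, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# disease_id\tgene_id\n")
        for dis in dgmap.modules:
            for g in sorted(dgmap.modules[dis]):
                fh.write(f"{dis}\t{g}\n")


# ---------------------------------------------------------------------------
# alias map
# ---------------------------------------------------------------------------


def read_alias_map(path) -> dict[str, str]:
    """old_name -> new_name table for unifying synonymous disease terms."""
    rows = _parse_tsv_rows(path, 2, 2)
    return {normalize_id(old): new.strip() for _ln, (old, new) in rows}


def apply_alias_map(A: AssociationMatrix, aliases: dict[str, str]) -> AssociationMatrix:
    """Rename (and, when aliases collide, merge) disease columns."""
    new_ids: list[str] = []
    pos: dict[str, int] = {}
    col_of: list[int] = []
    for name in A.disease_ids:
        renamed = aliases.get(normalize_id(name), name)
        key = normalize_id(renamed)
        if key not in pos:
            pos[key] = len(new_ids)
            new_ids.append(renamed)
        col_of.append(pos[key])
    values = np.zeros((A.n_lncrnas, len(new_ids)), dtype=np.int8)
    for j, jj in enumerate(col_of):
        values[:, jj] |= A.values[:, j]
    return AssociationMatrix(list(A.lncrna_ids), new_ids, values)


# ---------------------------------------------------------------------------
# similarity matrix cache
# ---------------------------------------------------------------------------


def write_similarity(sim, path) -> None:
    """CSV cache of a similarity matrix (ids as header row and index)."""
    pd.DataFrame(sim.values, index=sim.ids, columns=sim.ids).to_csv(path)


def read_similarity(path, kind: str = "cached"):
    from .similarity import SimilarityMatrix

    frame = pd.read_csv(path, index_col=0)
    if frame.shape[0] != frame.shape[1]:
        raise ValueError(f"{path}: similarity matrix is not square {frame.shape}")
    if [str(i) for i in frame.index] != [str(c) for c in frame.columns]:
        raise ValueError(f"{path}: row and column ids disagree")
    values = frame.to_numpy(dtype=float)
    if np.abs(values - values.T).max() > 1e-9:
        raise ValueError(f"{path}: similarity matrix asymmetric beyond 1e-9")
    return SimilarityMatrix([str(i) for i in frame.index], values, kind)
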