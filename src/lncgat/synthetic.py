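"""Self-contained synthetic datasets with planted structure.

The generator emulates the statistical shape of public lncRNA-disease
benchmarks without any download: a sparse binary bipartite association
matrix with planted block structure (lncRNA block b pairs with disease
block b mod n_disease_blocks; associations are Bernoulli(p_in) inside a
paired block combination and Bernoulli(p_out) elsewhere), a random
gene-gene interaction network, and disease modules drawn so that diseases
of the same block share an overlapping gene core from a block-private gene
pool, while modules of different blocks are disjoint.

A degree-preserving label shuffler (checkerboard edge swaps) provides the
matched negative control: the same margins, no planted structure.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import networkx as nx
import numpy as np

from .data_io import (
    AssociationMatrix,
    DiseaseGeneMap,
    GeneInteractionNetwork,
    write_association_table,
    write_disease_gene_map,
    write_gene_network,
)
from .pipeline import DatasetBundle

logger = logging.getLogger("lncgat")

__all__ = ["SyntheticSpec", "SyntheticDataset", "generate", "shuffle_labels", "write_dataset"]


@dataclass
class SyntheticSpec:
    """Parameters of the planted-structure generator.

    Defaults give a 40 x 30 association matrix with 4 lncRNA and 3 disease
    blocks, within-pair association probability 0.35 against a 0.03
    background, a 300-gene interaction network, and 12-gene disease modules
    overlapping 50% within a disease block.
    """

    L: int = 40
    D: int = 30
    lncrna_blocks: int = 4
    disease_blocks: int = 3
    p_in: float = 0.35
    p_out: float = 0.03
    n_genes: int = 300
    gene_network_model: str = "erdos_renyi"  # or "preferential_attachment"
    gene_network_param: float = 6.0  # ER: expected mean degree; PA: edges per new node
    genes_per_disease: int = 12
    module_overlap: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_out < self.p_in <= 1.0:
            raise ValueError("need 0 <= p_out < p_in <= 1")
        if self.lncrna_blocks > self.L or self.disease_blocks > self.D:
            raise ValueError("more blocks than entities")
        if self.genes_per_disease * self.disease_blocks > self.n_genes:
            raise ValueError(
                "infeasible overlap: genes_per_disease x disease_blocks exceeds gene count"
            )
        if not 0.0 <= self.module_overlap <= 1.0:
            raise ValueError("module_overlap must lie in [0, 1]")


@dataclass
class SyntheticDataset:
    """Generated bundle plus the planted ground truth."""

    spec: SyntheticSpec
    associations: AssociationMatrix
    gene_network: GeneInteractionNetwork
    disease_gene_map: DiseaseGeneMap
    lncrna_block: np.ndarray
    disease_block: np.ndarray

    def bundle(self) -> DatasetBundle:
        return DatasetBundle(self.associations, self.gene_network, self.disease_gene_map)


def _blocks(n: int, k: int) -> np.ndarray:
    """Equal partition into k blocks; the remainder goes to the last block."""
    size = n // k
    labels = np.repeat(np.arange(k), size)
    return np.concatenate([labels, np.full(n - len(labels), k - 1)])


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw one dataset from the planted-structure model (seeded)."""
    rng = np.random.default_rng(spec.seed)

    lb = _blocks(spec.L, spec.lncrna_blocks)
    db = _blocks(spec.D, spec.disease_blocks)
    paired = (lb[:, None] % spec.disease_blocks) == db[None, :]
    P = np.where(paired, spec.p_in, spec.p_out)
    values = (rng.random((spec.L, spec.D)) < P).astype(np.int8)
    if values.sum() == 0:  # degenerate draw; plant one association
        values[0, 0] = 1
    lnc_ids = [f"lnc{i + 1:03d}" for i in range(spec.L)]
    dis_ids = [f"dis{j + 1:03d}" for j in range(spec.D)]
    A = AssociationMatrix(lnc_ids, dis_ids, values)

    gene_ids = [f"g{i + 1:04d}" for i in range(spec.n_genes)]
    if spec.gene_network_model == "erdos_renyi":
        p_edge = min(1.0, spec.gene_network_param / max(spec.n_genes - 1, 1))
        g = nx.fast_gnp_random_graph(
            spec.n_genes, p_edge, seed=int(rng.integers(2**31 - 1))
        )
    elif spec.gene_network_model == "preferential_attachment":
        g = nx.barabasi_albert_graph(
            spec.n_genes, max(1, int(spec.gene_network_param)),
            seed=int(rng.integers(2**31 - 1)),
        )
    else:
        raise ValueError(f"unknown gene network model {spec.gene_network_model!r}")
    edges = {frozenset((gene_ids[u], gene_ids[v])) for u, v in g.edges() if u != v}
    net = GeneInteractionNetwork(gene_ids, edges)

    # disjoint gene pool per disease block; shared core within a block
    pool_size = spec.n_genes // spec.disease_blocks
    core_size = int(round(spec.genes_per_disease * spec.module_overlap))
    modules: dict[str, set] = {}
    for b in range(spec.disease_blocks):
        pool = np.arange(b * pool_size, (b + 1) * pool_size)
        core = rng.choice(pool, size=core_size, replace=False)
        rest_pool = np.setdiff1d(pool, core)
        for j in np.flatnonzero(db == b):
            own = rng.choice(
                rest_pool, size=spec.genes_per_disease - core_size, replace=False
            )
            modules[dis_ids[j]] = {gene_ids[i] for i in np.concatenate([core, own])}
    dgmap = DiseaseGeneMap(modules, [])

    return SyntheticDataset(spec, A, net, dgmap, lb, db)


def shuffle_labels(ds: SyntheticDataset, seed: int = 0) -> SyntheticDataset:
    """Negative control: randomise the association matrix by checkerboard
    edge swaps, preserving every row and column sum (degree sequence)."""
    rng = np.random.default_rng(seed)
    M = ds.associations.values.copy()
    edges = [tuple(e) for e in np.argwhere(M == 1)]
    if len(edges) < 2:
        logger.warning("too few associations to swap; returning identity shuffle")
        return SyntheticDataset(
            ds.spec, ds.associations.copy(), ds.gene_network, ds.disease_gene_map,
            ds.lncrna_block, ds.disease_block,
        )
    n_attempts = 10 * len(edges)
    for _ in range(n_attempts):
        a, b = rng.integers(len(edges), size=2)
        (l1, d1), (l2, d2) = edges[a], edges[b]
        if l1 == l2 or d1 == d2:
            continue
        if M[l1, d2] or M[l2, d1]:
            continue
        M[l1, d1] = M[l2, d2] = 0
        M[l1, d2] = M[l2, d1] = 1
        edges[a], edges[b] = (l1, d2), (l2, d1)
    shuffled = AssociationMatrix(
        list(ds.associations.lncrna_ids), list(ds.associations.disease_ids), M
    )
    return SyntheticDataset(
        ds.spec, shuffled, ds.gene_network, ds.disease_gene_map,
        ds.lncrna_block, ds.disease_block,
    )


def write_dataset(ds: SyntheticDataset, out_dir) -> None:
    """Write the three standard input files plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_association_table(ds.associations, out / "associations.tsv", "edge_list")
    write_gene_network(ds.gene_network, out / "gene_network.tsv")
    write_disease_gene_map(ds.disease_gene_map, out / "disease_genes.tsv")
    manifest = {
        "spec": asdict(ds.spec),
        "lncrna_block": ds.lncrna_block.tolist(),
        "disease_block": ds.disease_block.tolist(),
        "n_associations": ds.associations.n_associations,
        "density": ds.associations.density,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
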