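"""Cross-validation pipeline: negative sampling, fold construction, training,
scoring, metrics and candidate ranking.

Three cross-validation protocols are supported:

* **CVP** — partition the known association *pairs* into k folds;
* **CVL** — partition the *lncRNAs* (rows) into k groups, testing each group
  once as cold-start lncRNAs;
* **CVD** — the same on *diseases* (columns).

In every fold the test positives are zeroed out of the training association
matrix before anything downstream sees it: the lncRNA GIP similarity is
recomputed from the train-fold matrix, subgraphs are extracted from the
train-fold graph only, and the target edge of every training positive is
removed from its own subgraph. Negatives are unknown pairs sampled 1:1 with
positives; in CVL/CVD the test negatives are drawn from the test rows or
columns so that the cold-start evaluation stays cold.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    precision_score,
    recall_score,
    roc_auc_score,
)

from .data_io import AssociationMatrix, DiseaseGeneMap, GeneInteractionNetwork
from .features import attach_features, label_code_width
from .gnn import Adam, GraphBatch, ModelConfig, TrainedModel, init_model
from .similarity import PairExcludingGip, SimilarityMatrix, disease_similarity
from .subgraph import BipartiteGraph, build_bipartite_graph, extract_enclosing_subgraph

logger = logging.getLogger("lncgat")

__all__ = [
    "DatasetBundle",
    "FoldSplit",
    "MetricsReport",
    "sample_negatives",
    "make_folds",
    "train",
    "predict",
    "compute_metrics",
    "run_cv",
    "rank_candidates",
    "fit_full",
]

MODES = ("CVP", "CVL", "CVD")


@dataclass
class DatasetBundle:
    """The three inputs of a study: associations, gene network, disease modules.

    The gene network and disease-gene map are optional; without them the
    disease similarity falls back to the disease-axis GIP kernel computed
    from the train-fold matrix.
    """

    associations: AssociationMatrix
    gene_network: GeneInteractionNetwork | None = None
    disease_gene_map: DiseaseGeneMap | None = None


@dataclass
class FoldSplit:
    """One train/test split of one repeat of a cross-validation run."""

    mode: str
    repeat: int
    fold: int
    seed: int
    train_pos: list[tuple[int, int]]
    train_neg: list[tuple[int, int]]
    test_pos: list[tuple[int, int]]
    test_neg: list[tuple[int, int]]
    train_matrix: AssociationMatrix


@dataclass
class MetricsReport:
    """Per-fold metric table and mean +/- sd summary."""

    mode: str
    threshold: float
    per_fold: pd.DataFrame

    METRICS = ("auc", "aupr", "f1", "accuracy", "precision", "recall")

    def summary(self) -> dict:
        out = {}
        for m in self.METRICS:
            vals = self.per_fold[m].to_numpy(dtype=float)
            out[m] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=0))}
        return out

    def mean(self, metric: str) -> float:
        return float(self.per_fold[metric].mean())

    def to_json(self) -> str:
        return json.dumps(
            {
                "mode": self.mode,
                "threshold": self.threshold,
                "summary": self.summary(),
                "n_folds": int(len(self.per_fold)),
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# negative sampling and fold construction
# ---------------------------------------------------------------------------


def sample_negatives(
    A: AssociationMatrix,
    n: int,
    seed_or_rng,
    exclude=(),
    rows=None,
    cols=None,
) -> list[tuple[int, int]]:
    """Sample ``n`` distinct unknown pairs (A == 0), avoiding ``exclude``.

    ``rows``/``cols`` restrict candidates to given row/column indices (used
    for cold-start folds). Reproducible for a given seed.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    zeros = np.argwhere(A.values == 0)
    if rows is not None:
        zeros = zeros[np.isin(zeros[:, 0], np.asarray(list(rows)))]
    if cols is not None:
        zeros = zeros[np.isin(zeros[:, 1], np.asarray(list(cols)))]
    excluded = set(map(tuple, exclude))
    if excluded:
        keep = np.array([tuple(z) not in excluded for z in zeros])
        zeros = zeros[keep]
    if len(zeros) < n:
        raise ValueError(
            f"cannot sample {n} negatives: only {len(zeros)} unknown pairs available"
        )
    pick = rng.choice(len(zeros), size=n, replace=False)
    return [tuple(z) for z in zeros[np.sort(pick)]]


def _zero_pairs(A: AssociationMatrix, pairs) -> AssociationMatrix:
    M = A.copy()
    for i, j in pairs:
        M.values[i, j] = 0
    return M


def make_folds(
    A: AssociationMatrix,
    mode: str = "CVP",
    k: int = 5,
    repeats: int = 10,
    seed: int = 0,
    single_split: bool = False,
) -> list[FoldSplit]:
    """Build the train/test splits of a cross-validation protocol.

    CVP partitions positive pairs into k folds; CVL/CVD partition row/column
    indices into k groups, each serving once as the (1/k) test side.
    ``single_split`` keeps only the first fold of each repeat (a single
    20% draw at the default k=5).
    """
    mode = mode.upper()
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    pos = np.array(A.pairs())
    folds: list[FoldSplit] = []
    for rep in range(repeats):
        rep_seed = seed * 1009 + rep
        rng = np.random.default_rng(rep_seed)
        if mode == "CVP":
            if len(pos) < k:
                raise ValueError(f"only {len(pos)} positives for k={k} folds")
            order = rng.permutation(len(pos))
            groups = [order[f::k] for f in range(k)]
        else:
            n_units = A.n_lncrnas if mode == "CVL" else A.n_diseases
            if n_units < k:
                raise ValueError(f"only {n_units} units for k={k} folds")
            order = rng.permutation(n_units)
            groups = [order[f::k] for f in range(k)]

        for f in range(k):
            if single_split and f > 0:
                break
            fold_rng = np.random.default_rng(rep_seed * 31 + f)
            if mode == "CVP":
                test_pos = [tuple(p) for p in pos[groups[f]]]
                train_pos = [
                    tuple(p)
                    for g in range(k)
                    if g != f
                    for p in pos[groups[g]]
                ]
                test_neg = sample_negatives(A, len(test_pos), fold_rng)
                train_neg = sample_negatives(
                    A, len(train_pos), fold_rng, exclude=test_neg
                )
            else:
                test_units = set(int(u) for u in groups[f])
                train_units = set(range(len(order))) - test_units
                axis = 0 if mode == "CVL" else 1
                test_pos = [tuple(p) for p in pos if int(p[axis]) in test_units]
                train_pos = [tuple(p) for p in pos if int(p[axis]) in train_units]
                if not test_pos or not train_pos:
                    raise ValueError(
                        f"{mode} fold {f}: empty train or test positive set"
                    )
                kw_test = {"rows": test_units} if mode == "CVL" else {"cols": test_units}
                kw_train = {"rows": train_units} if mode == "CVL" else {"cols": train_units}
                test_neg = sample_negatives(A, len(test_pos), fold_rng, **kw_test)
                train_neg = sample_negatives(
                    A, len(train_pos), fold_rng, exclude=test_neg, **kw_train
                )
            folds.append(
                FoldSplit(
                    mode=mode,
                    repeat=rep,
                    fold=f,
                    seed=rep_seed * 31 + f,
                    train_pos=train_pos,
                    train_neg=train_neg,
                    test_pos=test_pos,
                    test_neg=test_neg,
                    train_matrix=_zero_pairs(A, test_pos),
                )
            )
    return folds


def audit_fold(fold: FoldSplit, A: AssociationMatrix) -> None:
    """Assert the leakage invariants of one fold; raises on violation."""
    for i, j in fold.test_pos:
        if fold.train_matrix.values[i, j] != 0:
            raise AssertionError(f"test positive ({i},{j}) visible in train matrix")
    known = set(map(tuple, np.argwhere(A.values == 1)))
    for p in fold.test_neg + fold.train_neg:
        if tuple(p) in known:
            raise AssertionError(f"sampled negative {p} is a known positive")
    if set(fold.test_neg) & set(fold.train_neg):
        raise AssertionError("train and test negatives overlap")


# ---------------------------------------------------------------------------
# training and prediction
# ---------------------------------------------------------------------------


def train(
    graphs: list,
    config: ModelConfig,
    model: TrainedModel | None = None,
    log_csv=None,
) -> TrainedModel:
    """Train the graph classifier on labeled attributed subgraphs.

    Runs ``config.epochs`` epochs of shuffled mini-batches with Adam at the
    configured learning rate; the per-epoch mean loss is recorded on the
    returned model (and optionally written as CSV).
    """
    if not graphs:
        raise ValueError("no training subgraphs")
    if any(g.y is None for g in graphs):
        raise ValueError("training subgraphs must carry labels")
    model = model if model is not None else init_model(config)
    rng = np.random.default_rng(config.seed + 1)
    opt = Adam(model.params, lr=config.learning_rate)
    n = len(graphs)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, config.batch_size):
            batch = GraphBatch([graphs[i] for i in order[start : start + config.batch_size]])
            lval, grads = model.loss_and_grads(batch, rng=rng)
            if not np.isfinite(lval):
                raise RuntimeError(
                    f"non-finite loss {lval} at epoch {epoch}, batch start {start}"
                )
            opt.step(grads)
            total += lval if config.loss_reduction == "sum" else lval * batch.n_graphs
        model.loss_history.append(total / n)
    if log_csv is not None:
        pd.DataFrame(
            {"epoch": range(1, len(model.loss_history) + 1), "mean_loss": model.loss_history}
        ).to_csv(log_csv, index=False)
    return model


def _pair_graphs(
    pairs,
    labels,
    graph: BipartiteGraph,
    S_lnc: SimilarityMatrix,
    S_dis: SimilarityMatrix,
    h: int,
    remove_target_edge: bool = True,
    loo_lnc: PairExcludingGip | None = None,
    loo_dis: PairExcludingGip | None = None,
):
    """Attributed enclosing subgraphs for a list of pairs.

    With ``remove_target_edge`` the pair's own association (when present in
    the graph) is excluded both from the subgraph edges and — via the
    ``loo_*`` leave-one-out GIP providers — from the interaction profiles
    behind the pair's similarity features, so the class label never reaches
    the classifier input.
    """
    out = []
    for (l, d), y in zip(pairs, labels):
        sub = extract_enclosing_subgraph(graph, l, d, h, remove_target_edge)
        sub.y = int(y)
        Sl, Sd = S_lnc, S_dis
        if remove_target_edge and graph.has_edge(l, d):
            if loo_lnc is not None:
                Sl = loo_lnc.without(l, d)
            if loo_dis is not None:
                Sd = loo_dis.without(d, l)
        out.append(attach_features(sub, Sl, Sd))
    return out


def predict(
    model: TrainedModel,
    pairs,
    graph: BipartiteGraph,
    S_lnc: SimilarityMatrix,
    S_dis: SimilarityMatrix,
    h: int = 1,
) -> np.ndarray:
    """Association score p1 for each pair, judged from its enclosing subgraph
    in the (train-fold) graph."""
    graphs = _pair_graphs(pairs, [0] * len(pairs), graph, S_lnc, S_dis, h)
    expect = S_lnc.n + S_dis.n + label_code_width(h)
    if model.config.input_dim != expect:
        raise ValueError(
            f"model input_dim {model.config.input_dim} != feature dim {expect}"
        )
    return model.predict_score(graphs)


def compute_metrics(scores, labels, threshold: float = 0.5) -> dict:
    """AUC (rank-based, ties half credit), AUPR (step-interpolated PR area)
    and threshold metrics for one fold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("AUC/AUPR undefined: labels contain a single class")
    pred = (scores >= threshold).astype(int)
    return {
        "auc": float(roc_auc_score(labels, scores)),
        "aupr": float(average_precision_score(labels, scores)),
        "f1": float(
            2
            * precision_score(labels, pred, zero_division=0)
            * recall_score(labels, pred, zero_division=0)
            / max(
                precision_score(labels, pred, zero_division=0)
                + recall_score(labels, pred, zero_division=0),
                1e-300,
            )
        ),
        "accuracy": float(accuracy_score(labels, pred)),
        "precision": float(precision_score(labels, pred, zero_division=0)),
        "recall": float(recall_score(labels, pred, zero_division=0)),
    }


# ---------------------------------------------------------------------------
# full cross-validation loop
# ---------------------------------------------------------------------------


def run_cv(
    data: DatasetBundle,
    mode: str = "CVP",
    model_config: ModelConfig | None = None,
    h: int = 1,
    k: int = 5,
    repeats: int = 10,
    seed: int = 0,
    threshold: float = 0.5,
    single_split: bool = False,
    separation: str = "nearest",
    out_dir=None,
    collect_artifacts: bool = False,
):
    """Full cross-validation: folds -> similarities -> subgraphs -> train ->
    predict -> metrics, aggregated over folds x repeats.

    The lncRNA GIP similarity is recomputed from each train-fold matrix; the
    gene-network disease similarity (when gene data exists) is fold-
    independent. Returns a :class:`MetricsReport` (and the per-fold
    artifacts when ``collect_artifacts``).
    """
    A = data.associations
    K = label_code_width(h)
    input_dim = A.n_lncrnas + A.n_diseases + K
    base = model_config or ModelConfig(input_dim=input_dim)
    if base.input_dim != input_dim:
        base = replace(base, input_dim=input_dim)

    fixed_S_dis = None
    if data.gene_network is not None and data.disease_gene_map is not None:
        with_data = [d for d in A.disease_ids if data.disease_gene_map.has_data(d)]
        if len(with_data) >= 2:
            fixed_S_dis, _ = disease_similarity(
                data.gene_network, data.disease_gene_map, A.disease_ids, convention=separation
            )
        else:
            logger.warning("fewer than two diseases with gene data; GIP fallback")

    folds = make_folds(A, mode, k=k, repeats=repeats, seed=seed, single_split=single_split)
    rows = []
    artifacts = []
    for fold in folds:
        loo_lnc = PairExcludingGip(fold.train_matrix, axis="lncrna")
        S_lnc = loo_lnc.base()
        loo_dis = None
        if fixed_S_dis is None:
            loo_dis = PairExcludingGip(fold.train_matrix, axis="disease")
        S_dis = loo_dis.base() if loo_dis is not None else fixed_S_dis
        graph = build_bipartite_graph(fold.train_matrix)
        cfg = replace(base, seed=(base.seed + 7919 * fold.seed) % (2**31 - 1))
        train_graphs = _pair_graphs(
            fold.train_pos + fold.train_neg,
            [1] * len(fold.train_pos) + [0] * len(fold.train_neg),
            graph, S_lnc, S_dis, h,
            loo_lnc=loo_lnc, loo_dis=loo_dis,
        )
        model = train(train_graphs, cfg)
        test_pairs = fold.test_pos + fold.test_neg
        labels = np.array([1] * len(fold.test_pos) + [0] * len(fold.test_neg))
        scores = predict(model, test_pairs, graph, S_lnc, S_dis, h)
        m = compute_metrics(scores, labels, threshold)
        m.update(repeat=fold.repeat, fold=fold.fold, n_test=len(test_pairs))
        rows.append(m)
        logger.info(
            "%s repeat %d fold %d: AUC %.3f AUPR %.3f",
            mode, fold.repeat, fold.fold, m["auc"], m["aupr"],
        )
        if collect_artifacts:
            artifacts.append(
                {"fold": fold, "train_graphs": train_graphs, "S_lnc": S_lnc,
                 "scores": scores, "labels": labels}
            )

    per_fold = pd.DataFrame(rows)[
        ["repeat", "fold", "n_test", "auc", "aupr", "f1", "accuracy", "precision", "recall"]
    ]
    report = MetricsReport(mode=mode.upper(), threshold=threshold, per_fold=per_fold)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / f"metrics_{mode.lower()}.json").write_text(report.to_json())
        per_fold.to_csv(out_dir / f"per_fold_{mode.lower()}.csv", index=False)
    if collect_artifacts:
        return report, artifacts
    return report


# ---------------------------------------------------------------------------
# candidate ranking (case-study workflow)
# ---------------------------------------------------------------------------


def fit_full(
    data: DatasetBundle,
    model_config: ModelConfig | None = None,
    h: int = 1,
    seed: int = 0,
    separation: str = "nearest",
):
    """Train one model on all known associations (plus 1:1 sampled
    negatives); returns (model, graph, S_lnc, S_dis)."""
    A = data.associations
    K = label_code_width(h)
    input_dim = A.n_lncrnas + A.n_diseases + K
    cfg = model_config or ModelConfig(input_dim=input_dim, seed=seed)
    if cfg.input_dim != input_dim:
        cfg = replace(cfg, input_dim=input_dim)
    loo_lnc = PairExcludingGip(A, axis="lncrna")
    S_lnc = loo_lnc.base()
    fixed = None
    if data.gene_network is not None and data.disease_gene_map is not None:
        with_data = [d for d in A.disease_ids if data.disease_gene_map.has_data(d)]
        if len(with_data) >= 2:
            fixed, _ = disease_similarity(
                data.gene_network, data.disease_gene_map, A.disease_ids,
                convention=separation,
            )
    loo_dis = None if fixed is not None else PairExcludingGip(A, axis="disease")
    S_dis = fixed if fixed is not None else loo_dis.base()
    graph = build_bipartite_graph(A)
    pos = A.pairs()
    neg = sample_negatives(A, len(pos), np.random.default_rng(seed))
    graphs = _pair_graphs(
        pos + neg, [1] * len(pos) + [0] * len(neg), graph, S_lnc, S_dis, h,
        loo_lnc=loo_lnc, loo_dis=loo_dis,
    )
    model = train(graphs, cfg)
    return model, graph, S_lnc, S_dis


def rank_candidates(
    model: TrainedModel,
    disease_id: str,
    A: AssociationMatrix,
    graph: BipartiteGraph,
    S_lnc: SimilarityMatrix,
    S_dis: SimilarityMatrix,
    h: int = 1,
    topn: int = 15,
) -> pd.DataFrame:
    """Rank the candidate lncRNAs (those not known to associate with the
    disease) by predicted score; ties broken by lncRNA id for stability."""
    if disease_id not in A.disease_ids:
        raise KeyError(f"unknown disease id {disease_id!r}")
    d = A.disease_ids.index(disease_id)
    candidates = [l for l in range(A.n_lncrnas) if A.values[l, d] == 0]
    scores = predict(model, [(l, d) for l in candidates], graph, S_lnc, S_dis, h)
    order = sorted(
        range(len(candidates)), key=lambda i: (-scores[i], A.lncrna_ids[candidates[i]])
    )[: min(topn, len(candidates))]
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(order) + 1),
            "lncrna_id": [A.lncrna_ids[candidates[i]] for i in order],
            "score": [float(scores[i]) for i in order],
        }
    )
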