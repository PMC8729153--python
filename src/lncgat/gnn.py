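"""Graph-level classifier: one GCN layer, stacked GAT layers, target readout.

The network scores an attributed enclosing subgraph as a whole:

1. a single graph-convolution layer with symmetric degree normalisation,
   ``x_i' = sum_{j in N(i) u {i}} W x_j / sqrt(deg(i) deg(j))`` (self-loops
   added before normalisation);
2. a stack of graph-attention layers: additive attention
   ``e_ij = LeakyReLU(a^T [W h_i || W h_j])`` softmax-normalised over each
   node's neighbourhood (self-loops included), ELU activation, dropout on
   layer inputs and attention weights during training;
3. readout by concatenating the final representations of the two target
   nodes, a linear head to two logits, and a softmax; the association score
   is the probability of class 1. Training minimises summed cross-entropy.

Implemented directly in numpy with hand-derived gradients and an Adam
optimiser; batches of subgraphs are processed as one block-diagonal graph.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np

from .features import AttributedSubgraph

__all__ = [
    "ModelConfig",
    "TrainedModel",
    "GraphBatch",
    "init_model",
    "gcn_forward",
    "gat_attention",
    "gat_forward",
    "readout",
    "classify",
    "loss",
    "Adam",
]

_EPS = 1e-12


@dataclass
class ModelConfig:
    """Architecture and optimisation hyper-parameters.

    Defaults follow the tuned values where they are known (learning rate
    0.001, batch size 64, 60 epochs, dropout 0.5) and declared choices
    elsewhere (3 attention layers of width 32, single head).
    """

    input_dim: int
    gcn_dim: int = 32
    gat_layers: int = 3
    gat_dim: int = 32
    attention_heads: int = 1
    negative_slope: float = 0.2
    dropout: float = 0.5
    learning_rate: float = 0.001
    batch_size: int = 64
    epochs: int = 60
    seed: int = 0
    attention: str = "additive"  # or "dot"
    loss_reduction: str = "sum"  # or "mean"

    def __post_init__(self) -> None:
        if min(self.input_dim, self.gcn_dim, self.gat_dim, self.gat_layers) < 1:
            raise ValueError("all dimensions must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.attention_heads != 1:
            raise NotImplementedError("only a single attention head is supported")
        if self.attention not in ("additive", "dot"):
            raise ValueError(f"unknown attention {self.attention!r}")
        if self.loss_reduction not in ("sum", "mean"):
            raise ValueError(f"unknown reduction {self.loss_reduction!r}")


# ---------------------------------------------------------------------------
# batching
# ---------------------------------------------------------------------------


class GraphBatch:
    """A list of attributed subgraphs packed as one block-diagonal graph."""

    def __init__(self, graphs: list[AttributedSubgraph]):
        if not graphs:
            raise ValueError("empty batch")
        xs, srcs, dsts, tpos, ys = [], [], [], [], []
        offset = 0
        for g in graphs:
            n = g.n_nodes
            xs.append(g.x)
            for u, v in g.edges:
                srcs += [u + offset, v + offset]
                dsts += [v + offset, u + offset]
            # self-loops for every node
            srcs += list(range(offset, offset + n))
            dsts += list(range(offset, offset + n))
            tl, td = g.target_positions
            tpos.append((tl + offset, td + offset))
            ys.append(-1 if g.y is None else int(g.y))
            offset += n
        self.x = np.concatenate(xs, axis=0)
        self.n_nodes = offset
        self.src = np.asarray(srcs, dtype=np.intp)
        self.dst = np.asarray(dsts, dtype=np.intp)
        self.target_positions = np.asarray(tpos, dtype=np.intp)  # (B, 2)
        self.y = np.asarray(ys, dtype=np.intp)
        self.n_graphs = len(graphs)
        deg = np.zeros(self.n_nodes)
        np.add.at(deg, self.dst, 1.0)  # includes the self-loop
        self.gcn_norm = 1.0 / np.sqrt(deg[self.src] * deg[self.dst])


# ---------------------------------------------------------------------------
# layer primitives (stateless; used by the model and by oracle tests)
# ---------------------------------------------------------------------------


def gcn_forward(x: np.ndarray, edges: list[tuple[int, int]], W: np.ndarray) -> np.ndarray:
    """Degree-normalised graph convolution over an undirected edge list.

    Self-loops are added internally; degrees are counted after adding them.
    """
    n = x.shape[0]
    src, dst = _directed_with_loops(n, edges)
    deg = np.zeros(n)
    np.add.at(deg, dst, 1.0)
    norm = 1.0 / np.sqrt(deg[src] * deg[dst])
    xw = x @ W
    out = np.zeros((n, W.shape[1]))
    np.add.at(out, dst, norm[:, None] * xw[src])
    return out


def _directed_with_loops(n, edges):
    src, dst = [], []
    for u, v in edges:
        src += [u, v]
        dst += [v, u]
    src += list(range(n))
    dst += list(range(n))
    return np.asarray(src, dtype=np.intp), np.asarray(dst, dtype=np.intp)


def _segment_softmax(scores: np.ndarray, dst: np.ndarray, n: int) -> np.ndarray:
    mx = np.full(n, -np.inf)
    np.maximum.at(mx, dst, scores)
    ex = np.exp(scores - mx[dst])
    den = np.zeros(n)
    np.add.at(den, dst, ex)
    return ex / den[dst]


def gat_attention(
    h: np.ndarray,
    edges: list[tuple[int, int]],
    W: np.ndarray,
    a_dst: np.ndarray,
    a_src: np.ndarray,
    negative_slope: float = 0.2,
    attention: str = "additive",
) -> dict:
    """Attention weights alpha_ij over each node's neighbourhood.

    Returns per-edge arrays (src, dst, alpha) with self-loops included;
    alpha sums to 1 over the incoming edges of every node.
    """
    n = h.shape[0]
    src, dst = _directed_with_loops(n, edges)
    z = h @ W
    if attention == "additive":
        pre = z @ a_dst
        pre = pre[dst] + (z @ a_src)[src]
        e = np.where(pre > 0, pre, negative_slope * pre)
    else:  # dot-product attention
        e = (z[dst] * z[src]).sum(axis=1) / np.sqrt(z.shape[1])
    alpha = _segment_softmax(e, dst, n)
    return {"src": src, "dst": dst, "alpha": alpha, "z": z}


def gat_forward(
    h: np.ndarray,
    edges: list[tuple[int, int]],
    W: np.ndarray,
    a_dst: np.ndarray,
    a_src: np.ndarray,
    negative_slope: float = 0.2,
    attention: str = "additive",
) -> np.ndarray:
    """One attention layer in evaluation mode: ELU(sum_j alpha_ij W h_j)."""
    att = gat_attention(h, edges, W, a_dst, a_src, negative_slope, attention)
    n = h.shape[0]
    m = np.zeros((n, W.shape[1]))
    np.add.at(m, att["dst"], att["alpha"][:, None] * att["z"][att["src"]])
    return _elu(m)


def readout(h_final: np.ndarray, target_positions) -> np.ndarray:
    """Graph vector: concatenation of the two target-node representations."""
    tl, td = target_positions
    if not (0 <= tl < h_final.shape[0] and 0 <= td < h_final.shape[0]):
        raise IndexError("target position out of range")
    return np.concatenate([h_final[tl], h_final[td]])


def classify(g: np.ndarray, W_out: np.ndarray, b_out: np.ndarray) -> np.ndarray:
    """Softmax probabilities (p0, p1) from a graph vector."""
    logits = g @ W_out + b_out
    logits = logits - logits.max(axis=-1, keepdims=True)
    ex = np.exp(logits)
    return ex / ex.sum(axis=-1, keepdims=True)


def loss(probs: np.ndarray, labels: np.ndarray, reduction: str = "sum") -> float:
    """Cross-entropy over a batch; probabilities clamped at 1e-12."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=np.intp)
    if probs.ndim == 1:
        probs = probs[None, :]
        labels = labels.reshape(1)
    p = np.clip(probs[np.arange(len(labels)), labels], _EPS, 1.0)
    total = float(-np.log(p).sum())
    return total / len(labels) if reduction == "mean" else total


def _elu(m: np.ndarray) -> np.ndarray:
    return np.where(m > 0, m, np.expm1(np.minimum(m, 0.0)))


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


@dataclass
class TrainedModel:
    """Model configuration plus learned parameter tensors."""

    config: ModelConfig
    params: dict = field(default_factory=dict)
    loss_history: list = field(default_factory=list)

    # -- persistence ---------------------------------------------------

    def save(self, path) -> None:
        meta = json.dumps(asdict(self.config))
        np.savez(
            path,
            __config__=np.frombuffer(meta.encode(), dtype=np.uint8),
            __loss__=np.asarray(self.loss_history, dtype=float),
            **self.params,
        )

    @classmethod
    def load(cls, path) -> "TrainedModel":
        data = np.load(path if str(path).endswith(".npz") else f"{path}.npz")
        meta = json.loads(bytes(data["__config__"]).decode())
        params = {k: data[k] for k in data.files if not k.startswith("__")}
        model = cls(ModelConfig(**meta), params)
        model.loss_history = data["__loss__"].tolist()
        return model

    # -- forward -------------------------------------------------------

    def _layer_dims(self):
        cfg = self.config
        dims = []
        d_in = cfg.gcn_dim
        for _ in range(cfg.gat_layers):
            dims.append((d_in, cfg.gat_dim))
            d_in = cfg.gat_dim
        return dims

    def forward(self, batch: GraphBatch, training: bool = False, rng=None):
        """Full forward pass; returns (probs, cache for backprop)."""
        cfg = self.config
        p = self.params
        keep = 1.0 - cfg.dropout
        if training and cfg.dropout > 0 and rng is None:
            raise ValueError("training-mode forward needs an rng for dropout")

        cache: dict = {"layers": []}
        xw = batch.x @ p["W_gcn"]
        h = np.zeros((batch.n_nodes, cfg.gcn_dim))
        np.add.at(h, batch.dst, batch.gcn_norm[:, None] * xw[batch.src])
        cache["gcn_out"] = h

        for li in range(cfg.gat_layers):
            lc: dict = {"h_in": h}
            if training and cfg.dropout > 0:
                mask = (rng.random(h.shape) >= cfg.dropout) / keep
            else:
                mask = None
            hd = h * mask if mask is not None else h
            z = hd @ p[f"W_gat{li}"]
            if cfg.attention == "additive":
                s = z @ p[f"a_dst{li}"]
                r = z @ p[f"a_src{li}"]
                pre = s[batch.dst] + r[batch.src]
                e = np.where(pre > 0, pre, cfg.negative_slope * pre)
            else:
                pre = (z[batch.dst] * z[batch.src]).sum(axis=1) / np.sqrt(z.shape[1])
                e = pre
            alpha_raw = _segment_softmax(e, batch.dst, batch.n_nodes)
            if training and cfg.dropout > 0:
                amask = (rng.random(alpha_raw.shape) >= cfg.dropout) / keep
            else:
                amask = None
            alpha = alpha_raw * amask if amask is not None else alpha_raw
            m = np.zeros((batch.n_nodes, cfg.gat_dim))
            np.add.at(m, batch.dst, alpha[:, None] * z[batch.src])
            h = _elu(m)
            lc.update(mask=mask, hd=hd, z=z, pre=pre, alpha_raw=alpha_raw,
                      amask=amask, alpha=alpha, m=m, h_out=h)
            cache["layers"].append(lc)

        tl = batch.target_positions[:, 0]
        td = batch.target_positions[:, 1]
        g = np.concatenate([h[tl], h[td]], axis=1)
        probs = classify(g, p["W_out"], p["b_out"])
        cache.update(h_final=h, g=g, probs=probs)
        return probs, cache

    def predict_proba(self, graphs: list[AttributedSubgraph], batch_size: int | None = None) -> np.ndarray:
        """Deterministic evaluation-mode class probabilities, one row per graph."""
        bs = batch_size or self.config.batch_size
        out = []
        for i in range(0, len(graphs), bs):
            probs, _ = self.forward(GraphBatch(graphs[i : i + bs]), training=False)
            out.append(probs)
        return np.concatenate(out, axis=0)

    def predict_score(self, graphs: list[AttributedSubgraph]) -> np.ndarray:
        """Association score p1 per subgraph."""
        return self.predict_proba(graphs)[:, 1]

    # -- backward ------------------------------------------------------

    def loss_and_grads(self, batch: GraphBatch, rng=None):
        """Training-mode forward + full backward pass.

        Returns (loss value, gradient dict keyed like ``params``).
        """
        cfg = self.config
        p = self.params
        keep = 1.0 - cfg.dropout
        probs, cache = self.forward(batch, training=True, rng=rng)
        y = batch.y
        if (y < 0).any():
            raise ValueError("batch contains unlabeled subgraphs")
        lval = loss(probs, y, cfg.loss_reduction)

        grads = {k: np.zeros_like(v) for k, v in p.items()}
        B = batch.n_graphs
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        if cfg.loss_reduction == "mean":
            dlogits /= B

        g = cache["g"]
        grads["W_out"] = g.T @ dlogits
        grads["b_out"] = dlogits.sum(axis=0)
        dg = dlogits @ p["W_out"].T

        d = cfg.gat_dim
        dh = np.zeros((batch.n_nodes, d))
        np.add.at(dh, batch.target_positions[:, 0], dg[:, :d])
        np.add.at(dh, batch.target_positions[:, 1], dg[:, d:])

        src, dst = batch.src, batch.dst
        for li in reversed(range(cfg.gat_layers)):
            lc = cache["layers"][li]
            m, z = lc["m"], lc["z"]
            dm = dh * np.where(m > 0, 1.0, np.exp(np.minimum(m, 0.0)))
            dalpha = (dm[dst] * z[src]).sum(axis=1)
            dz = np.zeros_like(z)
            np.add.at(dz, src, lc["alpha"][:, None] * dm[dst])
            if lc["amask"] is not None:
                dalpha = dalpha * lc["amask"]
            # softmax over incoming edges of each destination node
            ar = lc["alpha_raw"]
            sacc = np.zeros(batch.n_nodes)
            np.add.at(sacc, dst, ar * dalpha)
            de = ar * (dalpha - sacc[dst])
            if cfg.attention == "additive":
                dpre = de * np.where(lc["pre"] > 0, 1.0, cfg.negative_slope)
                ds = np.zeros(batch.n_nodes)
                dr = np.zeros(batch.n_nodes)
                np.add.at(ds, dst, dpre)
                np.add.at(dr, src, dpre)
                grads[f"a_dst{li}"] = z.T @ ds
                grads[f"a_src{li}"] = z.T @ dr
                dz += ds[:, None] * p[f"a_dst{li}"] + dr[:, None] * p[f"a_src{li}"]
            else:
                scale = 1.0 / np.sqrt(z.shape[1])
                np.add.at(dz, dst, de[:, None] * z[src] * scale)
                np.add.at(dz, src, de[:, None] * z[dst] * scale)
            grads[f"W_gat{li}"] = lc["hd"].T @ dz
            dh = dz @ p[f"W_gat{li}"].T
            if lc["mask"] is not None:
                dh = dh * lc["mask"]

        # GCN layer
        dxw = np.zeros((batch.n_nodes, cfg.gcn_dim))
        np.add.at(dxw, src, batch.gcn_norm[:, None] * dh[dst])
        grads["W_gcn"] = batch.x.T @ dxw
        return lval, grads


def _glorot(rng, fan_in, fan_out, shape=None):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


def init_model(config: ModelConfig, seed: int | None = None) -> TrainedModel:
    """Deterministic Glorot-uniform initialisation from a seed."""
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    cfg = config
    params = {"W_gcn": _glorot(rng, cfg.input_dim, cfg.gcn_dim)}
    d_in = cfg.gcn_dim
    for li in range(cfg.gat_layers):
        params[f"W_gat{li}"] = _glorot(rng, d_in, cfg.gat_dim)
        params[f"a_dst{li}"] = _glorot(rng, cfg.gat_dim, 1, shape=(cfg.gat_dim,))
        params[f"a_src{li}"] = _glorot(rng, cfg.gat_dim, 1, shape=(cfg.gat_dim,))
        d_in = cfg.gat_dim
    params["W_out"] = _glorot(rng, 2 * cfg.gat_dim, 2)
    params["b_out"] = np.zeros(2)
    return TrainedModel(config, params)


def parameter_count(config: ModelConfig) -> int:
    """Closed-form number of learnable scalars for a configuration."""
    n = config.input_dim * config.gcn_dim
    d_in = config.gcn_dim
    for _ in range(config.gat_layers):
        n += d_in * config.gat_dim + 2 * config.gat_dim
        d_in = config.gat_dim
    n += 2 * config.gat_dim * 2 + 2
    return n


class Adam:
    """Adam optimiser over a named parameter dict."""

    def __init__(self, params: dict, lr: float = 0.001, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            self.params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
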