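"""Neural-aggregation node embeddings: GCN, GAT and GraphSAGE encoders.

One encoder with shared parameters is trained on a uniformly sampled
subset of frames under an unsupervised link-prediction objective
(positives = observed edges, negatives sampled uniformly from non-edges,
binary cross-entropy on the sigmoid of embedding inner products), then
applied to every frame with a deterministic inference pass.

Node input features are the one-hot node identity concatenated with the
node's weighted degree: identity is frame-constant so all frame-to-frame
signal flows through the edges, while the degree injects local geometry.

The encoders are small dense NumPy implementations with hand-written
backward passes; node counts are residue counts (a few hundred), so dense
|V| x |V| propagation is cheap and exactly reproducible under a seed.
"""

from __future__ import annotations

import numpy as np

from trajembed.embeddings.config import EmbeddingConfig
from trajembed.embeddings.series import EmbeddingSeries, FrameEmbedding
from trajembed.errors import ArgumentError, TrainingError
from trajembed.graph_builder import ContactGraph, GraphSeries

_LEAKY_SLOPE = 0.2


def _node_features(graph: ContactGraph) -> np.ndarray:
    """One-hot identity plus weighted degree, shape (|V|, |V| + 1)."""
    n = graph.n_nodes
    deg = np.zeros(n)
    if graph.edge_index.size:
        np.add.at(deg, graph.edge_index[:, 0], graph.weights)
        np.add.at(deg, graph.edge_index[:, 1], graph.weights)
    return np.hstack([np.eye(n), deg[:, None]])


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    scale = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, scale, size=(fan_in, fan_out))


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -35, 35)))


# ---------------------------------------------------------------------------
# encoders


class _GCNEncoder:
    """Symmetric-normalized weighted adjacency propagation."""

    def __init__(self, dims: list[int], rng: np.random.Generator):
        self.params: dict[str, np.ndarray] = {}
        for l in range(len(dims) - 1):
            self.params[f"W{l}"] = _glorot(rng, dims[l], dims[l + 1])
            self.params[f"b{l}"] = np.zeros(dims[l + 1])
        self.n_layers = len(dims) - 1

    @staticmethod
    def _norm_adjacency(graph: ContactGraph) -> np.ndarray:
        a = graph.adjacency() + np.eye(graph.n_nodes)
        dinv = 1.0 / np.sqrt(a.sum(axis=1))
        return a * dinv[:, None] * dinv[None, :]

    def forward(self, graph: ContactGraph, x: np.ndarray, train: bool,
                rng: np.random.Generator | None):
        ahat = self._norm_adjacency(graph)
        h = x
        caches = []
        for l in range(self.n_layers):
            p = ahat @ h
            zpre = p @ self.params[f"W{l}"] + self.params[f"b{l}"]
            caches.append((p, zpre))
            h = zpre if l == self.n_layers - 1 else _relu(zpre)
        return h, (ahat, x, caches)

    def backward(self, cache, dz: np.ndarray) -> dict[str, np.ndarray]:
        ahat, x, caches = cache
        grads: dict[str, np.ndarray] = {}
        dh = dz
        for l in reversed(range(self.n_layers)):
            p, zpre = caches[l]
            dzpre = dh if l == self.n_layers - 1 else dh * (zpre > 0)
            grads[f"W{l}"] = p.T @ dzpre
            grads[f"b{l}"] = dzpre.sum(axis=0)
            dp = dzpre @ self.params[f"W{l}"].T
            dh = ahat @ dp  # ahat is symmetric
        return grads


class _SAGEEncoder:
    """Mean aggregation over (sampled) neighborhoods, concatenated with self."""

    def __init__(self, dims: list[int], sample_sizes: tuple[int, ...],
                 rng: np.random.Generator):
        self.params: dict[str, np.ndarray] = {}
        for l in range(len(dims) - 1):
            self.params[f"W{l}"] = _glorot(rng, 2 * dims[l], dims[l + 1])
            self.params[f"b{l}"] = np.zeros(dims[l + 1])
        self.n_layers = len(dims) - 1
        self.sample_sizes = sample_sizes

    def _mean_matrix(self, graph: ContactGraph, layer: int, train: bool,
                     rng: np.random.Generator | None) -> np.ndarray:
        nbrs, _ = graph.neighbor_lists()
        n = graph.n_nodes
        m = np.zeros((n, n))
        size = self.sample_sizes[min(layer, len(self.sample_sizes) - 1)]
        for i, cand in enumerate(nbrs):
            if cand.size == 0:
                continue  # empty-neighborhood aggregate stays zero
            if train and rng is not None and cand.size > size:
                cand = rng.choice(cand, size=size, replace=False)
            m[i, cand] = 1.0 / cand.size
        return m

    def forward(self, graph: ContactGraph, x: np.ndarray, train: bool,
                rng: np.random.Generator | None):
        h = x
        caches = []
        for l in range(self.n_layers):
            m = self._mean_matrix(graph, l, train, rng)
            c = np.hstack([h, m @ h])
            zpre = c @ self.params[f"W{l}"] + self.params[f"b{l}"]
            caches.append((m, c, zpre, h.shape[1]))
            h = zpre if l == self.n_layers - 1 else _relu(zpre)
        return h, caches

    def backward(self, caches, dz: np.ndarray) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        dh = dz
        for l in reversed(range(self.n_layers)):
            m, c, zpre, in_dim = caches[l]
            dzpre = dh if l == self.n_layers - 1 else dh * (zpre > 0)
            grads[f"W{l}"] = c.T @ dzpre
            grads[f"b{l}"] = dzpre.sum(axis=0)
            dc = dzpre @ self.params[f"W{l}"].T
            dh = dc[:, :in_dim] + m.T @ dc[:, in_dim:]
        return grads


class _GATEncoder:
    """Learned attention coefficients, softmax-normalized over neighborhoods.

    Hidden layers concatenate ``heads`` attention heads; the output layer
    uses a single head. Self-loops are always part of the neighborhood.
    """

    def __init__(self, dims: list[int], heads: int, rng: np.random.Generator):
        self.n_layers = len(dims) - 1
        self.heads_per_layer = [heads] * (self.n_layers - 1) + [1]
        self.params: dict[str, np.ndarray] = {}
        in_dim = dims[0]
        for l in range(self.n_layers):
            nh = self.heads_per_layer[l]
            out = dims[l + 1] if l == self.n_layers - 1 else dims[l + 1] // nh
            if out < 1:
                raise ArgumentError("hidden_dim must be >= attention_heads for GAT")
            for k in range(nh):
                self.params[f"W{l}_{k}"] = _glorot(rng, in_dim, out)
                self.params[f"asrc{l}_{k}"] = rng.normal(0, 0.1, size=out)
                self.params[f"adst{l}_{k}"] = rng.normal(0, 0.1, size=out)
            in_dim = out * nh

    def forward(self, graph: ContactGraph, x: np.ndarray, train: bool,
                rng: np.random.Generator | None):
        n = graph.n_nodes
        mask = (graph.adjacency() > 0) | np.eye(n, dtype=bool)
        h = x
        caches = []
        for l in range(self.n_layers):
            head_outs, head_caches = [], []
            for k in range(self.heads_per_layer[l]):
                s = h @ self.params[f"W{l}_{k}"]
                alpha = s @ self.params[f"asrc{l}_{k}"]
                beta = s @ self.params[f"adst{l}_{k}"]
                logits = alpha[:, None] + beta[None, :]
                pre = np.where(logits > 0, logits, _LEAKY_SLOPE * logits)
                e = np.where(mask, pre, -np.inf)
                e = e - e.max(axis=1, keepdims=True)
                expo = np.exp(e)
                att = expo / expo.sum(axis=1, keepdims=True)
                head_outs.append(att @ s)
                head_caches.append((s, logits, att))
            zpre = np.hstack(head_outs)
            caches.append((h, mask, head_caches, zpre))
            h = zpre if l == self.n_layers - 1 else _relu(zpre)
        return h, caches

    def backward(self, caches, dz: np.ndarray) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        dh = dz
        for l in reversed(range(self.n_layers)):
            h_in, mask, head_caches, zpre = caches[l]
            dzpre = dh if l == self.n_layers - 1 else dh * (zpre > 0)
            dh_in = np.zeros_like(h_in)
            col = 0
            for k, (s, logits, att) in enumerate(head_caches):
                out = s.shape[1]
                dhead = dzpre[:, col:col + out]
                col += out
                datt = dhead @ s.T
                ds = att.T @ dhead
                # softmax backward (rows); att is 0 off-mask so dpre is too
                dpre = att * (datt - (datt * att).sum(axis=1, keepdims=True))
                dlogits = dpre * np.where(logits > 0, 1.0, _LEAKY_SLOPE)
                dalpha = dlogits.sum(axis=1)
                dbeta = dlogits.sum(axis=0)
                ds += np.outer(dalpha, self.params[f"asrc{l}_{k}"])
                ds += np.outer(dbeta, self.params[f"adst{l}_{k}"])
                grads[f"asrc{l}_{k}"] = s.T @ dalpha
                grads[f"adst{l}_{k}"] = s.T @ dbeta
                grads[f"W{l}_{k}"] = h_in.T @ ds
                dh_in += ds @ self.params[f"W{l}_{k}"].T
            dh = dh_in
        return grads


# ---------------------------------------------------------------------------
# training


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _link_prediction_loss(
    z: np.ndarray, graph: ContactGraph, negative_ratio: float,
    rng: np.random.Generator,
) -> tuple[float, np.ndarray]:
    """BCE on sigmoid inner products; returns (loss, dL/dz)."""
    n = graph.n_nodes
    dz = np.zeros_like(z)
    if graph.n_edges == 0:
        return 0.0, dz
    pos = graph.edge_index
    n_neg = max(1, int(round(negative_ratio * graph.n_edges)))
    existing = graph.edge_set()
    cand = rng.integers(0, n, size=(4 * n_neg + 16, 2))
    cand = np.sort(cand, axis=1)
    ok = cand[:, 0] < cand[:, 1]
    cand = cand[ok]
    neg_rows = [tuple(r) for r in cand if tuple(r) not in existing][:n_neg]
    neg = np.array(neg_rows, dtype=np.int64).reshape(-1, 2)

    pairs = np.vstack([pos, neg])
    labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    i, j = pairs[:, 0], pairs[:, 1]
    scores = np.einsum("ed,ed->e", z[i], z[j])
    sig = _sigmoid(scores)
    eps = 1e-12
    loss = -np.mean(labels * np.log(sig + eps) + (1 - labels) * np.log(1 - sig + eps))
    g = (sig - labels) / labels.size
    np.add.at(dz, i, g[:, None] * z[j])
    np.add.at(dz, j, g[:, None] * z[i])
    return float(loss), dz


def _build_encoder(config: EmbeddingConfig, input_dim: int, rng: np.random.Generator):
    dims = [input_dim] + [config.hidden_dim] * (config.n_layers - 1) + [config.dimension]
    if config.method == "gcn":
        return _GCNEncoder(dims, rng)
    if config.method == "graphsage":
        return _SAGEEncoder(dims, config.sample_sizes, rng)
    if config.method == "gat":
        return _GATEncoder(dims, config.attention_heads, rng)
    raise ArgumentError(f"unknown GNN method {config.method!r}")


def gnn_embed(series: GraphSeries, config: EmbeddingConfig) -> EmbeddingSeries:
    """Train a shared encoder by link prediction, then embed every frame."""
    if config.method not in ("gcn", "gat", "graphsage"):
        raise ArgumentError(f"config.method must be a GNN method, got {config.method!r}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x9A11]))
    n_frames = len(series)
    encoder = _build_encoder(config, series.n_nodes + 1, rng)
    opt = _Adam(encoder.params, config.gnn_learning_rate)

    k = min(max(1, int(round(config.training_frame_sample * n_frames))),
            config.max_training_frames, n_frames)
    train_idx = np.sort(rng.choice(n_frames, size=k, replace=False))
    features = {int(f): _node_features(series[f]) for f in train_idx}

    for epoch in range(config.gnn_epochs):
        for f in train_idx:
            graph = series[int(f)]
            z, cache = encoder.forward(graph, features[int(f)], train=True, rng=rng)
            loss, dz = _link_prediction_loss(z, graph, config.negative_ratio, rng)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite link-prediction loss at epoch {epoch}")
            grads = encoder.backward(cache, dz)
            opt.step(grads)

    frames = []
    for f in range(n_frames):
        graph = series[f]
        z, _ = encoder.forward(graph, _node_features(graph), train=False, rng=None)
        frames.append(FrameEmbedding(matrix=z, frame_index=graph.frame_index))
    return EmbeddingSeries(frames=frames, config=config)
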