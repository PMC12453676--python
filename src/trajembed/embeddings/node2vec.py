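"""node2vec: second-order biased random walks + skip-gram with negative sampling.

The walk bias follows the standard return/in-out rule: stepping from
``current`` having arrived from ``previous``, neighbor ``x`` is chosen with
probability proportional to ``w(current, x) * bias`` where bias is ``1/p``
if ``x == previous``, ``1`` if ``x`` is adjacent to ``previous``, and
``1/q`` otherwise. The first step of a walk has no previous node and uses
edge-weight-proportional probabilities.

The skip-gram model (negative sampling, linear-decay SGD) is implemented
directly in NumPy so runs are fully seed-deterministic.
"""

from __future__ import annotations

import warnings

import numpy as np

from trajembed.embeddings.config import EmbeddingConfig
from trajembed.embeddings.series import EmbeddingSeries, FrameEmbedding
from trajembed.errors import ArgumentError, IntegrityError
from trajembed.graph_builder import ContactGraph, GraphSeries


class WalkTermination(Exception):
    """Signal: the walk cannot continue (isolated current node)."""


def node2vec_transition_probs(
    graph: ContactGraph,
    previous_node: int | None,
    current_node: int,
    p: float,
    q: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Transition distribution over neighbors of ``current_node``.

    Returns ``(neighbors, probabilities)``; probabilities sum to 1.
    Raises :class:`WalkTermination` if the current node is isolated.
    """
    if p <= 0 or q <= 0:
        raise ArgumentError(f"p and q must be positive, got p={p}, q={q}")
    nbr_lists, wt_lists = _cached_neighbors(graph)
    nbrs = nbr_lists[current_node]
    if nbrs.size == 0:
        raise WalkTermination(f"node {current_node} has no neighbors")
    weights = wt_lists[current_node].copy()
    if previous_node is not None:
        prev_nbrs = set(nbr_lists[previous_node].tolist())
        bias = np.empty_like(weights)
        for k, x in enumerate(nbrs):
            if x == previous_node:
                bias[k] = 1.0 / p
            elif int(x) in prev_nbrs:
                bias[k] = 1.0
            else:
                bias[k] = 1.0 / q
        weights = weights * bias
    return nbrs, weights / weights.sum()


def _cached_neighbors(graph: ContactGraph):
    cache = getattr(graph, "_nbr_cache", None)
    if cache is None:
        cache = graph.neighbor_lists()
        graph._nbr_cache = cache
    return cache


def sample_walks(
    graph: ContactGraph,
    num_walks: int,
    walk_length: int,
    p: float,
    q: float,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Sample ``num_walks`` biased walks per node; isolated nodes yield length-1 walks."""
    walks = []
    for _ in range(num_walks):
        for start in range(graph.n_nodes):
            walk = [start]
            prev: int | None = None
            for _ in range(walk_length - 1):
                try:
                    nbrs, probs = node2vec_transition_probs(graph, prev, walk[-1], p, q)
                except WalkTermination:
                    break
                nxt = int(rng.choice(nbrs, p=probs))
                prev = walk[-1]
                walk.append(nxt)
            walks.append(np.array(walk, dtype=np.int64))
    return walks


def _skipgram_pairs(walks: list[np.ndarray], window: int) -> np.ndarray:
    """All (center, context) pairs within the fixed window, as an (N, 2) array."""
    pairs = []
    for walk in walks:
        n = walk.size
        for c in range(n):
            lo, hi = max(0, c - window), min(n, c + window + 1)
            for t in range(lo, hi):
                if t != c:
                    pairs.append((walk[c], walk[t]))
    if not pairs:
        return np.empty((0, 2), dtype=np.int64)
    return np.array(pairs, dtype=np.int64)


def _train_skipgram(
    pairs: np.ndarray,
    n_nodes: int,
    dim: int,
    epochs: int,
    lr: float,
    negative: int,
    rng: np.random.Generator,
    w_in: np.ndarray,
    w_out: np.ndarray,
    batch_size: int = 2048,
) -> None:
    """In-place SGD on the input/output vector tables (word2vec-style)."""
    if pairs.shape[0] == 0:
        return
    counts = np.bincount(pairs[:, 1], minlength=n_nodes).astype(np.float64)
    noise = counts ** 0.75
    noise /= noise.sum()
    n_pairs = pairs.shape[0]
    total_steps = max(1, epochs * ((n_pairs + batch_size - 1) // batch_size))
    step = 0
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        for lo in range(0, n_pairs, batch_size):
            batch = pairs[order[lo:lo + batch_size]]
            centers, contexts = batch[:, 0], batch[:, 1]
            b = centers.size
            negs = rng.choice(n_nodes, size=(b, negative), p=noise)
            targets = np.concatenate([contexts[:, None], negs], axis=1)  # (b, 1+neg)
            labels = np.zeros((b, 1 + negative))
            labels[:, 0] = 1.0
            alpha = lr * max(1e-4 / lr, 1.0 - step / total_steps)  # linear decay
            v = w_in[centers]                       # (b, d)
            u = w_out[targets]                      # (b, K, d)
            raw = np.clip(np.einsum("bkd,bd->bk", u, v), -35, 35)
            score = 1.0 / (1.0 + np.exp(-raw))
            g = (labels - score) * alpha            # (b, K)
            d_v = np.einsum("bk,bkd->bd", g, u)
            d_u = g[:, :, None] * v[:, None, :]
            np.add.at(w_out, targets.ravel(), d_u.reshape(-1, dim))
            np.add.at(w_in, centers, d_v)
            step += 1


def node2vec_embed(series: GraphSeries, config: EmbeddingConfig) -> EmbeddingSeries:
    """Embed every frame with per-frame skip-gram fits on biased-walk corpora.

    Frame t+1's vectors are warm-started from frame t's fitted vectors
    (``config.warm_start``) so consecutive frames stay in a common
    orientation; a frame whose graph is bit-identical to its predecessor
    reuses the predecessor's fitted matrix.
    """
    if config.method != "node2vec":
        raise ArgumentError(f"config.method must be 'node2vec', got {config.method!r}")
    n = series.n_nodes
    if n == 0:
        raise IntegrityError("cannot embed an empty graph")
    d = config.dimension
    if d >= n:
        warnings.warn(
            f"embedding dimension {d} >= node count {n}; embeddings will be overparameterized"
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x6E32]))
    w_in = (rng.random((n, d)) - 0.5) / d
    w_out = np.zeros((n, d))
    init_in, init_out = w_in.copy(), w_out.copy()

    frames: list[FrameEmbedding] = []
    prev_graph: ContactGraph | None = None
    prev_matrix: np.ndarray | None = None
    for k, graph in enumerate(series):
        if prev_graph is not None and _same_graph(graph, prev_graph):
            frames.append(FrameEmbedding(matrix=prev_matrix.copy(), frame_index=graph.frame_index))
            continue
        if not config.warm_start:
            w_in, w_out = init_in.copy(), init_out.copy()
        frame_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x6E32, k]))
        walks = sample_walks(
            graph, config.num_walks, config.walk_length, config.p, config.q, frame_rng
        )
        pairs = _skipgram_pairs(walks, config.window)
        _train_skipgram(
            pairs, n, d, config.epochs, config.learning_rate,
            config.negative, frame_rng, w_in, w_out,
        )
        prev_matrix = w_in.copy()
        prev_graph = graph
        frames.append(FrameEmbedding(matrix=prev_matrix.copy(), frame_index=graph.frame_index))
    return EmbeddingSeries(frames=frames, config=config)


def _same_graph(a: ContactGraph, b: ContactGraph) -> bool:
    return (
        a.n_nodes == b.n_nodes
        and a.edge_index.shape == b.edge_index.shape
        and np.array_equal(a.edge_index, b.edge_index)
        and np.array_equal(a.weights, b.weights)
    )
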