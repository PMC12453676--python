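"""Per-frame node embeddings: biased random walks (node2vec) and GNN encoders.

All methods map a :class:`~trajembed.graph_builder.GraphSeries` to an
:class:`EmbeddingSeries` of ``|V| x d`` matrices, one per frame. The GNN
methods (gcn, gat, graphsage) train a single shared encoder on a sampled
subset of frames under an unsupervised link-prediction objective and then
run a deterministic inference pass on every frame; node2vec fits a
skip-gram model per frame on walk corpora, warm-starting each frame from
the previous one so embeddings stay in a common orientation.
"""

from trajembed.embeddings.config import EmbeddingConfig
from trajembed.embeddings.series import (
    EmbeddingSeries,
    FrameEmbedding,
    load_embedding_series,
    save_embedding_series,
)
from trajembed.embeddings.node2vec import (
    WalkTermination,
    node2vec_embed,
    node2vec_transition_probs,
    sample_walks,
)
from trajembed.embeddings.gnn import gnn_embed

from trajembed.errors import ArgumentError
from trajembed.graph_builder import GraphSeries

GNN_METHODS = ("gcn", "gat", "graphsage")
METHODS = ("node2vec",) + GNN_METHODS


def embed_series(series: GraphSeries, config: EmbeddingConfig) -> EmbeddingSeries:
    """Dispatch to the configured embedding method."""
    if config.method == "node2vec":
        return node2vec_embed(series, config)
    if config.method in GNN_METHODS:
        return gnn_embed(series, config)
    raise ArgumentError(f"unknown embedding method {config.method!r}; choose from {METHODS}")


__all__ = [
    "EmbeddingConfig",
    "EmbeddingSeries",
    "FrameEmbedding",
    "GNN_METHODS",
    "METHODS",
    "WalkTermination",
    "embed_series",
    "gnn_embed",
    "load_embedding_series",
    "node2vec_embed",
    "node2vec_transition_probs",
    "sample_walks",
    "save_embedding_series",
]
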