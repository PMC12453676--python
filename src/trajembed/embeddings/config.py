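"""Embedding method configuration."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

from trajembed.errors import ArgumentError


@dataclass
class EmbeddingConfig:
    """Hyperparameters for one embedding run.

    ``method`` is one of ``node2vec``, ``gcn``, ``gat``, ``graphsage``.
    node2vec parameters follow the usual naming (return parameter ``p``,
    in-out parameter ``q``); GNN parameters configure the shared encoder
    trained by unsupervised link prediction.
    """

    method: str = "graphsage"
    dimension: int = 64
    seed: int = 0

    # node2vec
    num_walks: int = 10
    walk_length: int = 20
    p: float = 1.0
    q: float = 1.0
    window: int = 5
    negative: int = 5
    epochs: int = 3
    learning_rate: float = 0.025
    warm_start: bool = True

    # gnn
    n_layers: int = 2
    hidden_dim: int = 64
    attention_heads: int = 2
    sample_sizes: tuple[int, ...] = (10, 10)
    gnn_epochs: int = 40
    gnn_learning_rate: float = 0.01
    negative_ratio: float = 1.0
    training_frame_sample: float = 0.10
    max_training_frames: int = 200

    def __post_init__(self):
        if self.dimension < 1:
            raise ArgumentError(f"dimension must be >= 1, got {self.dimension}")
        if self.p <= 0 or self.q <= 0:
            raise ArgumentError(f"p and q must be positive, got p={self.p}, q={self.q}")
        for name in ("num_walks", "walk_length", "window", "negative", "epochs",
                     "n_layers", "hidden_dim", "attention_heads", "gnn_epochs"):
            if getattr(self, name) < 1:
                raise ArgumentError(f"{name} must be >= 1, got {getattr(self, name)}")
        if not 0 < self.training_frame_sample <= 1:
            raise ArgumentError("training_frame_sample must be in (0, 1]")
        self.sample_sizes = tuple(int(s) for s in self.sample_sizes)
        if any(s < 1 for s in self.sample_sizes):
            raise ArgumentError("sample_sizes entries must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sample_sizes"] = list(self.sample_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EmbeddingConfig":
        d = dict(d)
        if "sample_sizes" in d:
            d["sample_sizes"] = tuple(d["sample_sizes"])
        return cls(**d)
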