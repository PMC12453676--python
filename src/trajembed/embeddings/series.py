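"""Embedding result containers and their text persistence."""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

from trajembed.embeddings.config import EmbeddingConfig
from trajembed.errors import IntegrityError, ParseError


@dataclass
class FrameEmbedding:
    """One frame's node-embedding matrix; row i embeds node i."""

    matrix: np.ndarray  # (|V|, d)
    frame_index: int

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise IntegrityError(f"embedding matrix must be 2-D, got shape {self.matrix.shape}")
        if not np.all(np.isfinite(self.matrix)):
            raise IntegrityError(f"frame {self.frame_index}: embedding has non-finite entries")


@dataclass
class EmbeddingSeries:
    """Per-frame |V| x d embedding matrices under one trained model."""

    frames: list[FrameEmbedding]
    config: EmbeddingConfig

    def __post_init__(self):
        if not self.frames:
            raise IntegrityError("embedding series must contain at least one frame")
        shape = self.frames[0].matrix.shape
        for fe in self.frames:
            if fe.matrix.shape != shape:
                raise IntegrityError("all frame embeddings must share one |V| x d shape")

    @property
    def n_nodes(self) -> int:
        return self.frames[0].matrix.shape[0]

    @property
    def dimension(self) -> int:
        return self.frames[0].matrix.shape[1]

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i) -> FrameEmbedding:
        return self.frames[i]


def save_embedding_series(series: EmbeddingSeries, directory) -> None:
    """Persist as one delimited matrix per frame plus a JSON config sidecar."""
    os.makedirs(directory, exist_ok=True)
    with open(os.path.join(directory, "config.json"), "w") as fh:
        json.dump(
            {"config": series.config.to_dict(), "n_frames": len(series),
             "n_nodes": series.n_nodes, "dimension": series.dimension},
            fh, indent=2,
        )
    for fe in series.frames:
        path = os.path.join(directory, f"frame_{fe.frame_index:06d}.tsv")
        np.savetxt(path, fe.matrix, delimiter="\t", fmt="%.12g")


def load_embedding_series(directory) -> EmbeddingSeries:
    sidecar = os.path.join(directory, "config.json")
    if not os.path.exists(sidecar):
        raise ParseError(f"missing config sidecar in {directory}")
    with open(sidecar) as fh:
        meta = json.load(fh)
    config = EmbeddingConfig.from_dict(meta["config"])
    frames = []
    for name in sorted(os.listdir(directory)):
        if not name.startswith("frame_") or not name.endswith(".tsv"):
            continue
        idx = int(name[len("frame_"):-len(".tsv")])
        matrix = np.atleast_2d(np.loadtxt(os.path.join(directory, name), delimiter="\t"))
        frames.append(FrameEmbedding(matrix=matrix, frame_index=idx))
    if len(frames) != meta.get("n_frames", len(frames)):
        raise ParseError(
            f"expected {meta['n_frames']} frame files, found {len(frames)} in {directory}"
        )
    return EmbeddingSeries(frames=frames, config=config)
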