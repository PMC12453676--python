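"""Per-frame contact graphs: distance matrix -> cutoff-filtered weighted graph.

An edge links residues i and j iff their pairwise distance d satisfies
``d < cutoff`` (strict), with weight ``1 - d/cutoff`` (in (0, 1]).
Distances are rigid-motion invariant, so the graphs are too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from trajembed.errors import ArgumentError, IntegrityError, ParseError
from trajembed.trajectory_io import CoordinateEnsemble

DEFAULT_CUTOFF = 10.0


@dataclass
class DistanceMatrix:
    """Symmetric pairwise Euclidean distance matrix (Angstrom) for one frame."""

    values: np.ndarray
    frame_index: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise IntegrityError(f"distance matrix must be square, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise IntegrityError("distance matrix contains non-finite values")
        if np.any(v < 0):
            raise IntegrityError("distance matrix contains negative entries")
        if not np.allclose(v, v.T, atol=1e-8):
            raise IntegrityError("distance matrix is not symmetric")
        if np.any(np.abs(np.diagonal(v)) > 1e-8):
            raise IntegrityError("distance matrix diagonal is not zero")


@dataclass
class ContactGraph:
    """Undirected weighted contact graph on the selected residues.

    Edges are stored as parallel arrays ``edge_index`` (E x 2, i < j) and
    ``weights`` (E,), each weight equal to ``1 - d/cutoff`` for the
    generating distance d.
    """

    n_nodes: int
    edge_index: np.ndarray
    weights: np.ndarray
    cutoff: float
    frame_index: int = 0

    def __post_init__(self):
        self.edge_index = np.asarray(self.edge_index, dtype=np.int64).reshape(-1, 2)
        self.weights = np.asarray(self.weights, dtype=np.float64).reshape(-1)
        if self.edge_index.shape[0] != self.weights.shape[0]:
            raise IntegrityError("edge_index and weights disagree on edge count")
        if self.edge_index.size:
            i, j = self.edge_index[:, 0], self.edge_index[:, 1]
            if np.any(i >= j):
                raise IntegrityError("edges must satisfy i < j")
            if np.any(j >= self.n_nodes) or np.any(i < 0):
                raise IntegrityError("edge endpoint out of node range")
            if np.any(self.weights <= 0) or np.any(self.weights > 1):
                raise IntegrityError("edge weights must lie in (0, 1]")

    @property
    def n_edges(self) -> int:
        return self.edge_index.shape[0]

    def edge_set(self) -> set[tuple[int, int]]:
        return {(int(i), int(j)) for i, j in self.edge_index}

    def adjacency(self) -> np.ndarray:
        """Dense symmetric weighted adjacency matrix."""
        a = np.zeros((self.n_nodes, self.n_nodes))
        if self.edge_index.size:
            i, j = self.edge_index[:, 0], self.edge_index[:, 1]
            a[i, j] = self.weights
            a[j, i] = self.weights
        return a

    def neighbor_lists(self) -> tuple[list[np.ndarray], list[np.ndarray]]:
        """Per-node neighbor index arrays and matching edge weights."""
        nbrs: list[list[int]] = [[] for _ in range(self.n_nodes)]
        wts: list[list[float]] = [[] for _ in range(self.n_nodes)]
        for (i, j), w in zip(self.edge_index, self.weights):
            nbrs[i].append(int(j))
            wts[i].append(float(w))
            nbrs[j].append(int(i))
            wts[j].append(float(w))
        return (
            [np.array(n, dtype=np.int64) for n in nbrs],
            [np.array(w, dtype=np.float64) for w in wts],
        )

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_weighted_edges_from(
            (int(i), int(j), float(w)) for (i, j), w in zip(self.edge_index, self.weights)
        )
        return g


@dataclass
class GraphSeries:
    """Ordered per-frame contact graphs sharing one node set and cutoff."""

    graphs: list[ContactGraph]

    def __post_init__(self):
        if not self.graphs:
            raise IntegrityError("graph series must contain at least one graph")
        n = self.graphs[0].n_nodes
        c = self.graphs[0].cutoff
        for g in self.graphs:
            if g.n_nodes != n or g.cutoff != c:
                raise IntegrityError("all graphs must share node count and cutoff")

    @property
    def n_nodes(self) -> int:
        return self.graphs[0].n_nodes

    @property
    def cutoff(self) -> float:
        return self.graphs[0].cutoff

    def __len__(self) -> int:
        return len(self.graphs)

    def __iter__(self):
        return iter(self.graphs)

    def __getitem__(self, i) -> ContactGraph:
        return self.graphs[i]


def pairwise_distances(ensemble: CoordinateEnsemble, frame_index: int) -> DistanceMatrix:
    """Euclidean distance matrix between all selected atoms of one frame."""
    if not 0 <= frame_index < ensemble.n_frames:
        raise IndexError(f"frame index {frame_index} out of range [0, {ensemble.n_frames})")
    xyz = ensemble.coords[frame_index]
    if xyz.shape[0] == 1:
        values = np.zeros((1, 1))
    else:
        values = squareform(pdist(xyz))
    return DistanceMatrix(values=values, frame_index=frame_index)


def build_contact_graph(dm: DistanceMatrix, cutoff: float = DEFAULT_CUTOFF) -> ContactGraph:
    """Threshold a distance matrix into a weighted contact graph.

    Edge (i, j) exists iff d(i, j) < cutoff strictly; weight = 1 - d/cutoff.
    """
    if cutoff <= 0:
        raise ArgumentError(f"cutoff must be positive, got {cutoff}")
    v = dm.values
    iu, ju = np.triu_indices(v.shape[0], k=1)
    d = v[iu, ju]
    keep = d < cutoff
    edge_index = np.column_stack([iu[keep], ju[keep]])
    weights = 1.0 - d[keep] / cutoff
    return ContactGraph(
        n_nodes=v.shape[0],
        edge_index=edge_index,
        weights=weights,
        cutoff=float(cutoff),
        frame_index=dm.frame_index,
    )


def build_graph_series(ensemble: CoordinateEnsemble, cutoff: float = DEFAULT_CUTOFF) -> GraphSeries:
    """Contact graph for every frame of the ensemble."""
    graphs = [
        build_contact_graph(pairwise_distances(ensemble, f), cutoff=cutoff)
        for f in range(ensemble.n_frames)
    ]
    return GraphSeries(graphs=graphs)


def write_graph_series(series: GraphSeries, path) -> None:
    """Edge-list text export: one block per frame."""
    with open(path, "w") as fh:
        fh.write(f"# trajembed graphs v1 n_nodes={series.n_nodes} cutoff={series.cutoff!r}\n")
        for k, g in enumerate(series):
            fh.write(f"frame\t{k}\t{g.n_edges}\n")
            for (i, j), w in zip(g.edge_index, g.weights):
                fh.write(f"{i}\t{j}\t{w:.12g}\n")


def read_graph_series(path) -> GraphSeries:
    """Read the edge-list text format written by :func:`write_graph_series`."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("# trajembed graphs v1"):
        raise ParseError("missing trajembed graphs header", line=1)
    try:
        fields = dict(tok.split("=") for tok in lines[0].split()[4:])
        n_nodes = int(fields["n_nodes"])
        cutoff = float(fields["cutoff"])
    except (KeyError, ValueError) as exc:
        raise ParseError(f"malformed graphs header: {exc}", line=1) from exc

    graphs: list[ContactGraph] = []
    idx = 1
    while idx < len(lines):
        parts = lines[idx].split("\t")
        if parts[0] != "frame":
            raise ParseError(f"expected frame record, got {lines[idx]!r}", line=idx + 1)
        try:
            frame_no, n_edges = int(parts[1]), int(parts[2])
        except (IndexError, ValueError) as exc:
            raise ParseError(f"malformed frame record: {exc}", line=idx + 1) from exc
        idx += 1
        edges = np.empty((n_edges, 2), dtype=np.int64)
        weights = np.empty(n_edges)
        for e in range(n_edges):
            if idx >= len(lines):
                raise ParseError("unexpected end of file in edge block", line=idx)
            try:
                i, j, w = lines[idx].split("\t")
                edges[e] = (int(i), int(j))
                weights[e] = float(w)
            except ValueError as exc:
                raise ParseError(f"malformed edge row: {exc}", line=idx + 1) from exc
            idx += 1
        graphs.append(
            ContactGraph(
                n_nodes=n_nodes, edge_index=edges, weights=weights,
                cutoff=cutoff, frame_index=frame_no,
            )
        )
    return GraphSeries(graphs=graphs)
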