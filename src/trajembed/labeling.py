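"""Conformational-state labeling: superpose -> PCA -> 2D density -> regions.

Frames are least-squares superposed onto a reference, PCA is run on the
flattened coordinates, frames are projected to (PC1, PC2), a Gaussian
kernel density is estimated on a regular grid, super-threshold connected
regions are traced into polygons, and each frame is labeled by the region
containing its score point — or ``N`` (non-state) if it lies in a
low-density area.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import box as _box
from shapely.ops import unary_union

from trajembed.errors import ArgumentError, IntegrityError, LabelingError
from trajembed.trajectory_io import CoordinateEnsemble

NON_STATE = "N"


# ---------------------------------------------------------------------------
# types


@dataclass
class ProjectionResult:
    """PCA projection of superposed coordinates.

    ``scores`` is n_frames x k (columns PC1, PC2, ...); ``components`` is
    k x 3m with mutually orthonormal rows; ``mean_structure`` is the 3m
    coordinate mean. ``degenerate`` flags a zero-variance ensemble.
    """

    scores: np.ndarray
    explained_variance_ratio: np.ndarray
    components: np.ndarray
    mean_structure: np.ndarray
    degenerate: bool = False

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.float64)
        evr = np.asarray(self.explained_variance_ratio, dtype=np.float64)
        if not self.degenerate:
            if np.any(np.diff(evr) > 1e-9):
                raise IntegrityError("explained variance ratios must be non-increasing")
            if evr.sum() > 1 + 1e-9:
                raise IntegrityError("explained variance ratios sum above 1")
        self.explained_variance_ratio = evr


@dataclass
class DensityField:
    """Gaussian-kernel density on a regular (PC1, PC2) grid.

    ``density[i, j]`` is the density at ``(xs[i], ys[j])``.
    """

    xs: np.ndarray
    ys: np.ndarray
    density: np.ndarray
    bandwidths: tuple[float, float]
    threshold: float | None = None

    def __post_init__(self):
        if np.any(self.density < 0):
            raise IntegrityError("density must be non-negative")
        if self.threshold is not None and self.threshold <= 0:
            raise IntegrityError("threshold must be positive")

    def integral(self) -> float:
        return float(np.trapezoid(np.trapezoid(self.density, self.ys, axis=1), self.xs))


@dataclass
class StateRegions:
    """Named closed polygons in (PC1, PC2) space (shapely geometry)."""

    regions: list[tuple[object, str]] = field(default_factory=list)

    def __post_init__(self):
        names = [name for _, name in self.regions]
        if len(names) != len(set(names)):
            raise IntegrityError("region labels must be unique")

    def __len__(self) -> int:
        return len(self.regions)

    def labels(self) -> list[str]:
        return [name for _, name in self.regions]

    def to_json(self, path) -> None:
        payload = []
        for poly, name in self.regions:
            payload.append({
                "label": name,
                "exterior": [list(xy) for xy in poly.exterior.coords],
                "holes": [[list(xy) for xy in ring.coords] for ring in poly.interiors],
            })
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "StateRegions":
        from shapely.geometry import Polygon

        with open(path) as fh:
            payload = json.load(fh)
        regions = [
            (Polygon(item["exterior"], holes=item.get("holes") or None), item["label"])
            for item in payload
        ]
        return cls(regions=regions)


@dataclass
class StateLabelSeries:
    """Per-frame categorical state label from a declared set plus ``N``."""

    labels: np.ndarray
    label_set: tuple[str, ...]

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=object)
        declared = set(self.label_set) | {NON_STATE}
        bad = sorted({str(v) for v in self.labels} - declared)
        if bad:
            raise IntegrityError(f"labels outside declared set: {bad}")

    def __len__(self) -> int:
        return len(self.labels)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# label_set\t{','.join(self.label_set)}\n")
            fh.write("frame_index\tlabel\n")
            for i, lab in enumerate(self.labels):
                fh.write(f"{i}\t{lab}\n")

    @classmethod
    def from_tsv(cls, path) -> "StateLabelSeries":
        with open(path) as fh:
            lines = fh.read().splitlines()
        label_set = tuple(lines[0].split("\t")[1].split(",")) if lines and lines[0].startswith("#") else ()
        labels = [row.split("\t")[1] for row in lines[2:] if row]
        return cls(labels=np.array(labels, dtype=object), label_set=label_set)


# ---------------------------------------------------------------------------
# operations


def superpose(ensemble: CoordinateEnsemble, reference_frame: int = 0) -> CoordinateEnsemble:
    """Least-squares fit (optimal rotation + translation) of each frame onto a reference.

    Uses the Kabsch algorithm; per-frame RMSD to the reference never
    increases. Emits a conditioning warning for (near-)collinear frames,
    where the optimal rotation is ill-determined.
    """
    from dataclasses import replace

    if not 0 <= reference_frame < ensemble.n_frames:
        raise ArgumentError(f"reference frame {reference_frame} out of range")
    ref = ensemble.coords[reference_frame]
    ref_centered = ref - ref.mean(axis=0)
    fitted = np.empty_like(ensemble.coords)
    warned = False
    for f in range(ensemble.n_frames):
        mobile = ensemble.coords[f]
        mob_centered = mobile - mobile.mean(axis=0)
        cov = mob_centered.T @ ref_centered
        u, s, vt = np.linalg.svd(cov)
        if not warned and s[0] > 0 and s[1] / s[0] < 1e-8:
            warnings.warn(
                f"frame {f} is (near-)collinear; superposition rotation is ill-conditioned"
            )
            warned = True
        d = np.sign(np.linalg.det(u @ vt))
        rot = u @ np.diag([1.0, 1.0, d]) @ vt
        fitted[f] = mob_centered @ rot + ref.mean(axis=0)
    return replace(ensemble, coords=fitted, source=f"{ensemble.source} [fit->frame {reference_frame}]")


def pca_project(ensemble: CoordinateEnsemble, k: int = 2) -> ProjectionResult:
    """PCA of the n_frames x 3m flattened, mean-centered coordinate matrix.

    Component signs are fixed so each component's largest-magnitude loading
    is positive, making score plots reproducible.
    """
    from sklearn.decomposition import PCA

    n, m = ensemble.n_frames, ensemble.n_atoms
    if n <= k:
        raise ArgumentError(f"need n_frames > k, got n_frames={n}, k={k}")
    if k > min(n - 1, 3 * m):
        raise ArgumentError(f"k={k} exceeds min(n_frames-1, 3m)={min(n - 1, 3 * m)}")
    flat = ensemble.coords.reshape(n, 3 * m)
    mean = flat.mean(axis=0)
    total_var = float(np.var(flat - mean))
    if total_var < 1e-24:
        warnings.warn("ensemble has zero coordinate variance; projection is degenerate")
        return ProjectionResult(
            scores=np.zeros((n, k)),
            explained_variance_ratio=np.zeros(k),
            components=np.zeros((k, 3 * m)),
            mean_structure=mean,
            degenerate=True,
        )
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(flat)
    components = pca.components_.copy()
    for c in range(k):
        lead = np.argmax(np.abs(components[c]))
        if components[c, lead] < 0:
            components[c] = -components[c]
            scores[:, c] = -scores[:, c]
    return ProjectionResult(
        scores=scores,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        components=components,
        mean_structure=mean,
    )


def normal_reference_bandwidths(scores: np.ndarray) -> tuple[float, float]:
    """Per-axis normal-reference (Scott) bandwidths for 2D data."""
    n = scores.shape[0]
    sig = scores.std(axis=0, ddof=1)
    if np.any(sig <= 0):
        raise ArgumentError("zero-variance axis: cannot choose a bandwidth")
    h = sig * n ** (-1.0 / 6.0)
    return float(h[0]), float(h[1])


def estimate_density(
    scores: np.ndarray,
    grid_size: int = 128,
    bandwidths: tuple[float, float] | None = None,
) -> DensityField:
    """Product-Gaussian kernel density on a regular grid over the score range.

    The grid extends 4 bandwidths beyond the data range so the field
    integrates to ~1 (within 2%) over the grid.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.ndim != 2 or scores.shape[1] < 2:
        raise ArgumentError("scores must be an n x 2 array")
    scores = scores[:, :2]
    n = scores.shape[0]
    if n < 10:
        raise ArgumentError(f"need at least 10 points for density estimation, got {n}")
    if bandwidths is None:
        bandwidths = normal_reference_bandwidths(scores)
    hx, hy = bandwidths
    if hx <= 0 or hy <= 0:
        raise ArgumentError(f"bandwidths must be positive, got {bandwidths}")
    margin = 4.0
    xs = np.linspace(scores[:, 0].min() - margin * hx, scores[:, 0].max() + margin * hx, grid_size)
    ys = np.linspace(scores[:, 1].min() - margin * hy, scores[:, 1].max() + margin * hy, grid_size)

    density = np.zeros((grid_size, grid_size))
    norm = 1.0 / (n * 2 * np.pi * hx * hy)
    chunk = max(1, int(2e6 // grid_size))
    for lo in range(0, n, chunk):
        px = scores[lo:lo + chunk, 0]
        py = scores[lo:lo + chunk, 1]
        kx = np.exp(-0.5 * ((xs[:, None] - px[None, :]) / hx) ** 2)
        ky = np.exp(-0.5 * ((ys[:, None] - py[None, :]) / hy) ** 2)
        density += kx @ ky.T
    density *= norm
    return DensityField(xs=xs, ys=ys, density=density, bandwidths=(hx, hy))


def extract_regions(
    field: DensityField,
    threshold: float,
    state_names: list[str],
    anchors: dict[str, tuple[float, float]] | None = None,
) -> StateRegions:
    """Trace connected super-threshold grid components into named polygons.

    Without ``anchors`` the components are named in order of decreasing
    peak density. With ``anchors`` (one (PC1, PC2) point per state name,
    the explicit expert-knowledge step) each region takes the name of the
    anchor it contains; an anchorless region is an error.
    """
    if threshold <= 0:
        raise ArgumentError(f"threshold must be positive, got {threshold}")
    mask = field.density > threshold
    labeled, n_comp = ndimage.label(mask)  # 4-connectivity
    if n_comp == 0:
        field.threshold = threshold
        return StateRegions(regions=[])

    dx = float(field.xs[1] - field.xs[0])
    dy = float(field.ys[1] - field.ys[0])
    # cell-boundary grids shared between neighbors, so adjacent boxes have
    # bit-identical edges and union into a single polygon without slivers
    ex = np.concatenate([field.xs - dx / 2, [field.xs[-1] + dx / 2]])
    ey = np.concatenate([field.ys - dy / 2, [field.ys[-1] + dy / 2]])
    polys, peaks = [], []
    for comp in range(1, n_comp + 1):
        ii, jj = np.nonzero(labeled == comp)
        cells = [_box(ex[i], ey[j], ex[i + 1], ey[j + 1]) for i, j in zip(ii, jj)]
        poly = unary_union(cells)
        if poly.geom_type == "MultiPolygon":  # 8-connected diagonal touch only
            poly = max(poly.geoms, key=lambda g: g.area)
        polys.append(poly)
        peaks.append(float(field.density[ii, jj].max()))

    centroids = [(p.centroid.x, p.centroid.y) for p in polys]
    if n_comp > len(state_names):
        raise LabelingError(
            f"found {n_comp} regions for {len(state_names)} state names; "
            f"region centroids: {centroids}"
        )

    if anchors is not None:
        assigned: list[tuple[object, str]] = []
        for poly, centroid in zip(polys, centroids):
            hits = [name for name, pt in anchors.items()
                    if name in state_names and poly.covers(shapely.Point(pt))]
            if not hits:
                raise LabelingError(f"region at centroid {centroid} contains no anchor point")
            if len(hits) > 1:
                raise LabelingError(f"region at centroid {centroid} contains anchors {hits}")
            assigned.append((poly, hits[0]))
    else:
        order = np.argsort(peaks)[::-1]
        assigned = [(polys[i], state_names[rank]) for rank, i in enumerate(order)]

    field.threshold = threshold
    return StateRegions(regions=assigned)


def assign_labels(scores: np.ndarray, regions: StateRegions,
                  label_set: tuple[str, ...] | None = None) -> StateLabelSeries:
    """Label each score point by its containing region, else ``N``.

    Boundary points count as inside (regions are closed sets): ``N`` means
    "low density", not "numerical edge case".
    """
    scores = np.asarray(scores, dtype=np.float64)[:, :2]
    pts = shapely.points(scores)
    labels = np.full(scores.shape[0], NON_STATE, dtype=object)
    for poly, name in regions.regions:
        inside = shapely.covers(poly, pts)
        labels[inside & (labels == NON_STATE)] = name
    if label_set is None:
        label_set = tuple(regions.labels())
    return StateLabelSeries(labels=labels, label_set=label_set)


def plot_projection(scores: np.ndarray, labels: StateLabelSeries | None, path,
                    mispredicted: np.ndarray | None = None) -> None:
    """Scatter of (PC1, PC2) scores colored by label; mispredictions in red."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scores = np.asarray(scores)[:, :2]
    fig, ax = plt.subplots(figsize=(6, 5))
    if labels is None:
        ax.scatter(scores[:, 0], scores[:, 1], s=4, alpha=0.6)
    else:
        for lab in sorted({str(v) for v in labels.labels}):
            sel = np.asarray([str(v) == lab for v in labels.labels])
            ax.scatter(scores[sel, 0], scores[sel, 1], s=4, alpha=0.6, label=lab)
        ax.legend(markerscale=3, fontsize=8)
    if mispredicted is not None and np.any(mispredicted):
        ax.scatter(scores[mispredicted, 0], scores[mispredicted, 1],
                   s=6, c="red", label="mispredicted")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def export_scores(scores: np.ndarray, path) -> None:
    scores = np.asarray(scores)
    header = "\t".join(f"PC{i + 1}" for i in range(scores.shape[1]))
    np.savetxt(path, scores, delimiter="\t", fmt="%.10g", header=header, comments="")
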