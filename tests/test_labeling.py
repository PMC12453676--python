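import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from trajembed.errors import ArgumentError, LabelingError
from trajembed.labeling import (
    StateLabelSeries,
    StateRegions,
    assign_labels,
    estimate_density,
    extract_regions,
    normal_reference_bandwidths,
    pca_project,
    superpose,
)
from trajembed.trajectory_io import AtomRecord, CoordinateEnsemble


def _make_ensemble(coords):
    coords = np.asarray(coords, dtype=float)
    meta = [AtomRecord(i + 1, "GLY", "CA") for i in range(coords.shape[1])]
    return CoordinateEnsemble(coords, np.arange(float(coords.shape[0])), meta)


def _rmsd(a, b):
    return np.sqrt(((a - b) ** 2).sum(axis=-1).mean())


def _two_gaussians(n=1000, sep=10.0, sigma=1.0, seed=0):
    """Score clouds 'sep' sigma apart along PC1."""
    rng = np.random.default_rng(seed)
    half = n // 2
    a = rng.normal([0.0, 0.0], sigma, size=(half, 2))
    b = rng.normal([sep * sigma, 0.0], sigma, size=(n - half, 2))
    return np.vstack([a, b]), np.array(["A"] * half + ["B"] * (n - half))


class TestSuperpose:
    def test_idempotent_on_aligned(self):
        rng = np.random.default_rng(0)
        frame = rng.normal(size=(10, 3))
        ens = _make_ensemble(np.stack([frame, frame]))
        out = superpose(ens, 0)
        assert np.allclose(out.coords[1], out.coords[0], atol=1e-9)
        again = superpose(out, 0)
        assert np.allclose(again.coords, out.coords, atol=1e-9)

    def test_recovers_rigid_motion(self):
        rng = np.random.default_rng(1)
        frame = rng.normal(size=(12, 3))
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = frame @ rot.T + np.array([5.0, -3.0, 2.0])
        ens = _make_ensemble(np.stack([frame, moved]))
        out = superpose(ens, 0)
        assert _rmsd(out.coords[1], out.coords[0]) < 1e-9

    def test_never_increases_rmsd(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(size=(15, 3))
        frames = [ref] + [ref + rng.normal(0, 1.0, size=(15, 3)) for _ in range(8)]
        ens = _make_ensemble(np.stack(frames))
        out = superpose(ens, 0)
        for f in range(1, ens.n_frames):
            assert _rmsd(out.coords[f], ref) <= _rmsd(ens.coords[f], ref) + 1e-12

    def test_collinear_warns(self):
        line = np.zeros((6, 3))
        line[:, 0] = np.arange(6.0)
        ens = _make_ensemble(np.stack([line, line + [1.0, 2.0, 3.0]]))
        with pytest.warns(UserWarning, match="collinear"):
            superpose(ens, 0)


class TestPcaProject:
    def test_degenerate_all_identical(self):
        frame = np.arange(30.0).reshape(10, 3)
        ens = _make_ensemble(np.stack([frame] * 5))
        with pytest.warns(UserWarning, match="degenerate"):
            proj = pca_project(ens, k=2)
        assert proj.degenerate
        assert np.allclose(proj.scores, 0.0)

    def test_hinge_coordinate_recovered(self):
        # 1-D hinge: frames interpolate between two conformations + small noise
        rng = np.random.default_rng(3)
        open_ref = rng.normal(size=(20, 3)) * 5
        direction = rng.normal(size=(20, 3))
        direction /= np.linalg.norm(direction)
        hinge = rng.uniform(0, 10, size=200)
        frames = open_ref[None] + hinge[:, None, None] * direction[None] \
            + rng.normal(0, 0.1, size=(200, 20, 3))
        proj = pca_project(superpose(_make_ensemble(frames), 0), k=2)
        r = np.corrcoef(proj.scores[:, 0], hinge)[0, 1]
        assert abs(r) > 0.9

    def test_variance_ratio_contract(self, two_state_bundle):
        ensemble, _, _ = two_state_bundle
        proj = pca_project(superpose(ensemble, 0), k=3)
        evr = proj.explained_variance_ratio
        assert np.all(evr >= 0) and np.all(evr <= 1)
        assert np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() <= 1 + 1e-9
        # components orthonormal
        gram = proj.components @ proj.components.T
        assert np.allclose(gram, np.eye(3), atol=1e-8)

    def test_k_out_of_range(self, two_state_bundle):
        ensemble, _, _ = two_state_bundle
        with pytest.raises(ArgumentError):
            pca_project(ensemble, k=ensemble.n_frames)

    def test_sign_convention_deterministic(self, two_state_bundle):
        ensemble, _, _ = two_state_bundle
        fitted = superpose(ensemble, 0)
        a = pca_project(fitted, k=2)
        b = pca_project(fitted, k=2)
        assert np.array_equal(a.scores, b.scores)
        for c in range(2):
            lead = np.argmax(np.abs(a.components[c]))
            assert a.components[c, lead] > 0


class TestEstimateDensity:
    def test_unimodal_peak_near_mean(self):
        rng = np.random.default_rng(4)
        pts = rng.normal([2.0, -1.0], 0.5, size=(500, 2))
        field = estimate_density(pts, grid_size=64)
        i, j = np.unravel_index(np.argmax(field.density), field.density.shape)
        assert abs(field.xs[i] - 2.0) < 0.3
        assert abs(field.ys[j] + 1.0) < 0.3

    def test_two_modes(self):
        scores, _ = _two_gaussians(n=2000, sep=10.0, seed=5)
        field = estimate_density(scores, grid_size=96)
        half_max = 0.5 * field.density.max()
        from scipy import ndimage
        peaks = (field.density == ndimage.maximum_filter(field.density, size=5)) \
            & (field.density > half_max)
        assert peaks.sum() == 2

    def test_normalization(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(300, 2))
        field = estimate_density(pts)
        assert np.all(field.density >= 0)
        assert 0.98 <= field.integral() <= 1.02

    def test_too_few_points(self):
        with pytest.raises(ArgumentError):
            estimate_density(np.zeros((5, 2)))

    def test_zero_variance_axis(self):
        pts = np.zeros((50, 2))
        pts[:, 0] = np.random.default_rng(0).normal(size=50)
        with pytest.raises(ArgumentError):
            normal_reference_bandwidths(pts)
        with pytest.raises(ArgumentError):
            estimate_density(pts)


class TestExtractRegions:
    def test_empty_when_threshold_above_max(self):
        scores, _ = _two_gaussians(n=500, seed=7)
        field = estimate_density(scores)
        regions = extract_regions(field, threshold=2 * field.density.max(),
                                  state_names=["A", "B"])
        assert len(regions) == 0

    def test_two_separated_gaussians(self):
        scores, _ = _two_gaussians(n=2000, sep=10.0, seed=8)
        field = estimate_density(scores, grid_size=96)
        lower_peak = _lower_peak(field)
        regions = extract_regions(field, threshold=0.5 * lower_peak,
                                  state_names=["A", "B"])
        assert len(regions) == 2

    def test_three_gaussian_named_regions(self):
        rng = np.random.default_rng(9)
        pts = np.vstack([
            rng.normal([0, 0], 0.5, size=(400, 2)),
            rng.normal([8, 0], 0.5, size=(400, 2)),
            rng.normal([4, 7], 0.5, size=(400, 2)),
        ])
        field = estimate_density(pts, grid_size=96, bandwidths=(0.5, 0.5))
        regions = extract_regions(field, threshold=0.1 * field.density.max(),
                                  state_names=["A", "B", "I"])
        assert len(regions) == 3
        assert sorted(regions.labels()) == ["A", "B", "I"]

    def test_more_regions_than_names_errors(self):
        scores, _ = _two_gaussians(n=2000, sep=10.0, seed=10)
        field = estimate_density(scores, grid_size=96)
        with pytest.raises(LabelingError, match="centroid"):
            extract_regions(field, threshold=0.5 * _lower_peak(field), state_names=["A"])

    def test_anchor_assignment(self):
        scores, _ = _two_gaussians(n=2000, sep=10.0, seed=11)
        field = estimate_density(scores, grid_size=96)
        regions = extract_regions(
            field, threshold=0.5 * _lower_peak(field), state_names=["A", "B"],
            anchors={"A": (0.0, 0.0), "B": (10.0, 0.0)})
        by_label = {name: poly for poly, name in regions.regions}
        assert by_label["A"].centroid.x < by_label["B"].centroid.x

    def test_anchorless_region_errors(self):
        scores, _ = _two_gaussians(n=2000, sep=10.0, seed=12)
        field = estimate_density(scores, grid_size=96)
        with pytest.raises(LabelingError, match="anchor"):
            extract_regions(field, threshold=0.5 * _lower_peak(field),
                            state_names=["A", "B"],
                            anchors={"A": (0.0, 0.0), "B": (99.0, 99.0)})

    def test_threshold_monotonicity(self):
        scores, _ = _two_gaussians(n=1500, sep=10.0, seed=13)
        field = estimate_density(scores, grid_size=96)
        areas = []
        for frac in (0.2, 0.4, 0.6, 0.8):
            regions = extract_regions(field, threshold=frac * field.density.max(),
                                      state_names=["A", "B", "C", "D"])
            areas.append(sum(poly.area for poly, _ in regions.regions))
        assert all(a >= b - 1e-12 for a, b in zip(areas, areas[1:]))


def _lower_peak(field):
    """Peak density of the weaker mode (max over the right half vs left half)."""
    mid = field.density.shape[0] // 2
    return min(field.density[:mid].max(), field.density[mid:].max())


class TestAssignLabels:
    def test_centroid_inside_and_far_outside(self):
        scores, _ = _two_gaussians(n=2000, sep=10.0, seed=14)
        field = estimate_density(scores, grid_size=96)
        regions = extract_regions(field, threshold=0.5 * _lower_peak(field),
                                  state_names=["A", "B"],
                                  anchors={"A": (0.0, 0.0), "B": (10.0, 0.0)})
        centro = regions.regions[0][0].centroid
        out = assign_labels(np.array([[centro.x, centro.y], [500.0, 500.0]]), regions)
        assert out.labels[0] == regions.regions[0][1]
        assert out.labels[1] == "N"

    def test_core_points_get_generative_label(self):
        scores, truth = _two_gaussians(n=2000, sep=10.0, seed=15)
        field = estimate_density(scores, grid_size=96)
        regions = extract_regions(field, threshold=0.5 * _lower_peak(field),
                                  state_names=["A", "B"],
                                  anchors={"A": (0.0, 0.0), "B": (10.0, 0.0)})
        labels = assign_labels(scores, regions)
        centers = np.where(truth[:, None] == "A", [0.0, 0.0], [10.0, 0.0])
        core = np.linalg.norm(scores - centers, axis=1) < 1.0  # mode cores (1 sigma)
        agree = np.mean(labels.labels[core] == truth[core])
        assert agree >= 0.9
        # no confusion between cores
        assert not np.any((labels.labels == "A") & (truth == "B") & core)

    def test_total_and_deterministic(self):
        scores, _ = _two_gaussians(n=500, seed=16)
        field = estimate_density(scores, grid_size=64)
        regions = extract_regions(field, threshold=0.5 * field.density.max(),
                                  state_names=["A", "B"])
        a = assign_labels(scores, regions)
        b = assign_labels(scores, regions)
        assert len(a) == len(scores)
        assert np.array_equal(a.labels, b.labels)
        declared = set(regions.labels()) | {"N"}
        assert {str(v) for v in a.labels} <= declared


class TestStateLabelSeriesIO:
    def test_tsv_round_trip(self, tmp_path):
        labels = StateLabelSeries(labels=np.array(["A", "B", "N", "A"], dtype=object),
                                  label_set=("A", "B"))
        path = tmp_path / "labels.tsv"
        labels.to_tsv(path)
        back = StateLabelSeries.from_tsv(path)
        assert np.array_equal(back.labels, labels.labels)
        assert back.label_set == labels.label_set

    def test_regions_json_round_trip(self, tmp_path):
        scores, _ = _two_gaussians(n=800, sep=10.0, seed=17)
        field = estimate_density(scores, grid_size=64)
        regions = extract_regions(field, threshold=0.5 * _lower_peak(field),
                                  state_names=["A", "B"])
        path = tmp_path / "regions.json"
        regions.to_json(path)
        back = StateRegions.from_json(path)
        assert back.labels() == regions.labels()
        for (p1, _), (p2, _) in zip(regions.regions, back.regions):
            assert p1.symmetric_difference(p2).area < 1e-9
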