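"""Synthetic multi-state conformational ensembles with ground-truth labels.

A toy hinge protein: an m-residue Cα chain with exact 3.8 Å consecutive
spacing whose "closed" reference is the "open" one with the second half
rotated about the midpoint hinge. Frames sample the reference states (or
the linear interpolation path between the first two states), add isotropic
Gaussian noise, and then receive a random rigid motion — deliberately, so
the graph stage's rigid-motion invariance is exercised and the labeling
stage is forced to superpose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from trajembed.errors import SpecError
from trajembed.labeling import StateLabelSeries
from trajembed.trajectory_io import AtomRecord, CoordinateEnsemble

BOND_LENGTH = 3.8  # Angstrom, consecutive Calpha spacing
_ZIGZAG_DEG = 15.0  # in-plane zig-zag half-angle of the reference chain
TRANSITION_LABEL = "I"
_CORE_FRACTION = 0.2  # interpolation u <= 0.2 / >= 0.8 folds into the endpoint states


def default_hinge_references(m: int, bend_angle: float = 90.0) -> dict[str, np.ndarray]:
    """Two m x 3 reference conformations: extended ("A") and bent ("B") hinge.

    The chain zig-zags in the xy-plane with exact 3.8 Å steps; the bent
    reference rotates residues past the midpoint hinge by ``bend_angle``
    degrees about the z-axis through the hinge atom, so cross-hinge
    residue pairs move from beyond to within a 10 Å contact cutoff.
    """
    if m < 8:
        raise SpecError(f"need at least 8 residues for a hinge chain, got {m}")
    theta = np.deg2rad(_ZIGZAG_DEG)
    open_ref = np.zeros((m, 3))
    for k in range(1, m):
        phi = theta if k % 2 else -theta
        open_ref[k] = open_ref[k - 1] + BOND_LENGTH * np.array([np.cos(phi), np.sin(phi), 0.0])

    hinge = m // 2
    rot = Rotation.from_euler("z", bend_angle, degrees=True).as_matrix()
    closed_ref = open_ref.copy()
    pivot = open_ref[hinge]
    closed_ref[hinge + 1:] = (open_ref[hinge + 1:] - pivot) @ rot.T + pivot

    d = np.linalg.norm(closed_ref[:, None] - closed_ref[None, :], axis=-1)
    off_diag = ~np.eye(m, dtype=bool) & ~np.eye(m, k=1, dtype=bool) & ~np.eye(m, k=-1, dtype=bool)
    if np.any(d[off_diag] < 2.0):
        raise SpecError(
            f"bend_angle={bend_angle} produces chain self-intersection "
            f"(non-consecutive contact below 2 Angstrom)"
        )
    return {"A": open_ref, "B": closed_ref}


@dataclass
class SyntheticSpec:
    """Generator specification for a multi-state toy ensemble.

    ``references`` maps state names to m x 3 reference coordinates (default:
    the open/bent hinge pair). ``occupancies`` are per-state fractions;
    together with ``transition_fraction`` (frames drawn along the linear
    interpolation between the first two states) they must sum to 1.
    """

    n_residues: int = 40
    n_frames: int = 1000
    noise_sigma: float = 0.5
    transition_fraction: float = 0.0
    occupancies: dict[str, float] | None = None
    references: dict[str, np.ndarray] | None = None
    bend_angle: float = 90.0
    rigid_motion: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_residues < 4:
            raise SpecError(f"need at least 4 residues, got {self.n_residues}")
        if self.noise_sigma < 0:
            raise SpecError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if self.references is None:
            self.references = default_hinge_references(self.n_residues, self.bend_angle)
        for name, ref in self.references.items():
            ref = np.asarray(ref, dtype=np.float64)
            if ref.shape != (self.n_residues, 3):
                raise SpecError(f"reference {name!r} must be {self.n_residues} x 3, got {ref.shape}")
            self.references[name] = ref
        names = list(self.references)
        if self.occupancies is None:
            share = (1.0 - self.transition_fraction) / len(names)
            self.occupancies = {name: share for name in names}
        if set(self.occupancies) != set(names):
            raise SpecError("occupancies must name exactly the reference states")
        total = sum(self.occupancies.values()) + self.transition_fraction
        if abs(total - 1.0) > 1e-9:
            raise SpecError(f"occupancies + transition_fraction must sum to 1, got {total}")
        if any(v < 0 for v in self.occupancies.values()) or self.transition_fraction < 0:
            raise SpecError("occupancies and transition_fraction must be non-negative")
        if self.transition_fraction > 0 and len(names) < 2:
            raise SpecError("transition frames need at least two reference states")

    @property
    def state_names(self) -> list[str]:
        return list(self.references)


def generate_ensemble(spec: SyntheticSpec) -> tuple[CoordinateEnsemble, StateLabelSeries]:
    """Sample frames per the spec; returns the ensemble and generative labels.

    Each frame = a state reference (or interpolation point) + isotropic
    Gaussian noise, then a random rigid motion. Interpolation frames in the
    middle 60% of the path are labeled ``I``; the path's first/last 20%
    folds into the endpoint states.
    """
    rng = np.random.default_rng(spec.seed)
    names = spec.state_names
    categories = names + ["__transition__"]
    probs = np.array([spec.occupancies[n] for n in names] + [spec.transition_fraction])
    probs = probs / probs.sum()

    m = spec.n_residues
    coords = np.empty((spec.n_frames, m, 3))
    labels = np.empty(spec.n_frames, dtype=object)
    ref_a = spec.references[names[0]]
    ref_b = spec.references[names[1]] if len(names) > 1 else None

    choice = rng.choice(len(categories), size=spec.n_frames, p=probs)
    for f in range(spec.n_frames):
        cat = categories[choice[f]]
        if cat == "__transition__":
            u = rng.uniform()
            xyz = (1.0 - u) * ref_a + u * ref_b
            if u <= _CORE_FRACTION:
                labels[f] = names[0]
            elif u >= 1.0 - _CORE_FRACTION:
                labels[f] = names[1]
            else:
                labels[f] = TRANSITION_LABEL
        else:
            xyz = spec.references[cat]
            labels[f] = cat
        if spec.noise_sigma > 0:
            xyz = xyz + rng.normal(0.0, spec.noise_sigma, size=(m, 3))
        else:
            xyz = xyz.copy()
        if spec.rigid_motion:
            quat = rng.normal(size=4)
            rot = Rotation.from_quat(quat / np.linalg.norm(quat)).as_matrix()
            xyz = xyz @ rot.T + rng.uniform(-20.0, 20.0, size=3)
        coords[f] = xyz

    atom_meta = [AtomRecord(i + 1, "GLY", "CA") for i in range(m)]
    ensemble = CoordinateEnsemble(
        coords=coords,
        times=np.arange(spec.n_frames, dtype=np.float64),
        atom_meta=atom_meta,
        source=f"synthetic hinge m={m} seed={spec.seed}",
    )
    label_set = tuple(names) + ((TRANSITION_LABEL,) if spec.transition_fraction > 0 else ())
    return ensemble, StateLabelSeries(labels=labels, label_set=label_set)
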