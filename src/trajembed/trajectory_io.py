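"""Trajectory reading and the internal delimited ensemble format.

Trajectories are read with MDAnalysis (PDB/GRO topologies; DCD/XTC or
multi-model PDB coordinates). Internally a trajectory is a
:class:`CoordinateEnsemble`: a dense ``n_frames x n_atoms x 3`` array in
Angstrom for a fixed atom selection, plus per-atom metadata. The module
also defines a plain-text ensemble format used for diffable fixtures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from trajembed.errors import ArgumentError, FormatError, IntegrityError, ParseError, SelectionError

DEFAULT_SELECTION = "protein and name CA"

_FORMAT_HEADER = "# trajembed ensemble v1"


@dataclass(frozen=True)
class AtomRecord:
    """Identity of one selected atom: 1-based residue index, residue and atom names."""

    residue_index: int
    residue_name: str
    atom_name: str


@dataclass(frozen=True)
class AtomSelection:
    """An MDAnalysis selection expression; defaults to protein alpha-carbons."""

    expression: str = DEFAULT_SELECTION


@dataclass
class CoordinateEnsemble:
    """Ordered frames of 3D coordinates (Angstrom) for a fixed atom selection.

    Attributes
    ----------
    coords : ndarray, shape (n_frames, n_atoms, 3)
        Cartesian coordinates in Angstrom.
    times : ndarray, shape (n_frames,)
        Frame times in picoseconds, strictly increasing.
    atom_meta : list of AtomRecord
        Per-atom identity, aligned with the atom axis of ``coords``.
    source : str
        Provenance string (file paths, generator spec, ...).
    """

    coords: np.ndarray
    times: np.ndarray
    atom_meta: list[AtomRecord]
    source: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise IntegrityError(f"coords must be (n_frames, n_atoms, 3), got {self.coords.shape}")
        if self.coords.shape[0] < 1:
            raise IntegrityError("ensemble must contain at least one frame")
        if not np.all(np.isfinite(self.coords)):
            raise IntegrityError("coordinates contain non-finite values")
        if self.times.shape != (self.coords.shape[0],):
            raise IntegrityError("times length must equal n_frames")
        if self.n_frames > 1 and not np.all(np.diff(self.times) > 0):
            raise IntegrityError("times must be strictly increasing")
        if len(self.atom_meta) != self.coords.shape[1]:
            raise IntegrityError(
                f"atom_meta has {len(self.atom_meta)} entries for {self.coords.shape[1]} atoms"
            )

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


def load_ensemble(
    topology: str,
    trajectory: str | None = None,
    selection: AtomSelection | str = AtomSelection(),
) -> CoordinateEnsemble:
    """Read a trajectory into a :class:`CoordinateEnsemble`.

    Parameters
    ----------
    topology
        PDB or GRO file defining atom identities. A multi-model PDB may serve
        as both topology and trajectory.
    trajectory
        DCD/XTC/multi-model-PDB coordinate file; omitted to read frames from
        the topology file itself.
    selection
        MDAnalysis selection expression; atoms are re-ordered by residue
        index (ties by atom name) so node identity is stable across frames.
    """
    import MDAnalysis as mda

    if isinstance(selection, str):
        selection = AtomSelection(selection)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if trajectory is None or trajectory == topology:
                universe = mda.Universe(topology)
            else:
                universe = mda.Universe(topology, trajectory)
        except (OSError, ValueError, EOFError) as exc:
            raise FormatError(f"cannot read trajectory inputs: {exc}") from exc
        try:
            group = universe.select_atoms(selection.expression)
        except Exception as exc:  # MDAnalysis raises its own SelectionError
            raise SelectionError(f"invalid selection {selection.expression!r}: {exc}") from exc
        if len(group) == 0:
            raise SelectionError(f"selection {selection.expression!r} matched no atoms")

        order = sorted(
            range(len(group)), key=lambda i: (int(group.resids[i]), str(group.names[i]))
        )
        group = group[order]
        atom_meta = [
            AtomRecord(int(a.resid), str(a.resname), str(a.name)) for a in group
        ]

        frames = []
        times = []
        for ts in universe.trajectory:
            pos = np.array(group.positions, dtype=np.float64)
            if pos.shape != (len(group), 3):
                raise IntegrityError(
                    f"frame {ts.frame}: expected {len(group)} atoms, got {pos.shape[0]}"
                )
            frames.append(pos)
            times.append(float(ts.time))

    coords = np.stack(frames)
    times = np.asarray(times, dtype=np.float64)
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        times = np.arange(len(frames), dtype=np.float64)  # synthesize frame indices as ps
    src = topology if trajectory in (None, topology) else f"{topology} + {trajectory}"
    return CoordinateEnsemble(coords, times, atom_meta, source=f"{src} [{selection.expression}]")


def stride_ensemble(ensemble: CoordinateEnsemble, stride: int) -> CoordinateEnsemble:
    """Keep frames 0, stride, 2*stride, ... preserving time alignment."""
    if int(stride) != stride or stride < 1:
        raise ArgumentError(f"stride must be a positive integer, got {stride}")
    stride = int(stride)
    if stride == 1:
        return ensemble
    return replace(
        ensemble,
        coords=ensemble.coords[::stride].copy(),
        times=ensemble.times[::stride].copy(),
        source=f"{ensemble.source} [stride {stride}]",
    )


def write_ensemble(ensemble: CoordinateEnsemble, path) -> None:
    """Write the internal delimited text format (round-trips to >= 6 digits)."""
    if ensemble.n_frames < 1:
        raise ArgumentError("refusing to write an empty ensemble")
    with open(path, "w") as fh:
        fh.write(_FORMAT_HEADER + "\n")
        fh.write(f"source\t{ensemble.source}\n")
        fh.write(f"n_frames\t{ensemble.n_frames}\n")
        fh.write(f"n_atoms\t{ensemble.n_atoms}\n")
        for rec in ensemble.atom_meta:
            fh.write(f"atom\t{rec.residue_index}\t{rec.residue_name}\t{rec.atom_name}\n")
        for f in range(ensemble.n_frames):
            fh.write(f"frame\t{f}\t{float(ensemble.times[f])!r}\n")
            for a in range(ensemble.n_atoms):
                x, y, z = ensemble.coords[f, a]
                fh.write(f"{x:.10g}\t{y:.10g}\t{z:.10g}\n")


def read_ensemble(path) -> CoordinateEnsemble:
    """Read the internal delimited text format written by :func:`write_ensemble`."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0] != _FORMAT_HEADER:
        raise ParseError("missing trajembed ensemble header", line=1)

    lineno = 1
    source = ""
    n_frames = n_atoms = None
    atom_meta: list[AtomRecord] = []
    idx = 1

    def _next():
        nonlocal idx, lineno
        if idx >= len(lines):
            raise ParseError("unexpected end of file", line=lineno)
        lineno = idx + 1
        row = lines[idx]
        idx += 1
        return row

    try:
        while True:
            row = _next()
            parts = row.split("\t")
            key = parts[0]
            if key == "source":
                source = parts[1] if len(parts) > 1 else ""
            elif key == "n_frames":
                n_frames = int(parts[1])
            elif key == "n_atoms":
                n_atoms = int(parts[1])
            elif key == "atom":
                atom_meta.append(AtomRecord(int(parts[1]), parts[2], parts[3]))
            elif key == "frame":
                idx -= 1
                break
            else:
                raise ParseError(f"unrecognized record {key!r}", line=lineno)
    except (IndexError, ValueError) as exc:
        raise ParseError(f"malformed header record: {exc}", line=lineno) from exc

    if n_frames is None or n_atoms is None:
        raise ParseError("header missing n_frames or n_atoms", line=lineno)
    if len(atom_meta) != n_atoms:
        raise ParseError(f"expected {n_atoms} atom records, found {len(atom_meta)}", line=lineno)

    coords = np.empty((n_frames, n_atoms, 3), dtype=np.float64)
    times = np.empty(n_frames, dtype=np.float64)
    for f in range(n_frames):
        row = _next()
        parts = row.split("\t")
        if parts[0] != "frame":
            raise ParseError(f"expected frame record, got {row!r}", line=lineno)
        try:
            if int(parts[1]) != f:
                raise ParseError(f"frame records out of order at frame {f}", line=lineno)
            times[f] = float(parts[2])
        except (IndexError, ValueError) as exc:
            raise ParseError(f"malformed frame record: {exc}", line=lineno) from exc
        for a in range(n_atoms):
            row = _next()
            try:
                coords[f, a] = [float(v) for v in row.split("\t")]
            except ValueError as exc:
                raise ParseError(f"malformed coordinate row: {exc}", line=lineno) from exc

    return CoordinateEnsemble(coords, times, atom_meta, source=source)


def export_frame_pdb(ensemble: CoordinateEnsemble, frame_index: int, path) -> None:
    """Export one frame as a single-model PDB (CA-style records)."""
    if not 0 <= frame_index < ensemble.n_frames:
        raise ArgumentError(f"frame index {frame_index} out of range")
    with open(path, "w") as fh:
        for serial, (rec, xyz) in enumerate(
            zip(ensemble.atom_meta, ensemble.coords[frame_index]), start=1
        ):
            fh.write(
                f"ATOM  {serial:5d} {rec.atom_name:^4s}{rec.residue_name:>4s} A"
                f"{rec.residue_index:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"  1.00  0.00\n"
            )
        fh.write("END\n")


def meta_table(ensemble: CoordinateEnsemble):
    """Per-atom metadata as parallel arrays (used by graph/node provenance)."""
    return (
        np.array([r.residue_index for r in ensemble.atom_meta]),
        np.array([r.residue_name for r in ensemble.atom_meta]),
        np.array([r.atom_name for r in ensemble.atom_meta]),
    )
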