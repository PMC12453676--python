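import numpy as np
import pytest

from trajembed.graph_builder import build_graph_series
from trajembed.synthetic import SyntheticSpec, generate_ensemble
from trajembed.trajectory_io import AtomRecord, CoordinateEnsemble


@pytest.fixture
def small_ensemble():
    """3 frames x 5 atoms, deterministic coordinates."""
    rng = np.random.default_rng(42)
    coords = rng.uniform(-5, 5, size=(3, 5, 3))
    meta = [AtomRecord(i + 1, "ALA", "CA") for i in range(5)]
    return CoordinateEnsemble(coords, np.arange(3.0), meta, source="fixture")


@pytest.fixture
def peptide_pdb(tmp_path):
    """3-model PDB of a 5-residue peptide."""
    rng = np.random.default_rng(7)
    path = tmp_path / "peptide.pdb"
    resnames = ["ALA", "GLY", "SER", "VAL", "LEU"]
    with open(path, "w") as fh:
        for model in range(1, 4):
            fh.write(f"MODEL     {model:4d}\n")
            serial = 1
            for res in range(5):
                base = np.array([3.8 * res, 0.0, 0.0]) + rng.normal(0, 0.3, 3)
                for name, offset in (("N", -0.7), ("CA", 0.0), ("C", 0.7)):
                    x, y, z = base + [offset, 0, 0]
                    fh.write(
                        f"ATOM  {serial:5d}  {name:<3s}{resnames[res]:>4s} A"
                        f"{res + 1:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
                        f"           {name[0]:>2s}\n")
                    serial += 1
            fh.write("ENDMDL\n")
        fh.write("END\n")
    return str(path)


@pytest.fixture(scope="session")
def two_state_bundle():
    """Small two-state synthetic ensemble with graphs, shared across tests."""
    spec = SyntheticSpec(n_residues=20, n_frames=120, noise_sigma=0.4, seed=202)
    ensemble, labels = generate_ensemble(spec)
    series = build_graph_series(ensemble)
    return ensemble, labels, series
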