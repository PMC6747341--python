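"""Shared fixtures: tiny hand-built systems and synthetic scenarios."""

import numpy as np
import pytest

from iondyn.model_io import MolecularSystem, Trajectory


def make_system(names, elements, resids, resnames, domains,
                charges=None, sigmas=None, epsilons=None, masses=None):
    n = len(names)
    default_mass = {"C": 12.011, "N": 14.007, "O": 15.999, "ZN": 65.38,
                    "CA": 40.078}
    return MolecularSystem(
        names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        resids=np.array(resids, dtype=int),
        resnames=np.array(resnames, dtype=object),
        chains=np.array(["0"] * n, dtype=object),
        charges=np.zeros(n) if charges is None else np.asarray(charges, float),
        sigmas=np.zeros(n) if sigmas is None else np.asarray(sigmas, float),
        epsilons=np.zeros(n) if epsilons is None else np.asarray(epsilons, float),
        masses=np.array([default_mass.get(e.upper(), 12.0) for e in elements])
        if masses is None else np.asarray(masses, float),
        domains=np.array(domains, dtype=object),
    )


@pytest.fixture
def point_system():
    """Factory for an n-bead carbon system with unit-ish bookkeeping."""
    def build(n, domain="other"):
        return make_system(
            names=[f"C{i}" for i in range(n)],
            elements=["C"] * n,
            resids=list(range(1, n + 1)),
            resnames=["LIG"] * n,
            domains=[domain] * n,
        )
    return build


@pytest.fixture
def static_traj():
    """Factory: a static trajectory of given coordinates repeated F times."""
    def build(coords, n_frames=5, box_edge=None):
        coords = np.asarray(coords, dtype=float)
        stacked = np.repeat(coords[None, :, :], n_frames, axis=0)
        box = None
        if box_edge is not None:
            box = np.tile(np.eye(3) * box_edge, (n_frames, 1, 1))
        return Trajectory(stacked, np.arange(n_frames, dtype=float), box)
    return build


@pytest.fixture
def toy_pdb(tmp_path):
    """A 3-atom PDB plus a matching parameter table on disk."""
    pdb = tmp_path / "toy.pdb"
    pdb.write_text(
        "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N\n"
        "ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C\n"
        "ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C\n"
        "END\n"
    )
    table = tmp_path / "params.tsv"
    table.write_text(
        "ALA N -0.47 0.3296 0.8368\n"
        "ALA CA 0.07 0.3564 0.4602\n"
        "ALA C 0.51 0.3564 0.4602\n"
    )
    return pdb, table


@pytest.fixture
def zn_pdb(tmp_path):
    """A PDB with one protein atom and a HETATM Zn ion."""
    pdb = tmp_path / "zn.pdb"
    pdb.write_text(
        "ATOM      1  CA  ALA A 110       0.000   0.000   0.000  1.00  0.00           C\n"
        "HETATM    2 ZN    ZN A 701       2.000   0.000   0.000  1.00  0.00          ZN\n"
        "END\n"
    )
    return pdb
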