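"""Single-structure (crystal) analyses for the MMP-2 reference state.

Given the 1CK7 coordinates, reproduce the static observables of the
biologically active enzyme: the pro-peptide (residues 31-109) is removed,
the radius of gyration and inter-domain center-of-mass distances of the
C-alpha trace are computed, and every bound divalent cation is characterised
by its ligand distances and coordination geometry.

The PDB file itself is not distributed with the package; download accession
1CK7 from the PDB and pass its path.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .energetics import assign_geometry, ion_site_distances
from .geometry import com_distance, radius_of_gyration
from .model_io import load_system, select

#: Ion-site pairs reported for the crystal structure: (ion resname, ion ordinal
#: within that species, ligand residue id, ligand atom name).
CRYSTAL_SITES = [
    ("ZN", 1, 403, "NE2"),   # catalytic Zn - His403
    ("ZN", 1, 407, "NE2"),
    ("ZN", 1, 413, "NE2"),
    ("ZN", 2, 178, "NE2"),   # structural Zn - His178
    ("ZN", 2, 180, "OD2"),
    ("ZN", 2, 193, "NE2"),
    ("ZN", 2, 206, "ND1"),
    ("CA", 1, 186, "O"),     # Ca1 - Gly186 backbone carbonyl
    ("CA", 3, 476, "O"),     # Ca3 - Asp476 backbone carbonyl
]


def crystal_report(structure_file: str | Path,
                   drop_propeptide: tuple[int, int] = (31, 109)) -> dict:
    """Static geometry report for a processed MMP-2 crystal structure.

    Returns Rg of the C-alpha trace (nm), Cat-Hpx and Fib-Hpx COM distances
    (nm), per-ion ligand distances for :data:`CRYSTAL_SITES` and the
    coordination-geometry label of every divalent cation.
    """
    system, traj = load_system(structure_file, strict=False)
    keep = ~((system.resids >= drop_propeptide[0])
             & (system.resids <= drop_propeptide[1])
             & ~np.isin(system.domains, ["ion", "solvent"]))
    keep_idx = np.flatnonzero(keep)

    def sel(expr):
        return np.intersect1d(select(system, expr), keep_idx)

    ca_trace = sel("name CA and not domain ion and not domain solvent")
    report: dict = {}
    rg = radius_of_gyration(traj, ca_trace, system.masses[ca_trace])
    report["rg_ca_nm"] = rg.values[0]

    cat_fib = sel("name CA and domain Cat or name CA and domain Fib")
    fib = sel("name CA and domain Fib")
    hpx = sel("name CA and domain Hpx")
    report["cat_hpx_com_nm"] = com_distance(
        traj, cat_fib, hpx, system.masses[cat_fib], system.masses[hpx]).values[0]
    report["fib_hpx_com_nm"] = com_distance(
        traj, fib, hpx, system.masses[fib], system.masses[hpx]).values[0]

    # ions in author order per species
    ions = {}
    for resname in ("ZN", "CA"):
        found = [i for i in select(system, "domain ion")
                 if str(system.resnames[i]).upper().startswith(resname)]
        for ordinal, atom in enumerate(found, start=1):
            ions[(resname, ordinal)] = int(atom)

    distances = {}
    geometries = {}
    for (resname, ordinal, resid, atom_name) in CRYSTAL_SITES:
        key = (resname, ordinal)
        if key not in ions:
            continue
        target = [i for i in np.flatnonzero(system.resids == resid)
                  if str(system.names[i]).upper() == atom_name]
        if not target:
            continue
        df = ion_site_distances(traj, ions[key], np.array(target))
        distances[f"{resname}{ordinal}-{resid}:{atom_name}"] = \
            float(df["mean_nm"].iloc[0])
    for (resname, ordinal), atom in ions.items():
        a = assign_geometry(traj.coords[0], atom, system)
        geometries[f"{resname}{ordinal}"] = a.label
    report["ion_site_distances_nm"] = distances
    report["ion_geometries"] = geometries
    return report
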