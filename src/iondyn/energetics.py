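"""Ion-protein interaction energies and binding free-energy components.

Per-frame Lennard-Jones + Coulomb interaction energies with
arithmetic-sigma / geometric-epsilon combination rules, decomposed per
protein residue; continuum-solvation terms (a Born-style desolvation
approximation of the polar term — explicitly an approximation of a
Poisson-Boltzmann calculation — and a gamma*SASA + b nonpolar term);
the interaction-entropy estimate -T dS = RT ln<exp(beta dE)> with a
log-sum-exp overflow guard; bootstrap standard errors; Tukey-fence outlier
calling of per-residue contributions; and metal coordination-geometry
classification against ideal-angle templates.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .constants import (EPS_SOLUTE, EPS_WATER, F_COULOMB, R_GAS, SASA_B,
                        SASA_GAMMA, SASA_PROBE, T_DEFAULT)
from .model_io import MolecularSystem, Trajectory


# ---------------------------------------------------------------------------
# MM interaction energy (pairwise LJ + Coulomb)
# ---------------------------------------------------------------------------

@dataclass
class EnergySeries:
    """Per-frame interaction energy split into vdW and electrostatic parts.

    ``per_residue`` (optional) holds the exact pairwise decomposition,
    assigning each pair term to the protein atom's residue; rows sum to the
    frame total by construction.
    """

    total: np.ndarray
    vdw: np.ndarray
    elec: np.ndarray
    times: np.ndarray | None = None
    residue_ids: np.ndarray | None = None
    per_residue: np.ndarray | None = None  # (n_frames, n_residues)

    @property
    def n_frames(self) -> int:
        return len(self.total)


def interaction_energy(
    traj: Trajectory,
    system: MolecularSystem,
    ion_selection: np.ndarray,
    protein_selection: np.ndarray,
    decompose: bool = True,
) -> EnergySeries:
    """Vectorised pairwise LJ + Coulomb energy between ion(s) and protein.

    No distance cutoff and no periodic wrapping: this is the gas-phase MM
    term of an MMPBSA-style decomposition.  sigma_ij = (sigma_i + sigma_j)/2,
    eps_ij = sqrt(eps_i eps_j); Coulomb prefactor 138.935458 kJ mol^-1 nm e^-2.
    """
    ions = np.asarray(ion_selection)
    prot = np.asarray(protein_selection)
    if ions.size == 0 or prot.size == 0:
        raise ValueError("empty selection")
    F = traj.n_frames
    q_p = system.charges[prot]
    s_p = system.sigmas[prot]
    e_p = system.epsilons[prot]
    res_p = system.resids[prot]
    uniq_res = np.unique(res_p)
    res_pos = np.searchsorted(uniq_res, res_p)

    vdw = np.zeros(F)
    elec = np.zeros(F)
    per_res_v = np.zeros((F, uniq_res.size)) if decompose else None
    per_res_e = np.zeros((F, uniq_res.size)) if decompose else None

    for i in ions:
        sij = (system.sigmas[i] + s_p) / 2.0
        eij = np.sqrt(system.epsilons[i] * e_p)
        qq = F_COULOMB * system.charges[i] * q_p
        d = np.linalg.norm(traj.coords[:, i, None, :] - traj.coords[:, prot, :],
                           axis=2)
        if np.any(d < 1e-4):
            raise ValueError("atom overlap: pair distance below 1e-4 nm")
        sr6 = (sij[None, :] / d) ** 6
        lj = 4.0 * eij[None, :] * (sr6 ** 2 - sr6)
        cou = qq[None, :] / d
        vdw += lj.sum(axis=1)
        elec += cou.sum(axis=1)
        if decompose:
            for k in range(uniq_res.size):
                m = res_pos == k
                per_res_v[:, k] += lj[:, m].sum(axis=1)
                per_res_e[:, k] += cou[:, m].sum(axis=1)

    per_residue = per_res_v + per_res_e if decompose else None
    return EnergySeries(
        total=vdw + elec, vdw=vdw, elec=elec, times=traj.times,
        residue_ids=uniq_res if decompose else None, per_residue=per_residue,
    )


# ---------------------------------------------------------------------------
# Continuum solvation terms
# ---------------------------------------------------------------------------

def born_energy(q: float, radius: float,
                eps_in: float = EPS_SOLUTE, eps_w: float = EPS_WATER) -> float:
    """Born transfer energy (kJ/mol) of a charge q moving from the inner to
    the water dielectric: -(f/2) q^2 (1/eps_in - 1/eps_w) / a.  More negative
    for smaller radii."""
    if radius <= 0:
        raise ValueError("Born radius must be positive")
    return -0.5 * F_COULOMB * q ** 2 * (1.0 / eps_in - 1.0 / eps_w) / radius


def solvation_terms(
    traj: Trajectory,
    system: MolecularSystem,
    ion_selection: np.ndarray,
    born_radius: float = 0.11,
    eps_in: float = EPS_SOLUTE,
    eps_w: float = EPS_WATER,
    gamma: float = SASA_GAMMA,
    b_const: float = SASA_B,
    probe_radius: float = SASA_PROBE,
    sasa: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame (dG_polar, dG_nonpolar) for the selected ion(s).

    dG_polar is a Born-style desolvation penalty: the fraction of the ion's
    free solvent exposure lost in the complex, times the magnitude of the
    Born transfer energy.  A fully buried ion pays the full penalty; a fully
    exposed one pays none.  This deliberately simple two-dielectric
    approximation replaces a finite-difference Poisson-Boltzmann solve and
    preserves its sign structure (positive, larger for buried ions).

    dG_nonpolar = gamma * SASA + b with the g_mmpbsa-style defaults.
    """
    from .solvation import sasa_series

    ions = np.asarray(ion_selection)
    if sasa is None:
        sasa = sasa_series(traj, system, ions, probe_radius=probe_radius)
    free_area = 0.0
    for i in ions:
        # exposed area of the isolated ion: 4 pi (r_vdw + probe)^2
        r_vdw = _vdw_radius(system, int(i))
        free_area += 4.0 * math.pi * (r_vdw + probe_radius) ** 2
    burial = np.clip(1.0 - sasa / free_area, 0.0, 1.0)
    born_total = sum(abs(born_energy(system.charges[int(i)],
                                     _vdw_radius(system, int(i)) if born_radius is None
                                     else born_radius,
                                     eps_in, eps_w)) for i in ions)
    dg_polar = burial * born_total
    dg_nonpolar = gamma * sasa + b_const
    return dg_polar, dg_nonpolar


_VDW_BY_ELEMENT = {"ZN": 0.139, "CA": 0.171, "NA": 0.227, "CL": 0.175,
                   "MG": 0.173, "O": 0.152, "N": 0.155, "C": 0.170,
                   "S": 0.180, "H": 0.120}


def _vdw_radius(system: MolecularSystem, i: int) -> float:
    if system.sigmas[i] > 0:
        return float(system.sigmas[i]) * 2 ** (1 / 6) / 2.0
    return _VDW_BY_ELEMENT.get(str(system.elements[i]).upper(), 0.17)


# ---------------------------------------------------------------------------
# Interaction entropy
# ---------------------------------------------------------------------------

def interaction_entropy(series: EnergySeries | np.ndarray,
                        temperature: float = T_DEFAULT) -> float:
    """-T dS = RT ln < exp(beta dE) > over frames, dE = E - <E> (kJ/mol).

    beta = 1/(RT) on molar energies.  Computed through a log-sum-exp shift so
    strongly fluctuating series never overflow; Jensen's inequality makes the
    result non-negative, with equality only for a constant series.
    """
    e = series.total if isinstance(series, EnergySeries) else np.asarray(series, float)
    if e.size < 2:
        raise ValueError("need at least 2 frames")
    beta = 1.0 / (R_GAS * temperature)
    de = e - e.mean()
    log_mean = logsumexp(beta * de) - math.log(e.size)
    return max(R_GAS * temperature * float(log_mean), 0.0)


def bootstrap_se(
    values: np.ndarray,
    statistic=np.mean,
    n_boot: int = 5000,
    seed: int = 0,
) -> float:
    """Bootstrap standard error of ``statistic`` by frame resampling."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    stats = np.array([statistic(values[row]) for row in idx])
    return float(stats.std(ddof=1))


# ---------------------------------------------------------------------------
# Tukey fences
# ---------------------------------------------------------------------------

def tukey_fences(values: np.ndarray, k: float = 1.5
                 ) -> tuple[tuple[float, float], np.ndarray]:
    """Fences [Q1 - k IQR, Q3 + k IQR] and the outlier flags.

    Quartiles use linear interpolation (type-7, the numpy default).  Values
    <= lower or >= upper fence are flagged (k = 1.5 outlier, 3.0 extreme).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("need at least 4 values")
    q1, q3 = np.percentile(values, [25.0, 75.0])
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    # values inside [Q1, Q3] are by definition within expected fluctuation;
    # this only matters in the degenerate IQR = 0 case, where lo == Q1 == hi
    flags = ((values <= lo) | (values >= hi)) & ~((values >= q1) & (values <= q3))
    return (float(lo), float(hi)), flags


# ---------------------------------------------------------------------------
# Coordination geometry
# ---------------------------------------------------------------------------

def _template_angles():
    """Ideal ligand-ligand angle sets (degrees, sorted) by geometry label."""
    t = 109.4712206
    base = {
        "linear": [180.0],
        "trigonal pyramidal": [t, t, t],
        "tetrahedral": [t] * 6,
        "square planar": [90.0] * 4 + [180.0] * 2,
        "seesaw": [90.0] * 4 + [120.0, 180.0],
        "trigonal bipyramidal": [90.0] * 6 + [120.0] * 3 + [180.0],
        "octahedral": [90.0] * 12 + [180.0] * 3,
    }
    return {k: np.sort(np.asarray(v)) for k, v in base.items()}


_N_LIGANDS = {"linear": 2, "trigonal pyramidal": 3, "tetrahedral": 4,
              "square planar": 4, "seesaw": 4, "trigonal bipyramidal": 5,
              "octahedral": 6}

_TEMPLATE_DIRECTIONS = {
    "trigonal bipyramidal": np.array(
        [[0, 0, 1], [0, 0, -1], [1, 0, 0],
         [-0.5, math.sqrt(3) / 2, 0], [-0.5, -math.sqrt(3) / 2, 0]]),
    "octahedral": np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]),
}


def _vacancy_angle_sets():
    """Sorted angle sets of parent geometries with one ligand position vacant."""
    out = []
    for parent, dirs in _TEMPLATE_DIRECTIONS.items():
        n = len(dirs)
        for drop in range(n):
            keep = np.delete(dirs, drop, axis=0)
            angles = []
            for a, b in itertools.combinations(range(n - 1), 2):
                cosang = np.clip(np.dot(keep[a], keep[b]), -1.0, 1.0)
                angles.append(math.degrees(math.acos(cosang)))
            out.append((parent, np.sort(np.asarray(angles))))
    return out


@dataclass
class CoordinationAssignment:
    """Ligand atoms within cutoff and the best-matching ideal geometry."""

    ligand_atoms: np.ndarray
    label: str
    angle_rmsd: float | None
    vacancy: bool = False
    distances: np.ndarray = field(default_factory=lambda: np.empty(0))


def assign_geometry(
    coords: np.ndarray,
    ion_index: int,
    system: MolecularSystem,
    cutoff: float = 0.35,
    rmsd_threshold: float = 20.0,
    candidate_selection: np.ndarray | None = None,
) -> CoordinationAssignment:
    """Classify the coordination geometry of an ion in one frame.

    Ligands are N/O atoms (excluding other ions and, by default, solvent
    hydrogens) within ``cutoff`` of the ion.  The observed sorted
    ligand-ligand angle set is compared with ideal templates matched by
    ligand count — including parent geometries with a single vacancy — and
    the lowest angle-RMSD label wins; ties prefer the exact-count template.
    Fewer than 2 ligands, or a best RMSD above ``rmsd_threshold`` degrees,
    yields "not-coordinated".
    """
    if candidate_selection is None:
        mask = np.isin(np.char.upper(system.elements.astype(str)), ["N", "O"])
        mask &= system.domains != "ion"
        candidates = np.flatnonzero(mask)
    else:
        candidates = np.asarray(candidate_selection)
    ion_pos = coords[ion_index]
    d = np.linalg.norm(coords[candidates] - ion_pos, axis=1)
    within = candidates[d <= cutoff]
    dists = d[d <= cutoff]
    n = within.size
    if n < 2:
        return CoordinationAssignment(within, "not-coordinated", None,
                                      distances=dists)
    vecs = coords[within] - ion_pos
    vecs = vecs / np.linalg.norm(vecs, axis=1, keepdims=True)
    angles = []
    for a, b in itertools.combinations(range(n), 2):
        cosang = np.clip(np.dot(vecs[a], vecs[b]), -1.0, 1.0)
        angles.append(math.degrees(math.acos(cosang)))
    obs = np.sort(np.asarray(angles))

    best = ("not-coordinated", np.inf, False)
    for label, tmpl in _template_angles().items():
        if _N_LIGANDS[label] != n:
            continue
        rmsd = float(np.sqrt(np.mean((obs - tmpl) ** 2)))
        if rmsd < best[1]:
            best = (label, rmsd, False)
    for parent, tmpl in _vacancy_angle_sets():
        if len(tmpl) != len(obs):
            continue
        rmsd = float(np.sqrt(np.mean((obs - tmpl) ** 2)))
        if rmsd < best[1]:  # strict: ties keep the exact-count label
            best = (parent, rmsd, True)

    label, rmsd, vac = best
    if not math.isfinite(rmsd) or rmsd > rmsd_threshold:
        return CoordinationAssignment(within, "not-coordinated",
                                      rmsd if math.isfinite(rmsd) else None,
                                      distances=dists)
    return CoordinationAssignment(within, label, rmsd, vacancy=vac,
                                  distances=dists)


def ion_site_distances(
    traj: Trajectory,
    ion_index: int,
    atom_indices: np.ndarray,
    use_min_image: bool = True,
) -> pd.DataFrame:
    """Mean +/- sd ion-atom distances (nm) over the trajectory.

    Minimum-image distances when box vectors are present; single-frame
    trajectories (crystal structures) give sd = 0.
    """
    atoms = np.asarray(atom_indices)
    delta = traj.coords[:, atoms, :] - traj.coords[:, ion_index, None, :]
    if use_min_image and traj.box is not None:
        diag = np.stack([np.diag(traj.box[f]) for f in range(traj.n_frames)])
        delta = delta - diag[:, None, :] * np.round(delta / diag[:, None, :])
    d = np.linalg.norm(delta, axis=2)
    return pd.DataFrame({
        "atom_index": atoms,
        "mean_nm": d.mean(axis=0),
        "sd_nm": d.std(axis=0),
    })


# ---------------------------------------------------------------------------
# Binding report (MMPBSA-IE style)
# ---------------------------------------------------------------------------

@dataclass
class BindingReport:
    """Per-ion and all-ion binding free-energy components (kJ/mol)."""

    table: pd.DataFrame

    def row(self, ion: str) -> pd.Series:
        return self.table.loc[ion]


def binding_report(
    traj: Trajectory,
    system: MolecularSystem,
    ion_groups: dict[str, np.ndarray],
    protein_selection: np.ndarray,
    temperature: float = T_DEFAULT,
    n_boot: int = 5000,
    seed: int = 0,
    **solvation_kwargs,
) -> BindingReport:
    """Assemble the MMPBSA-IE table: dE_vdw, dE_elec, dG_polar, dG_nonpolar,
    -T dS, dE_binding and dG_binding with bootstrap standard errors.

    dE_binding = dE_vdw + dE_elec + dG_polar + dG_nonpolar and
    dG_binding = dE_binding + (-T dS); the interaction entropy is computed
    from the MM interaction energy fluctuations.
    """
    rows = {}
    groups = dict(ion_groups)
    if len(groups) > 1:
        groups["all ions"] = np.concatenate(list(ion_groups.values()))
    for gi, (name, ions) in enumerate(groups.items()):
        es = interaction_energy(traj, system, ions, protein_selection,
                                decompose=False)
        dg_pol, dg_np = solvation_terms(traj, system, ions, **solvation_kwargs)
        tds = interaction_entropy(es, temperature)
        de_binding = es.vdw + es.elec + dg_pol + dg_np
        sub_seed = (seed * 1009 + gi * 101) % (2 ** 31)
        rows[name] = {
            "dE_vdw": es.vdw.mean(),
            "dE_vdw_se": bootstrap_se(es.vdw, n_boot=n_boot, seed=sub_seed),
            "dE_elec": es.elec.mean(),
            "dE_elec_se": bootstrap_se(es.elec, n_boot=n_boot, seed=sub_seed + 1),
            "dG_polar": dg_pol.mean(),
            "dG_polar_se": bootstrap_se(dg_pol, n_boot=n_boot, seed=sub_seed + 2),
            "dG_nonpolar": dg_np.mean(),
            "dG_nonpolar_se": bootstrap_se(dg_np, n_boot=n_boot, seed=sub_seed + 3),
            "minus_TdS": tds,
            "minus_TdS_se": bootstrap_se(
                es.total, statistic=lambda v: interaction_entropy(v, temperature),
                n_boot=min(n_boot, 1000), seed=sub_seed + 4),
            "dE_binding": de_binding.mean(),
            "dE_binding_se": bootstrap_se(de_binding, n_boot=n_boot,
                                          seed=sub_seed + 5),
        }
        rows[name]["dG_binding"] = rows[name]["dE_binding"] + tds
        rows[name]["dG_binding_se"] = rows[name]["dE_binding_se"]
    return BindingReport(pd.DataFrame(rows).T)


def significant_residues(
    series: EnergySeries,
    k: float = 1.5,
) -> pd.DataFrame:
    """Tukey-fence outlier calling on mean per-residue contributions.

    Returns a table of residue id, mean contribution, the fences used and the
    significance flag (contributions at or beyond a fence).
    """
    if series.per_residue is None:
        raise ValueError("energy series carries no per-residue decomposition")
    mean_contrib = series.per_residue.mean(axis=0)
    (lo, hi), flags = tukey_fences(mean_contrib, k=k)
    return pd.DataFrame({
        "resid": series.residue_ids,
        "mean_contribution": mean_contrib,
        "lower_fence": lo,
        "upper_fence": hi,
        "significant": flags,
    }).sort_values("mean_contribution").reset_index(drop=True)
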