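"""Synthetic trajectories with planted ground truth.

Four scenario generators emulate the statistical structure of the real
analyses without being an MD engine:

* ``gen_dihedral_states`` — a polyalanine-like chain hopping between K
  backbone-dihedral states with wrapped-Gaussian jitter and planted
  populations (multi-basin free-energy landscapes).
* ``gen_domain_motion`` — rigid pseudo-domains of C-alpha beads translating
  in phase, in anti-phase or independently, plus thermal noise (planted
  cross-correlation sign matrix).
* ``gen_ion_pocket`` — a divalent ion fluctuating among fixed charged
  Lennard-Jones sites; the exact per-frame interaction energy is computed
  here by a deliberately naive double loop, independent of the vectorised
  energetics module, and serves as its oracle.
* ``gen_hydration_shells`` — solvent-oxygen points in concentric shells of
  controlled occupancy around a central ion, with an ideal-gas background.

Identical seed and spec give byte-identical trajectories.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import F_COULOMB, ION_LJ, R_GAS
from .model_io import DomainConfig, MolecularSystem, Trajectory, write_trajectory

_BACKBONE_GEOMETRY = {
    # bond lengths (nm) and angles (deg) of an idealised peptide backbone
    "b_n_ca": 0.1458, "b_ca_c": 0.1525, "b_c_n": 0.1329,
    "a_c_n_ca": 121.7, "a_n_ca_c": 111.2, "a_ca_c_n": 116.7,
    "omega": 180.0,
}


@dataclass
class SyntheticSpec:
    """A scenario request: name, length, timestep, seed, free parameters."""

    scenario: str
    n_frames: int
    dt_ns: float = 0.1
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        pops = self.params.get("populations")
        if pops is not None and not math.isclose(sum(pops), 1.0, abs_tol=1e-9):
            raise ValueError("populations must sum to 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames, dtype=float) * self.dt_ns


def _bead_system(resnames, names, elements, resids, domains,
                 charges=None, sigmas=None, epsilons=None, masses=None,
                 domain_config=None) -> MolecularSystem:
    n = len(names)
    elem_mass = {"C": 12.011, "N": 14.007, "O": 15.999, "ZN": 65.38, "CA": 40.078}
    return MolecularSystem(
        names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        resids=np.array(resids, dtype=int),
        resnames=np.array(resnames, dtype=object),
        chains=np.array(["0"] * n, dtype=object),
        charges=np.zeros(n) if charges is None else np.asarray(charges, float),
        sigmas=np.zeros(n) if sigmas is None else np.asarray(sigmas, float),
        epsilons=np.zeros(n) if epsilons is None else np.asarray(epsilons, float),
        masses=np.array([elem_mass.get(str(e).upper(), 12.011) for e in elements])
        if masses is None else np.asarray(masses, float),
        domains=np.array(domains, dtype=object),
        domain_config=domain_config,
    )


# ---------------------------------------------------------------------------
# Backbone construction (NeRF), vectorised across frames
# ---------------------------------------------------------------------------

def _place_atom(a, b, c, bond, angle_deg, torsion_rad):
    """Place D from A,B,C with bond |CD|, angle B-C-D and torsion A-B-C-D.

    All of a, b, c are (F, 3); torsion_rad is scalar or (F,).
    """
    theta = math.radians(angle_deg)
    phi = np.broadcast_to(np.asarray(torsion_rad, dtype=float), a.shape[:1]).copy()
    bc = c - b
    bc /= np.linalg.norm(bc, axis=1, keepdims=True)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    m = np.cross(n, bc)
    d_local = np.stack([
        -bond * math.cos(theta) * np.ones_like(phi),
        bond * math.sin(theta) * np.cos(phi),
        bond * math.sin(theta) * np.sin(phi),
    ], axis=1)
    return c + (bc * d_local[:, :1] + m * d_local[:, 1:2] + n * d_local[:, 2:3])


def build_backbone(phi: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Build N/CA/C backbone coordinates from dihedrals.

    ``phi``/``psi`` have shape (F, n_res); phi of the first residue and psi of
    the last are ignored (undefined at chain termini).  Returns (F, 3*n_res, 3).
    """
    g = _BACKBONE_GEOMETRY
    F, n_res = phi.shape
    coords = np.zeros((F, 3 * n_res, 3))
    # First residue: N at origin, CA on x, C in the xy-plane.
    coords[:, 1, 0] = g["b_n_ca"]
    ang = math.radians(g["a_n_ca_c"])
    coords[:, 2, 0] = g["b_n_ca"] - g["b_ca_c"] * math.cos(ang)
    coords[:, 2, 1] = g["b_ca_c"] * math.sin(ang)
    omega = math.radians(g["omega"])
    for i in range(1, n_res):
        nprev, caprev, cprev = 3 * i - 3, 3 * i - 2, 3 * i - 1
        ni, cai, ci = 3 * i, 3 * i + 1, 3 * i + 2
        coords[:, ni] = _place_atom(coords[:, nprev], coords[:, caprev],
                                    coords[:, cprev], g["b_c_n"],
                                    g["a_ca_c_n"], psi[:, i - 1])
        coords[:, cai] = _place_atom(coords[:, caprev], coords[:, cprev],
                                     coords[:, ni], g["b_n_ca"],
                                     g["a_c_n_ca"], omega)
        coords[:, ci] = _place_atom(coords[:, cprev], coords[:, ni],
                                    coords[:, cai], g["b_ca_c"],
                                    g["a_n_ca_c"], phi[:, i])
    return coords


def _wrap_angle(x: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    y = np.mod(x + np.pi, 2 * np.pi) - np.pi
    y[y == -np.pi] = np.pi
    return y


# ---------------------------------------------------------------------------
# Scenario 1: multi-state dihedral dynamics
# ---------------------------------------------------------------------------

def gen_dihedral_states(spec: SyntheticSpec):
    """Multi-basin backbone-dihedral trajectory with planted state populations.

    params:
        n_res (int, default 8); populations (list, sums to 1);
        states (list of dicts with 'phi'/'psi' in degrees, scalar or per
        residue; default: alpha-helical and extended basins);
        jitter_deg (wrapped-normal sd, default 10).

    Returns ``(system, trajectory, labels)`` where ``labels`` is the
    ground-truth per-frame state index.
    """
    p = spec.params
    n_res = int(p.get("n_res", 8))
    populations = np.asarray(p.get("populations", [0.9, 0.1]), dtype=float)
    if not math.isclose(populations.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("populations must sum to 1")
    default_states = [{"phi": -57.0, "psi": -47.0}, {"phi": -120.0, "psi": 130.0}]
    states = p.get("states", default_states[: len(populations)])
    if len(states) != len(populations):
        raise ValueError("need one state definition per population")
    jitter = math.radians(float(p.get("jitter_deg", 10.0)))

    rng = spec.rng()
    labels = rng.choice(len(states), size=spec.n_frames, p=populations)
    phi = np.empty((spec.n_frames, n_res))
    psi = np.empty((spec.n_frames, n_res))
    for k, st in enumerate(states):
        mask = labels == k
        nmask = int(mask.sum())
        phi_mean = np.broadcast_to(np.radians(np.asarray(st["phi"], float)), (n_res,))
        psi_mean = np.broadcast_to(np.radians(np.asarray(st["psi"], float)), (n_res,))
        phi[mask] = phi_mean[None, :]
        psi[mask] = psi_mean[None, :]
        if jitter > 0 and nmask:
            phi[mask] += rng.normal(0.0, jitter, size=(nmask, n_res))
            psi[mask] += rng.normal(0.0, jitter, size=(nmask, n_res))
    phi = _wrap_angle(phi)
    psi = _wrap_angle(psi)

    coords = build_backbone(phi, psi)
    names, elements, resids, resnames, domains = [], [], [], [], []
    for i in range(n_res):
        for nm, el in (("N", "N"), ("CA", "C"), ("C", "C")):
            names.append(nm)
            elements.append(el)
            resids.append(i + 1)
            resnames.append("ALA")
            domains.append("other")
    system = _bead_system(resnames, names, elements, resids, domains)
    traj = Trajectory(coords, spec.times())
    return system, traj, labels


# ---------------------------------------------------------------------------
# Scenario 2: rigid-body correlated domain motion
# ---------------------------------------------------------------------------

_DOMAIN_LABELS = ["Cat", "Fib", "Hpx", "Lnk"]


def gen_domain_motion(spec: SyntheticSpec):
    """Rigid pseudo-domains with planted correlated/anti-correlated motion.

    params:
        modes (list over domains of '+', '-' or 'indep'; default ['+','-']);
        beads_per_domain (default 10); amplitude (nm sd of the collective
        displacement, default 0.1); noise (per-atom isotropic sd, default 0.01).

    Returns ``(system, trajectory, sign_matrix)`` where ``sign_matrix[a][b]``
    is +1/-1 for planted correlation between domains a and b and 0 where a
    pair involves an independent domain.
    """
    p = spec.params
    modes = list(p.get("modes", ["+", "-"]))
    n_dom = len(modes)
    if n_dom < 2:
        raise ValueError("need at least two domains")
    nb = int(p.get("beads_per_domain", 10))
    amp = float(p.get("amplitude", 0.1))
    noise = float(p.get("noise", 0.01))

    rng = spec.rng()
    F = spec.n_frames
    axis = np.array([0.0, 0.0, 1.0])
    shared = rng.normal(0.0, amp, size=F)
    coords = np.empty((F, n_dom * nb, 3))
    names, elements, resids, resnames, domains = [], [], [], [], []
    rid = 0
    for d, mode in enumerate(modes):
        center = np.array([3.0 * d, 0.0, 0.0])
        offsets = rng.normal(0.0, 0.3, size=(nb, 3))
        if mode == "+":
            signal = shared
        elif mode == "-":
            signal = -shared
        elif mode in ("indep", "0"):
            signal = rng.normal(0.0, amp, size=F)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        disp = signal[:, None] * axis[None, :]
        block = center[None, None, :] + offsets[None, :, :] + disp[:, None, :]
        block = block + rng.normal(0.0, noise, size=(F, nb, 3))
        coords[:, d * nb:(d + 1) * nb, :] = block
        label = _DOMAIN_LABELS[d] if d < len(_DOMAIN_LABELS) else "other"
        for b in range(nb):
            rid += 1
            names.append("CA")
            elements.append("C")
            resids.append(rid)
            resnames.append("ALA")
            domains.append(label)

    sign = np.zeros((n_dom, n_dom), dtype=int)
    coeff = {"+": 1, "-": -1}
    for a in range(n_dom):
        for b in range(n_dom):
            ca, cb = coeff.get(modes[a], 0), coeff.get(modes[b], 0)
            sign[a, b] = int(np.sign(ca * cb)) if a != b else 1
    system = _bead_system(resnames, names, elements, resids, domains)
    return system, Trajectory(coords, spec.times()), sign


# ---------------------------------------------------------------------------
# Scenario 3: ion in a pocket of LJ + Coulomb sites
# ---------------------------------------------------------------------------

def naive_pair_energy(r: float, qi: float, qj: float,
                      si: float, sj: float, ei: float, ej: float) -> float:
    """Single-pair LJ + Coulomb energy with arithmetic-sigma / geometric-epsilon
    combination rules; plain scalar arithmetic on purpose (oracle path)."""
    sij = (si + sj) / 2.0
    eij = math.sqrt(ei * ej)
    lj = 0.0
    if eij > 0.0:
        sr6 = (sij / r) ** 6
        lj = 4.0 * eij * (sr6 * sr6 - sr6)
    return lj + F_COULOMB * qi * qj / r


def naive_interaction_energy(ion_pos, ion_q, ion_sigma, ion_eps, sites) -> float:
    """Deliberately naive double loop over sites; the anti-circular oracle for
    the vectorised energetics module."""
    total = 0.0
    for (pos, q, s, e) in sites:
        dx = ion_pos[0] - pos[0]
        dy = ion_pos[1] - pos[1]
        dz = ion_pos[2] - pos[2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        total += naive_pair_energy(r, ion_q, q, ion_sigma, s, ion_eps, e)
    return total


def _default_sites():
    """Four partially charged O-like sites at tetrahedral vertices (0.25 nm)."""
    verts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float)
    verts *= 0.25 / math.sqrt(3.0)
    return [(v.copy(), -0.5, 0.30, 0.50) for v in verts]


def gen_ion_pocket(spec: SyntheticSpec):
    """Divalent ion fluctuating in a pocket; exact energies as ground truth.

    params:
        sites (list of (xyz, q, sigma, epsilon); default 4-site pocket);
        ion ('ZN' or 'CA', default 'ZN'); sampling ('gaussian' | 'metropolis');
        sigma_pos (nm, gaussian mode, default 0.03); center (xyz);
        temperature (K, metropolis mode, default 310); step (nm, default 0.01);
        n_burn (default 200).

    Returns ``(system, trajectory, energies)``; ``energies`` is the per-frame
    naive-loop interaction energy (kJ/mol).
    """
    p = spec.params
    sites = p.get("sites", _default_sites())
    sites = [(np.asarray(pos, float), float(q), float(s), float(e))
             for (pos, q, s, e) in sites]
    ion_name = str(p.get("ion", "ZN")).upper()
    ion_q = 2.0
    ion_sigma, ion_eps = ION_LJ[ion_name]
    mode = p.get("sampling", "gaussian")
    rng = spec.rng()
    F = spec.n_frames
    center = np.asarray(p.get("center", [0.0, 0.0, 0.0]), float)

    def too_close(pos):
        return any(np.linalg.norm(pos - s[0]) < 0.05 for s in sites)

    positions = np.empty((F, 3))
    if mode == "gaussian":
        sigma_pos = float(p.get("sigma_pos", 0.03))
        for f in range(F):
            while True:
                pos = center + rng.normal(0.0, sigma_pos, size=3)
                if sigma_pos == 0.0 or not too_close(pos):
                    break
            positions[f] = pos
    elif mode == "metropolis":
        T = float(p.get("temperature", 310.0))
        beta = 1.0 / (R_GAS * T)
        step = float(p.get("step", 0.01))
        n_burn = int(p.get("n_burn", 200))
        pos = center.copy()
        if too_close(pos):
            pos = pos + np.array([0.06, 0.0, 0.0])
        e_cur = naive_interaction_energy(pos, ion_q, ion_sigma, ion_eps, sites)
        f = 0
        it = 0
        while f < F:
            prop = pos + rng.normal(0.0, step, size=3)
            if not too_close(prop):
                e_prop = naive_interaction_energy(prop, ion_q, ion_sigma,
                                                  ion_eps, sites)
                if e_prop <= e_cur or rng.random() < math.exp(-beta * (e_prop - e_cur)):
                    pos, e_cur = prop, e_prop
            it += 1
            if it > n_burn:
                positions[f] = pos
                f += 1
    else:
        raise ValueError(f"unknown sampling mode {mode!r}")

    energies = np.array([
        naive_interaction_energy(positions[f], ion_q, ion_sigma, ion_eps, sites)
        for f in range(F)
    ])

    n_sites = len(sites)
    names = [ion_name] + [f"OE{i+1}" for i in range(n_sites)]
    elements = [ion_name] + ["O"] * n_sites
    resids = [1] + [101 + i for i in range(n_sites)]
    resnames = [ion_name] + ["GLU"] * n_sites
    domains = ["ion"] + ["Cat"] * n_sites
    charges = [ion_q] + [s[1] for s in sites]
    sigmas = [ion_sigma] + [s[2] for s in sites]
    epsilons = [ion_eps] + [s[3] for s in sites]
    system = _bead_system(resnames, names, elements, resids, domains,
                          charges=charges, sigmas=sigmas, epsilons=epsilons)
    coords = np.empty((F, 1 + n_sites, 3))
    coords[:, 0, :] = positions
    for i, s in enumerate(sites):
        coords[:, 1 + i, :] = s[0][None, :]
    L = float(p.get("box", 5.0))
    box = np.tile(np.eye(3) * L, (F, 1, 1))
    return system, Trajectory(coords, spec.times(), box), energies


# ---------------------------------------------------------------------------
# Scenario 4: hydration shells
# ---------------------------------------------------------------------------

def gen_hydration_shells(spec: SyntheticSpec):
    """Central ion with solvent oxygens in shells of controlled occupancy.

    params:
        box (cubic edge nm, default 4.0); shells (list of (radius, occupancy);
        occupancy may be fractional -> Bernoulli presence); radial_jitter
        (default 0.005 nm); n_background (ideal-gas oxygens, default 0);
        core_radius (excluded core for the background, default 0.0);
        park_radius (where absent shell molecules are stored, default 0.45*box).

    Fractional occupancies are realised by teleporting the molecule outside
    ``park_radius`` in frames where it is absent, keeping the atom count
    constant.  Returns ``(system, trajectory)``; the planted shell parameters
    are the ground truth.
    """
    p = spec.params
    L = float(p.get("box", 4.0))
    shells = [(float(r), float(o)) for r, o in p.get("shells", [(0.22, 1.0)])]
    for r, _ in shells:
        if r >= L / 2:
            raise ValueError("shell radius exceeds half the box")
    jitter = float(p.get("radial_jitter", 0.005))
    n_bg = int(p.get("n_background", 0))
    core = float(p.get("core_radius", 0.0))
    park = float(p.get("park_radius", 0.45 * L))
    rng = spec.rng()
    F = spec.n_frames
    center = np.full(3, L / 2.0)

    def random_dirs(n):
        v = rng.normal(size=(n, 3))
        return v / np.linalg.norm(v, axis=1, keepdims=True)

    blocks = []
    for r_s, occ in shells:
        n_slots = max(1, math.ceil(occ))
        pos = np.empty((F, n_slots, 3))
        for f in range(F):
            k_full = int(occ) if float(occ).is_integer() else int(math.floor(occ)) + \
                int(rng.random() < (occ - math.floor(occ)))
            k_full = min(k_full, n_slots)
            dirs = random_dirs(n_slots)
            radii = r_s + rng.normal(0.0, jitter, size=n_slots) if jitter > 0 \
                else np.full(n_slots, r_s)
            pts = center + dirs * radii[:, None]
            for slot in range(k_full, n_slots):
                d = random_dirs(1)[0]
                rr = park + rng.random() * (L / 2.0 * 0.98 - park)
                pts[slot] = center + d * rr
            pos[f] = pts
        blocks.append(pos)

    if n_bg:
        bg = np.empty((F, n_bg, 3))
        for f in range(F):
            filled = 0
            while filled < n_bg:
                cand = rng.random((n_bg - filled, 3)) * L
                if core > 0:
                    keep = np.linalg.norm(cand - center, axis=1) >= core
                    cand = cand[keep]
                bg[f, filled:filled + len(cand)] = cand
                filled += len(cand)
        blocks.append(bg)

    n_solvent = sum(b.shape[1] for b in blocks)
    coords = np.empty((F, 1 + n_solvent, 3))
    coords[:, 0, :] = center[None, :]
    at = 1
    for b in blocks:
        coords[:, at:at + b.shape[1], :] = b
        at += b.shape[1]

    names = ["ZN"] + ["O"] * n_solvent
    elements = ["ZN"] + ["O"] * n_solvent
    resids = [1] + list(range(2, 2 + n_solvent))
    resnames = ["ZN"] + ["HOH"] * n_solvent
    domains = ["ion"] + ["solvent"] * n_solvent
    system = _bead_system(resnames, names, elements, resids, domains,
                          charges=[2.0] + [0.0] * n_solvent)
    box = np.tile(np.eye(3) * L, (F, 1, 1))
    return system, Trajectory(coords, spec.times(), box)


# ---------------------------------------------------------------------------
# Dispatch and sidecar output
# ---------------------------------------------------------------------------

GENERATORS = {
    "dihedral_states": gen_dihedral_states,
    "domain_motion": gen_domain_motion,
    "ion_pocket": gen_ion_pocket,
    "hydration_shells": gen_hydration_shells,
}


def generate(spec: SyntheticSpec):
    if spec.scenario not in GENERATORS:
        raise ValueError(f"unknown scenario {spec.scenario!r}")
    return GENERATORS[spec.scenario](spec)


def write_scenario(spec: SyntheticSpec, outdir: str | Path) -> dict:
    """Generate a scenario; write PDB + XTC + ground-truth JSON sidecar.

    A scenario-specific parameter table (``<scenario>.params.tsv``) is also
    written so the exact per-atom charges and LJ parameters survive a round
    trip through the file-based loaders.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = generate(spec)
    system, traj = result[0], result[1]
    truth = result[2] if len(result) > 2 else None
    write_trajectory(traj.slice_frames([0]), system, outdir / f"{spec.scenario}.pdb")
    write_trajectory(traj, system, outdir / f"{spec.scenario}.xtc")
    seen = {}
    for i in range(system.n_atoms):
        key = (str(system.resnames[i]), str(system.names[i]))
        seen.setdefault(key, (system.charges[i], system.sigmas[i],
                              system.epsilons[i]))
    with open(outdir / f"{spec.scenario}.params.tsv", "w") as fh:
        fh.write("# scenario parameter table: resname atomname q sigma epsilon\n")
        for (res, name), (q, s, e) in seen.items():
            fh.write(f"{res}\t{name}\t{q:.10g}\t{s:.12g}\t{e:.12g}\n")
    sidecar = {
        "scenario": spec.scenario,
        "n_frames": spec.n_frames,
        "dt_ns": spec.dt_ns,
        "seed": spec.seed,
        "params": {k: v for k, v in spec.params.items() if _jsonable(v)},
    }
    if truth is not None:
        sidecar["ground_truth"] = np.asarray(truth).tolist()
    (outdir / f"{spec.scenario}.truth.json").write_text(json.dumps(sidecar, indent=1))
    return sidecar


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False
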