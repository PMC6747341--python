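"""Conformational-stability observables.

Superposition RMSD, per-residue RMSF, radius of gyration, inter-domain
center-of-mass distances and the minimum distance between periodic images.
All lengths are in nm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .model_io import MolecularSystem, Trajectory


@dataclass
class GeometrySeries:
    """A named per-frame scalar observable over a selection."""

    name: str
    values: np.ndarray
    times: np.ndarray
    selection: np.ndarray | None = None
    reference_frame: int | None = None

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def std(self) -> float:
        return float(np.std(self.values, ddof=0))


# ---------------------------------------------------------------------------
# Superposition (Kabsch)
# ---------------------------------------------------------------------------

def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference``; the rotation
    is proper (det = +1), so mirror-related structures keep a positive RMSD.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.shape[0] < 3:
        raise ValueError("superpose needs two equal sets of >= 3 points")
    if weights is None:
        w = np.ones(mobile.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
    wsum = w.sum()
    mu_m = (w[:, None] * mobile).sum(0) / wsum
    mu_r = (w[:, None] * reference).sum(0) / wsum
    X = mobile - mu_m
    Y = reference - mu_r
    # Degeneracy check: all points collinear -> rotation about the line is free.
    cov_pts = (w[:, None] * X).T @ X
    eig = np.linalg.eigvalsh(cov_pts)
    if eig[1] <= 1e-12 * max(eig[2], 1e-300):
        raise ValueError("degenerate geometry: points are collinear")
    H = (w[:, None] * X).T @ Y
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_r - R @ mu_m
    moved = X @ R.T
    rmsd = float(np.sqrt((w * ((moved - Y) ** 2).sum(1)).sum() / wsum))
    return R, t, rmsd


def rmsd_between(a: np.ndarray, b: np.ndarray, weights=None) -> float:
    return superpose(a, b, weights)[2]


def _apply_superposition(coords: np.ndarray, reference: np.ndarray,
                         weights: np.ndarray | None) -> np.ndarray:
    """Superpose every frame of ``coords`` (F,N,3) onto ``reference``."""
    out = np.empty_like(coords)
    for f in range(coords.shape[0]):
        R, t, _ = superpose(coords[f], reference, weights)
        out[f] = coords[f] @ R.T + t
    return out


def average_structure(
    coords: np.ndarray,
    weights: np.ndarray | None = None,
    max_iter: int = 10,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Iteratively converged mean structure and the superposed frames.

    Frames are superposed onto the running mean until the mean moves by less
    than ``tol`` nm RMS (two passes normally suffice).
    """
    fitted = coords - coords.mean(axis=1, keepdims=True)
    mean = fitted[0].copy()
    for _ in range(max_iter):
        fitted = _apply_superposition(fitted, mean, weights)
        new_mean = fitted.mean(axis=0)
        shift = float(np.sqrt(((new_mean - mean) ** 2).sum(1).mean()))
        mean = new_mean
        if shift < tol:
            break
    return mean, fitted


def rmsd_series(
    traj: Trajectory,
    selection: np.ndarray,
    weights: np.ndarray | None = None,
) -> GeometrySeries:
    """Per-frame RMSD of a selection from its time-average structure."""
    selection = np.asarray(selection)
    if selection.size == 0:
        raise ValueError("empty selection")
    sub = traj.coords[:, selection, :]
    mean, fitted = average_structure(sub, weights)
    if weights is None:
        w = np.ones(selection.size)
    else:
        w = np.asarray(weights, dtype=float)
    dev2 = ((fitted - mean) ** 2).sum(2)
    vals = np.sqrt((dev2 * w).sum(1) / w.sum())
    return GeometrySeries("rmsd", vals, traj.times, selection)


def rmsf_per_atom(
    traj: Trajectory,
    selection: np.ndarray,
    fit_selection: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """RMS fluctuation of each selected atom about its time-mean position.

    Frames are superposed on ``fit_selection`` (default: the selection itself).
    Passing the protein C-alpha trace as ``fit_selection`` while selecting an
    ion measures the ion's excursion relative to the protein frame, which is
    how ion RMSF values are reported.
    """
    selection = np.asarray(selection)
    if selection.size == 0:
        raise ValueError("empty selection")
    fit_sel = selection if fit_selection is None else np.asarray(fit_selection)
    fit_sub = traj.coords[:, fit_sel, :]
    mean_fit, _ = average_structure(fit_sub, weights)
    coords = np.empty_like(traj.coords[:, selection, :])
    for f in range(traj.n_frames):
        R, t, _ = superpose(traj.coords[f, fit_sel], mean_fit, weights)
        coords[f] = traj.coords[f, selection] @ R.T + t
    mean_pos = coords.mean(axis=0)
    return np.sqrt(((coords - mean_pos) ** 2).sum(2).mean(0))


def rmsf_per_residue(
    traj: Trajectory,
    system: MolecularSystem,
    selection: np.ndarray,
    fit_selection: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue RMSF: atom RMSF mass-averaged within each residue.

    Returns ``(resids, rmsf)`` sorted by residue id.
    """
    atom_rmsf = rmsf_per_atom(traj, selection, fit_selection)
    resids = system.resids[selection]
    masses = system.masses[selection]
    out_res = np.unique(resids)
    out = np.empty(out_res.size)
    for k, r in enumerate(out_res):
        m = resids == r
        out[k] = float((atom_rmsf[m] * masses[m]).sum() / masses[m].sum())
    return out_res, out


def radius_of_gyration(
    traj: Trajectory,
    selection: np.ndarray,
    masses: np.ndarray | None = None,
) -> GeometrySeries:
    """Per-frame radius of gyration; mass-weighted when masses are given."""
    selection = np.asarray(selection)
    if selection.size == 0:
        raise ValueError("empty selection")
    sub = traj.coords[:, selection, :]
    if masses is None:
        w = np.ones(selection.size)
    else:
        w = np.asarray(masses, dtype=float)
    w = w / w.sum()
    com = (sub * w[None, :, None]).sum(1, keepdims=True)
    rg = np.sqrt(((sub - com) ** 2).sum(2) @ w)
    return GeometrySeries("rg", rg, traj.times, selection)


def com_distance(
    traj: Trajectory,
    selection_a: np.ndarray,
    selection_b: np.ndarray,
    masses_a: np.ndarray | None = None,
    masses_b: np.ndarray | None = None,
) -> GeometrySeries:
    """Per-frame Euclidean distance between mass-weighted centers of mass.

    No periodic wrapping is applied: the inputs are assumed to be whole
    (unwrapped) molecules, since a domain split across the boundary has no
    meaningful center of mass.
    """
    def com(sel, masses):
        sel = np.asarray(sel)
        if sel.size == 0:
            raise ValueError("empty selection")
        sub = traj.coords[:, sel, :]
        w = np.ones(sel.size) if masses is None else np.asarray(masses, float)
        w = w / w.sum()
        return (sub * w[None, :, None]).sum(1)

    d = np.linalg.norm(com(selection_a, masses_a) - com(selection_b, masses_b), axis=1)
    return GeometrySeries("com_distance", d, traj.times)


def min_periodic_distance(traj: Trajectory, selection: np.ndarray) -> GeometrySeries:
    """Per-frame minimum distance between the selection and its periodic images.

    All 26 neighbouring lattice translations of an orthorhombic (or triclinic)
    box are searched with a KD-tree; a single atom therefore reports the
    shortest box vector, and a rod of length d centred in a cubic box of side
    L reports L - d.
    """
    if traj.box is None:
        raise ValueError("missing box vectors")
    selection = np.asarray(selection)
    if selection.size == 0:
        raise ValueError("empty selection")
    shifts = [np.array([i, j, k]) for i in (-1, 0, 1) for j in (-1, 0, 1)
              for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)]
    vals = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        pts = traj.coords[f, selection, :]
        tree = cKDTree(pts)
        best = np.inf
        for s in shifts:
            shift_vec = s @ traj.box[f]
            d, _ = tree.query(pts + shift_vec, k=1)
            best = min(best, float(d.min()))
        vals[f] = best
    return GeometrySeries("min_periodic_distance", vals, traj.times, selection)
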