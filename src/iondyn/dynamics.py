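"""Domain-movement analysis.

Cartesian covariance of the C-alpha trace, the dynamic cross-correlation
matrix (DCCM) of Pearson coefficients between per-atom displacement vectors,
and Cartesian PCA with per-component RMSF projections and variance fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import average_structure
from .model_io import Trajectory


def covariance_matrix(
    traj: Trajectory,
    selection: np.ndarray,
    superpose: bool = True,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """3N x 3N covariance (nm^2) of the selected atoms' centered coordinates.

    With ``superpose=True`` (the default for internal-motion analysis) every
    frame is first fitted onto the iteratively converged mean structure,
    removing the six rigid-body degrees of freedom.  Planted rigid-body
    scenarios should pass ``superpose=False`` so collective translations
    survive.
    """
    selection = np.asarray(selection)
    sub = traj.coords[:, selection, :]
    if superpose:
        _, sub = average_structure(sub, weights)
    F = sub.shape[0]
    X = sub.reshape(F, -1)
    Xc = X - X.mean(axis=0)
    return (Xc.T @ Xc) / max(F - 1, 1)


@dataclass
class DCCM:
    """Pearson cross-correlation of atomic displacement vectors.

    ``matrix[i, j] = <dr_i . dr_j> / sqrt(<dr_i^2><dr_j^2>)``; atoms without
    fluctuation are flagged in ``defined`` and their rows/columns set to 0
    rather than propagating NaNs.
    """

    matrix: np.ndarray
    defined: np.ndarray
    resids: np.ndarray | None = None
    domain_blocks: dict | None = None

    def block_mean(self, idx_a: np.ndarray, idx_b: np.ndarray) -> float:
        return float(self.matrix[np.ix_(idx_a, idx_b)].mean())


def dccm(cov: np.ndarray, resids: np.ndarray | None = None,
         domain_blocks: dict | None = None) -> DCCM:
    """DCCM from a 3N x 3N covariance matrix."""
    n3 = cov.shape[0]
    if cov.ndim != 2 or cov.shape[1] != n3 or n3 % 3:
        raise ValueError("covariance must be square with 3N rows")
    n = n3 // 3
    blocks = cov.reshape(n, 3, n, 3)
    inner = np.einsum("iaja->ij", blocks)     # trace of each 3x3 block
    var = np.diag(inner).copy()
    defined = var > 0
    if not defined.any():
        raise ValueError("no fluctuations: all atoms static")
    denom = np.sqrt(np.outer(np.where(defined, var, 1.0),
                             np.where(defined, var, 1.0)))
    mat = inner / denom
    mat[~defined, :] = 0.0
    mat[:, ~defined] = 0.0
    np.fill_diagonal(mat, np.where(defined, 1.0, 0.0))
    mat = np.clip(mat, -1.0, 1.0)
    return DCCM(matrix=mat, defined=defined, resids=resids,
                domain_blocks=domain_blocks)


@dataclass
class CartesianPCModel:
    """Eigendecomposition of the 3N covariance with trajectory projections."""

    eigenvectors: np.ndarray          # columns, descending
    eigenvalues: np.ndarray
    projections: np.ndarray           # (F, 3N)
    per_pc_rmsf: np.ndarray           # (n_pc, N) RMSF of single-PC reconstruction
    n_rigid_excluded: int = 6

    @property
    def variance_fractions_total(self) -> np.ndarray:
        tot = self.eigenvalues.sum()
        return self.eigenvalues / tot if tot > 0 else np.zeros_like(self.eigenvalues)

    @property
    def variance_fractions_internal(self) -> np.ndarray:
        """Fractions of internal variance: the ``n_rigid_excluded`` smallest
        eigenvalues (near-zero after superposition) are excluded from the
        denominator."""
        w = self.eigenvalues
        keep = w[: max(len(w) - self.n_rigid_excluded, 1)]
        tot = keep.sum()
        return w / tot if tot > 0 else np.zeros_like(w)

    def cumulative_fraction(self, n: int, internal: bool = True) -> float:
        f = self.variance_fractions_internal if internal else self.variance_fractions_total
        return float(f[:n].sum())


def cartesian_pca(
    cov: np.ndarray,
    traj: Trajectory,
    selection: np.ndarray,
    n_components: int | None = None,
    superpose: bool = True,
    weights: np.ndarray | None = None,
) -> CartesianPCModel:
    """PCA of the C-alpha covariance with per-PC RMSF of the projections.

    The trajectory is centered consistently with the covariance (superposed
    onto the mean structure when ``superpose``); the RMSF of the trajectory
    reconstructed from a single eigenvector v_k is std(p_k) * |v_k,atom|.
    """
    selection = np.asarray(selection)
    sub = traj.coords[:, selection, :]
    if superpose:
        _, sub = average_structure(sub, weights)
    F = sub.shape[0]
    X = sub.reshape(F, -1)
    Xc = X - X.mean(axis=0)
    w, V = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0.0, None)
    V = V[:, order]
    if n_components is None:
        n_components = len(w)
    proj = Xc @ V
    n_atoms = selection.size
    per_pc = np.empty((n_components, n_atoms))
    for k in range(n_components):
        amp = proj[:, k].std(ddof=0)
        shape = np.linalg.norm(V[:, k].reshape(n_atoms, 3), axis=1)
        per_pc[k] = amp * shape
    return CartesianPCModel(eigenvectors=V, eigenvalues=w, projections=proj,
                            per_pc_rmsf=per_pc)
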