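"""Dihedral principal component analysis and conformational families.

Backbone phi/psi extraction, the sin/cos embedding that removes angular
periodicity, PCA, the -RT ln(rho/rho_max) free-energy landscape over the
first two components, k-means family extraction with SSE / silhouette
diagnostics, representative-frame export, and the Schlitter quasi-harmonic
configurational entropy as a function of time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

from .constants import AMU_SI, E_SQUARED, HBAR_SI, KB_SI, NM_SI, R_GAS, T_DEFAULT
from .geometry import average_structure
from .model_io import MolecularSystem, Trajectory


# ---------------------------------------------------------------------------
# Dihedrals
# ---------------------------------------------------------------------------

def dihedral_angle(p0, p1, p2, p3) -> np.ndarray:
    """Signed torsion angle(s) of four points, vectorised over leading axes.

    Inputs broadcast with shape (..., 3); the result is in (-pi, pi].
    """
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - (b0 * b1n).sum(-1, keepdims=True) * b1n
    w = b2 - (b2 * b1n).sum(-1, keepdims=True) * b1n
    x = (v * w).sum(-1)
    y = (np.cross(b1n, v) * w).sum(-1)
    return np.arctan2(y, x)


@dataclass
class DihedralSeries:
    """Per-frame phi/psi (radians in (-pi, pi]) with residue bookkeeping.

    ``angles`` has shape (n_frames, n_angles); ``labels`` carries the
    (residue id, 'phi'|'psi') for every column.  Terminal residues lacking a
    preceding C or following N contribute no angle.
    """

    angles: np.ndarray
    labels: list = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return self.angles.shape[0]


def extract_dihedrals(
    traj: Trajectory,
    system: MolecularSystem,
    residue_range: tuple[int, int] | None = None,
) -> DihedralSeries:
    """Backbone phi/psi time series for residues in ``residue_range``.

    phi(i) = C(i-1)-N(i)-CA(i)-C(i); psi(i) = N(i)-CA(i)-C(i)-N(i+1).
    Residues flanking a chain break (non-consecutive residue ids or a missing
    backbone atom) are skipped.
    """
    backbone: dict[tuple[str, int], dict[str, int]] = {}
    for i in range(system.n_atoms):
        if system.names[i] in ("N", "CA", "C"):
            key = (str(system.chains[i]), int(system.resids[i]))
            backbone.setdefault(key, {})[str(system.names[i])] = i

    cols = []
    labels = []
    for (chain, resid), atoms in sorted(backbone.items()):
        if residue_range is not None and not (residue_range[0] <= resid <= residue_range[1]):
            continue
        if not all(k in atoms for k in ("N", "CA", "C")):
            continue
        prev = backbone.get((chain, resid - 1))
        nxt = backbone.get((chain, resid + 1))
        if prev is not None and "C" in prev:
            cols.append((prev["C"], atoms["N"], atoms["CA"], atoms["C"]))
            labels.append((resid, "phi"))
        if nxt is not None and "N" in nxt:
            cols.append((atoms["N"], atoms["CA"], atoms["C"], nxt["N"]))
            labels.append((resid, "psi"))

    if not cols:
        return DihedralSeries(np.empty((traj.n_frames, 0)), [])
    quad = np.asarray(cols)  # (M, 4)
    c = traj.coords
    ang = dihedral_angle(c[:, quad[:, 0]], c[:, quad[:, 1]],
                         c[:, quad[:, 2]], c[:, quad[:, 3]])
    return DihedralSeries(ang, labels)


# ---------------------------------------------------------------------------
# dPCA
# ---------------------------------------------------------------------------

@dataclass
class PCModel:
    """PCA of the (cos, sin) dihedral embedding (or any vector series)."""

    mean: np.ndarray
    eigenvectors: np.ndarray  # columns, descending eigenvalue order
    eigenvalues: np.ndarray
    projections: np.ndarray   # (n_frames, n_components)

    @property
    def variance_fractions(self) -> np.ndarray:
        tot = self.eigenvalues.sum()
        if tot <= 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / tot

    @property
    def total_variance(self) -> float:
        return float(self.eigenvalues.sum())


def _pca(X: np.ndarray) -> PCModel:
    mean = X.mean(axis=0)
    Xc = X - mean
    n = X.shape[0]
    cov = (Xc.T @ Xc) / max(n - 1, 1)
    w, V = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0.0, None)
    V = V[:, order]
    return PCModel(mean=mean, eigenvectors=V, eigenvalues=w, projections=Xc @ V)


def dpca(dihedrals: DihedralSeries) -> PCModel:
    """PCA of the per-frame vector (cos th, sin th) over every dihedral th."""
    if dihedrals.n_frames < 2:
        raise ValueError("dPCA needs at least 2 frames")
    ang = dihedrals.angles
    X = np.concatenate([np.cos(ang), np.sin(ang)], axis=1)
    return _pca(X)


# ---------------------------------------------------------------------------
# Free-energy landscape
# ---------------------------------------------------------------------------

@dataclass
class FreeEnergyLandscape:
    """Binned -RT ln(rho/rho_max) surface over two PC coordinates."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray
    prob: np.ndarray
    delta_g: np.ndarray          # kJ/mol; empty bins = +inf
    temperature: float
    max_bin: tuple[int, int]

    def bin_of(self, x: float, y: float) -> tuple[int, int]:
        ix = min(max(np.searchsorted(self.x_edges, x, side="right") - 1, 0),
                 self.counts.shape[0] - 1)
        iy = min(max(np.searchsorted(self.y_edges, y, side="right") - 1, 0),
                 self.counts.shape[1] - 1)
        return ix, iy

    def delta_g_at(self, x: float, y: float) -> float:
        ix, iy = self.bin_of(x, y)
        return float(self.delta_g[ix, iy])


def free_energy_landscape(
    pc: PCModel,
    components: tuple[int, int] = (0, 1),
    grid: int = 100,
    temperature: float = T_DEFAULT,
    padding: float = 0.01,
) -> FreeEnergyLandscape:
    """Eq-style landscape dG = -RT ln(rho_xy / rho_max) on an n x n grid.

    The grid covers the projection range padded by ``padding`` on each side;
    empty bins carry dG = +inf (the landscape is undefined at rho = 0).
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    xy = pc.projections[:, list(components)]
    if xy.shape[0] == 0:
        raise ValueError("empty projections")
    lo = xy.min(axis=0)
    hi = xy.max(axis=0)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    lo = lo - padding * span
    hi = hi + padding * span
    counts, x_edges, y_edges = np.histogram2d(
        xy[:, 0], xy[:, 1], bins=grid, range=[[lo[0], hi[0]], [lo[1], hi[1]]]
    )
    prob = counts / counts.sum()
    pmax = prob.max()
    with np.errstate(divide="ignore"):
        dg = -R_GAS * temperature * np.log(prob / pmax)
    dg[prob == 0] = np.inf
    max_bin = np.unravel_index(np.argmax(prob), prob.shape)
    return FreeEnergyLandscape(x_edges, y_edges, counts, prob, dg,
                               temperature, (int(max_bin[0]), int(max_bin[1])))


# ---------------------------------------------------------------------------
# k-means families
# ---------------------------------------------------------------------------

@dataclass
class ClusterModel:
    """k-means families in PC space with SSE and silhouette diagnostics."""

    k: int
    assignments: np.ndarray       # values in 0..k-1
    centroids: np.ndarray
    sse: float
    silhouette_values: np.ndarray | None
    silhouette_sample: np.ndarray | None   # indices the silhouettes refer to
    s_avg: float
    sc: float | None = None       # max over a k-scan of s_avg, if scanned


def kmeans_cluster(
    points: np.ndarray,
    k: int,
    n_init: int = 50,
    seed: int = 0,
    max_silhouette: int = 5000,
) -> ClusterModel:
    """Best-of-``n_init`` k-means (k-means++ starts) with silhouettes.

    Silhouettes are computed on a seeded subsample above ``max_silhouette``
    points (the exact computation is quadratic in n).
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    n = points.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError("k exceeds number of points")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(points)
    labels = km.labels_
    sse = float(km.inertia_)
    if k == 1 or n <= k:
        sil_vals, sil_idx, s_avg = None, None, 0.0
    else:
        if n > max_silhouette:
            rng = np.random.default_rng(seed)
            sil_idx = np.sort(rng.choice(n, size=max_silhouette, replace=False))
        else:
            sil_idx = np.arange(n)
        sub_labels = labels[sil_idx]
        if len(np.unique(sub_labels)) < 2:
            sil_vals, s_avg = None, 0.0
        else:
            sil_vals = silhouette_samples(points[sil_idx], sub_labels)
            s_avg = float(sil_vals.mean())
    return ClusterModel(k=k, assignments=labels, centroids=km.cluster_centers_,
                        sse=sse, silhouette_values=sil_vals,
                        silhouette_sample=sil_idx, s_avg=s_avg)


def kmeans_scan(points, ks, n_init: int = 50, seed: int = 0) -> dict[int, ClusterModel]:
    """Fit a range of k; the silhouette coefficient SC (max of S_AVG over the
    scan) is recorded on every returned model."""
    models = {k: kmeans_cluster(points, k, n_init=n_init, seed=seed) for k in ks}
    sc = max(m.s_avg for m in models.values())
    for m in models.values():
        m.sc = sc
    return models


def extract_centroids(
    cluster: ClusterModel,
    fel: FreeEnergyLandscape,
    pc: PCModel,
    components: tuple[int, int] = (0, 1),
) -> dict[int, int]:
    """For each cluster, the member frame sitting in its lowest-dG occupied bin.

    Ties inside the winning bin go to the frame nearest the cluster centroid.
    Returns ``{cluster_label: frame_index}`` for non-empty clusters.
    """
    xy = pc.projections[:, list(components)]
    frame_dg = np.array([fel.delta_g_at(x, y) for x, y in xy])
    reps: dict[int, int] = {}
    for c in range(cluster.k):
        members = np.flatnonzero(cluster.assignments == c)
        if members.size == 0:
            continue
        dg = frame_dg[members]
        best = dg.min()
        cand = members[dg == best]
        if cand.size > 1:
            d = np.linalg.norm(xy[cand] - cluster.centroids[c][list(range(len(components)))],
                               axis=1)
            cand = cand[[int(np.argmin(d))]]
        reps[c] = int(cand[0])
    return reps


def write_centroids(
    reps: dict[int, int],
    traj: Trajectory,
    system: MolecularSystem,
    outdir,
) -> list:
    """Write one PDB per cluster representative; returns the paths."""
    from pathlib import Path

    from .model_io import write_pdb_frame

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for c, frame in sorted(reps.items()):
        path = outdir / f"centroid_cluster{c:02d}_frame{frame:06d}.pdb"
        write_pdb_frame(traj, system, frame, path)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# Schlitter configurational entropy
# ---------------------------------------------------------------------------

def schlitter_entropy(
    coords: np.ndarray,
    masses: np.ndarray,
    temperature: float = T_DEFAULT,
) -> float:
    """Schlitter upper-bound entropy (kJ mol^-1 K^-1) of fitted coordinates.

    S <= (R/2) ln det[ 1 + (kB T e^2 / hbar^2) M^(1/2) C M^(1/2) ], with C the
    covariance of the (already superposed) Cartesian coordinates.  The
    +identity structure keeps the determinant finite for singular C, so a
    static ensemble cleanly gives S = 0.
    """
    coords = np.asarray(coords, dtype=float)
    F, N, _ = coords.shape
    if F < 2:
        raise ValueError("need at least 2 frames")
    X = coords.reshape(F, 3 * N)
    Xc = X - X.mean(axis=0)
    C = (Xc.T @ Xc) / (F - 1)               # nm^2
    m = np.repeat(np.asarray(masses, dtype=float), 3)
    sqrt_m = np.sqrt(m)
    alpha = KB_SI * temperature * E_SQUARED * AMU_SI * NM_SI ** 2 / HBAR_SI ** 2
    A = np.eye(3 * N) + alpha * (sqrt_m[:, None] * C * sqrt_m[None, :])
    sign, logdet = np.linalg.slogdet(A)
    if sign <= 0:  # pragma: no cover - A is positive definite by construction
        raise RuntimeError("non-positive determinant in Schlitter formula")
    return 0.5 * R_GAS * logdet


def configurational_entropy_series(
    traj: Trajectory,
    selection: np.ndarray,
    masses: np.ndarray,
    window_ends: np.ndarray,
    temperature: float = T_DEFAULT,
    superpose: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Schlitter entropy of the growing window [t0, t] for each window end.

    A plateau in S(t) signals equilibration.  Returns ``(ends, entropies)``
    using only window ends with >= 2 frames.
    """
    selection = np.asarray(selection)
    sub = traj.coords[:, selection, :]
    if superpose:
        _, sub = average_structure(sub, np.asarray(masses, dtype=float))
    ends, vals = [], []
    for t_end in np.asarray(window_ends, dtype=float):
        mask = traj.times <= t_end
        if mask.sum() < 2:
            continue
        ends.append(t_end)
        vals.append(schlitter_entropy(sub[mask], masses, temperature))
    return np.asarray(ends), np.asarray(vals)


def detect_equilibration(
    ends: np.ndarray,
    entropies: np.ndarray,
    rel_tol: float = 0.01,
    n_stable: int = 3,
) -> float | None:
    """First window end after which S changes < ``rel_tol`` (relative) over
    ``n_stable`` consecutive windows; None when no plateau is found."""
    for i in range(len(entropies) - n_stable):
        seg = entropies[i:i + n_stable + 1]
        ref = abs(seg[0]) if seg[0] != 0 else 1.0
        if np.all(np.abs(np.diff(seg)) / ref < rel_tol):
            return float(ends[i])
    return None
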