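"""Dihedral extraction, dPCA, free-energy landscape, clustering, entropy."""

import math

import numpy as np
import pytest

from iondyn.constants import (AMU_SI, E_SQUARED, HBAR_SI, KB_SI, NM_SI, R_GAS)
from iondyn.conformation import (DihedralSeries, detect_equilibration,
                                 dihedral_angle, dpca, extract_centroids,
                                 extract_dihedrals, free_energy_landscape,
                                 kmeans_cluster, kmeans_scan,
                                 schlitter_entropy)
from iondyn.model_io import Trajectory
from iondyn.synthetic import SyntheticSpec, build_backbone, gen_dihedral_states


class TestDihedralAngle:
    @pytest.mark.parametrize("torsion_deg", [0.0, 90.0, -90.0, 180.0, 37.5])
    def test_four_point_matches_mdtraj_oracle(self, torsion_deg):
        """Torsion of four points agrees with mdtraj's independent computation."""
        import mdtraj as md
        from mdtraj.core import element as melem

        phi = math.radians(torsion_deg)
        pts = np.array([
            [1.0, 1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 0.0],
            [-1.0, math.cos(phi), math.sin(phi)],
        ])
        got = float(dihedral_angle(*pts))
        top = md.Topology()
        res = top.add_residue("LIG", top.add_chain())
        for i in range(4):
            top.add_atom(f"C{i}", melem.carbon, res)
        t = md.Trajectory(xyz=pts[None].astype(np.float32), topology=top)
        oracle = float(md.compute_dihedrals(t, [[0, 1, 2, 3]])[0, 0])
        delta = math.degrees(abs(math.atan2(math.sin(got - oracle),
                                            math.cos(got - oracle))))
        assert delta < 1e-4


class TestExtractDihedrals:
    def test_planted_backbone_dihedrals_recovered(self):
        """Build a chain from known phi/psi and read them back."""
        n_res, F = 6, 4
        rng = np.random.default_rng(0)
        phi = rng.uniform(-math.pi, math.pi, size=(F, n_res))
        psi = rng.uniform(-math.pi, math.pi, size=(F, n_res))
        coords = build_backbone(phi, psi)
        spec = SyntheticSpec("dihedral_states", F, params={"n_res": n_res,
                             "populations": [1.0], "jitter_deg": 0.0})
        system, _, _ = gen_dihedral_states(spec)
        traj = Trajectory(coords, np.arange(F, dtype=float))
        series = extract_dihedrals(traj, system)
        # first residue has no phi, last no psi
        labels = set(series.labels)
        assert (1, "phi") not in labels and (n_res, "psi") not in labels
        for col, (resid, kind) in enumerate(series.labels):
            planted = phi[:, resid - 1] if kind == "phi" else psi[:, resid - 1]
            delta = np.angle(np.exp(1j * (series.angles[:, col] - planted)))
            assert np.abs(delta).max() < 1e-8

    def test_alpha_helix_angles(self):
        phi = np.full((1, 5), math.radians(-57.0))
        psi = np.full((1, 5), math.radians(-47.0))
        coords = build_backbone(phi, psi)
        spec = SyntheticSpec("dihedral_states", 1, params={"n_res": 5,
                             "populations": [1.0]})
        system, _, _ = gen_dihedral_states(spec)
        series = extract_dihedrals(Trajectory(coords, np.array([0.0])), system)
        for col, (resid, kind) in enumerate(series.labels):
            expected = -57.0 if kind == "phi" else -47.0
            assert math.degrees(series.angles[0, col]) == pytest.approx(expected,
                                                                        abs=1e-6)


class TestDpca:
    def test_constant_input_zero_variance(self):
        series = DihedralSeries(np.full((10, 4), 1.0), [])
        model = dpca(series)
        assert model.total_variance == pytest.approx(0.0, abs=1e-12)

    def test_two_valued_dihedral_single_mode(self):
        ang = np.full((40, 3), 0.5)
        ang[::2, 0] = 2.0   # one dihedral alternates between two values
        model = dpca(DihedralSeries(ang, []))
        assert model.eigenvalues[0] > 1e-6
        assert model.eigenvalues[1:] == pytest.approx(0.0, abs=1e-12)
        assert len(np.unique(np.round(model.projections[:, 0], 9))) == 2

    def test_invariant_to_2pi_shifts(self):
        rng = np.random.default_rng(1)
        ang = rng.uniform(-math.pi, math.pi, size=(50, 6))
        shifted = ang + 2 * math.pi * rng.integers(-2, 3, size=ang.shape)
        m1, m2 = dpca(DihedralSeries(ang, [])), dpca(DihedralSeries(shifted, []))
        assert m1.eigenvalues == pytest.approx(m2.eigenvalues, abs=1e-10)

    def test_eigen_sum_equals_embedded_variance(self):
        rng = np.random.default_rng(2)
        ang = rng.uniform(-math.pi, math.pi, size=(200, 5))
        model = dpca(DihedralSeries(ang, []))
        X = np.concatenate([np.cos(ang), np.sin(ang)], axis=1)
        total = X.var(axis=0, ddof=1).sum()
        assert model.total_variance == pytest.approx(total, rel=1e-8)
        assert model.variance_fractions.sum() == pytest.approx(1.0, rel=1e-8)

    def test_eigenvectors_orthonormal(self):
        rng = np.random.default_rng(3)
        ang = rng.uniform(-math.pi, math.pi, size=(60, 4))
        V = dpca(DihedralSeries(ang, [])).eigenvectors
        assert np.allclose(V.T @ V, np.eye(V.shape[1]), atol=1e-8)

    def test_two_state_scenario_separates_on_dpc1(self):
        spec = SyntheticSpec("dihedral_states", 4000, seed=4,
                             params={"populations": [0.9, 0.1]})
        system, traj, labels = gen_dihedral_states(spec)
        model = dpca(extract_dihedrals(traj, system))
        side = model.projections[:, 0] > 0
        purity = max((side == labels).mean(), (side != labels).mean())
        assert purity >= 0.99


class TestFreeEnergyLandscape:
    def test_max_density_bin_has_zero_dg(self):
        rng = np.random.default_rng(5)
        proj = rng.normal(size=(500, 2))
        model = dpca(DihedralSeries(rng.uniform(-1, 1, (500, 2)), []))
        model.projections = proj
        fel = free_energy_landscape(model, grid=20, temperature=310.0)
        assert fel.delta_g[fel.max_bin] == 0.0
        assert fel.prob.sum() == pytest.approx(1.0)
        assert np.isinf(fel.delta_g[fel.prob == 0]).all()

    def test_two_bin_populations_give_rt_gap(self):
        """Bins with populations p and p/e differ by exactly RT."""
        T = 310.0
        n2 = 1000
        n1 = int(round(n2 * math.e))
        x = np.concatenate([np.zeros(n1), np.ones(n2)])
        model = dpca(DihedralSeries(np.zeros((len(x), 2)), []))
        model.projections = np.column_stack([x, np.zeros_like(x)])
        fel = free_energy_landscape(model, grid=2, temperature=T)
        finite = fel.delta_g[np.isfinite(fel.delta_g)]
        gap = finite.max() - finite.min()
        expected = R_GAS * T * math.log(n1 / n2)
        assert gap == pytest.approx(expected, rel=1e-9)
        assert R_GAS * T == pytest.approx(2.577, abs=0.001)

    def test_normalisation_invariance_under_count_doubling(self):
        rng = np.random.default_rng(6)
        proj = rng.normal(size=(400, 2))
        model = dpca(DihedralSeries(rng.uniform(-1, 1, (400, 2)), []))
        model.projections = proj
        fel1 = free_energy_landscape(model, grid=15)
        model.projections = np.vstack([proj, proj])
        fel2 = free_energy_landscape(model, grid=15)
        m = np.isfinite(fel1.delta_g)
        assert np.allclose(fel1.delta_g[m], fel2.delta_g[m], atol=1e-10)


class TestKmeans:
    def test_k1_centroid_is_mean(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(100, 2))
        cm = kmeans_cluster(pts, 1, seed=0)
        assert cm.centroids[0] == pytest.approx(pts.mean(0), abs=1e-8)
        assert cm.sse == pytest.approx(((pts - pts.mean(0)) ** 2).sum(), rel=1e-8)

    def test_three_planted_gaussians_recovered(self):
        rng = np.random.default_rng(8)
        centers = np.array([[0, 0], [10, 0], [0, 10]], float)
        labels = rng.integers(0, 3, 600)
        pts = centers[labels] + rng.normal(0, 0.5, size=(600, 2))
        cm = kmeans_cluster(pts, 3, seed=1)
        # purity via best label permutation
        import itertools as it
        best = max(
            (np.mean([perm[l] for l in labels] == cm.assignments))
            for perm in it.permutations(range(3))
        )
        assert best >= 0.99
        assert cm.s_avg >= 0.8

    def test_sse_non_increasing_in_k(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(300, 2))
        models = kmeans_scan(pts, range(1, 9), n_init=10, seed=2)
        sses = [models[k].sse for k in range(1, 9)]
        assert all(a >= b - 1e-9 for a, b in zip(sses, sses[1:]))
        assert models[3].sc == max(models[k].s_avg for k in range(1, 9))

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            kmeans_cluster(np.zeros((5, 2)), 0)
        with pytest.raises(ValueError):
            kmeans_cluster(np.zeros((5, 2)), 6)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(10)
        pts = rng.normal(size=(200, 2))
        a = kmeans_cluster(pts, 4, seed=3)
        b = kmeans_cluster(pts, 4, seed=3)
        assert np.array_equal(a.assignments, b.assignments)
        assert a.sse == b.sse


class TestCentroids:
    def test_two_state_representatives_hit_planted_basins(self):
        spec = SyntheticSpec("dihedral_states", 3000, seed=11,
                             params={"populations": [0.7, 0.3]})
        system, traj, labels = gen_dihedral_states(spec)
        model = dpca(extract_dihedrals(traj, system))
        fel = free_energy_landscape(model, grid=40)
        cm = kmeans_cluster(model.projections[:, :2], 2, seed=0)
        reps = extract_centroids(cm, fel, model)
        assert len(reps) == 2
        rep_labels = {labels[f] for f in reps.values()}
        assert rep_labels == {0, 1}
        xy = model.projections[:, :2]
        frame_dg = np.array([fel.delta_g_at(x, y) for x, y in xy])
        for c, f in reps.items():
            # representative sits in the lowest-dG occupied bin of its cluster
            members = np.flatnonzero(cm.assignments == c)
            assert frame_dg[f] == pytest.approx(frame_dg[members].min())

    def test_cluster_count_matches_requested(self, tmp_path):
        from iondyn.conformation import write_centroids

        spec = SyntheticSpec("dihedral_states", 400, seed=12,
                             params={"populations": [0.5, 0.5]})
        system, traj, _ = gen_dihedral_states(spec)
        model = dpca(extract_dihedrals(traj, system))
        fel = free_energy_landscape(model, grid=30)
        cm = kmeans_cluster(model.projections[:, :2], 10, seed=1)
        reps = extract_centroids(cm, fel, model)
        paths = write_centroids(reps, traj, system, tmp_path)
        assert len(paths) == len(reps) > 0
        assert all(p.exists() for p in paths)


class TestSchlitterEntropy:
    def test_static_trajectory_zero(self):
        coords = np.zeros((10, 3, 3))
        assert schlitter_entropy(coords, np.ones(3)) == pytest.approx(0.0,
                                                                      abs=1e-12)

    def test_1d_harmonic_closed_form(self):
        rng = np.random.default_rng(13)
        sigma, mass, T = 0.05, 12.0, 310.0
        coords = np.zeros((20000, 1, 3))
        coords[:, 0, 0] = rng.normal(0, sigma, 20000)
        S = schlitter_entropy(coords, np.array([mass]), T)
        var = coords[:, 0, 0].var(ddof=1)
        alpha = KB_SI * T * E_SQUARED * AMU_SI * NM_SI ** 2 / HBAR_SI ** 2
        closed = 0.5 * R_GAS * math.log(1 + alpha * mass * var)
        assert S == pytest.approx(closed, rel=1e-10)

    def test_plateau_detects_planted_equilibration(self):
        """Entropy rises while the ensemble widens, then plateaus."""
        rng = np.random.default_rng(14)
        F = 2000
        widths = np.where(np.arange(F) < 600,
                          0.01 + 0.09 * np.arange(F) / 600, 0.1)
        coords = np.zeros((F, 4, 3))
        coords[:, :, 0] = rng.normal(size=(F, 4)) * widths[:, None]
        traj = Trajectory(coords, np.arange(F, dtype=float) * 0.1)
        from iondyn.conformation import configurational_entropy_series
        ends, S = configurational_entropy_series(
            traj, np.arange(4), np.full(4, 12.0),
            np.linspace(20, 200, 10), superpose=False)
        assert np.all(np.diff(S) > -1e-6)
        eq = detect_equilibration(ends, S, rel_tol=0.01)
        assert eq is not None
        assert 40 <= eq <= 140   # planted onset at frame 600 -> 60 ns
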