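"""Interaction energies, interaction entropy, bootstrap, Tukey fences,
coordination geometry and the binding report."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iondyn.constants import F_COULOMB, ION_LJ, R_GAS
from iondyn.energetics import (assign_geometry, binding_report, born_energy,
                               bootstrap_se, interaction_energy,
                               interaction_entropy, ion_site_distances,
                               significant_residues, solvation_terms,
                               tukey_fences)
from iondyn.model_io import Trajectory, select
from iondyn.synthetic import SyntheticSpec, gen_ion_pocket
from tests.conftest import make_system


def ion_site_pair(r, q_site=-1.0, sigma_site=0.0, eps_site=0.0, ion="ZN"):
    s_i, e_i = ION_LJ[ion]
    system = make_system(
        names=[ion, "O1"], elements=[ion, "O"], resids=[1, 2],
        resnames=[ion, "GLU"], domains=["ion", "Cat"],
        charges=[2.0, q_site], sigmas=[s_i, sigma_site],
        epsilons=[e_i, eps_site])
    coords = np.zeros((3, 2, 3))
    coords[:, 1, 0] = r
    traj = Trajectory(coords, np.arange(3, dtype=float))
    return system, traj


class TestInteractionEnergy:
    def test_coulomb_closed_form(self):
        system, traj = ion_site_pair(0.2)
        series = interaction_energy(traj, system, np.array([0]), np.array([1]))
        assert series.total == pytest.approx(np.full(3, -1389.35458))
        assert series.vdw == pytest.approx(np.zeros(3))

    def test_lj_zero_at_sigma(self):
        s_i, _ = ION_LJ["ZN"]
        sigma_site = 0.3
        sij = (s_i + sigma_site) / 2
        system, traj = ion_site_pair(sij, q_site=0.0, sigma_site=sigma_site,
                                     eps_site=0.5)
        series = interaction_energy(traj, system, np.array([0]), np.array([1]))
        assert series.total == pytest.approx(np.zeros(3), abs=1e-10)

    def test_matches_generator_oracle(self):
        spec = SyntheticSpec("ion_pocket", 1000, seed=1)
        system, traj, oracle = gen_ion_pocket(spec)
        series = interaction_energy(traj, system, select(system, "domain ion"),
                                    select(system, "domain Cat"))
        rel = np.abs(series.total - oracle) / np.abs(oracle)
        assert rel.max() <= 1e-10

    def test_decomposition_sums_to_total(self):
        spec = SyntheticSpec("ion_pocket", 50, seed=2)
        system, traj, _ = gen_ion_pocket(spec)
        series = interaction_energy(traj, system, select(system, "domain ion"),
                                    select(system, "domain Cat"))
        assert np.abs(series.per_residue.sum(1) - series.total).max() < 1e-6

    def test_overlap_rejected(self):
        system, traj = ion_site_pair(1e-5)
        with pytest.raises(ValueError, match="overlap"):
            interaction_energy(traj, system, np.array([0]), np.array([1]))

    def test_translation_rotation_invariance(self):
        from scipy.spatial.transform import Rotation

        spec = SyntheticSpec("ion_pocket", 20, seed=3)
        system, traj, _ = gen_ion_pocket(spec)
        ions, prot = select(system, "domain ion"), select(system, "domain Cat")
        e1 = interaction_energy(traj, system, ions, prot).total
        R = Rotation.from_euler("xyz", [11, 22, 33], degrees=True).as_matrix()
        moved = Trajectory(traj.coords @ R.T + 4.2, traj.times)
        e2 = interaction_energy(moved, system, ions, prot).total
        assert np.allclose(e1, e2, rtol=1e-12)

    def test_combination_rule_symmetry(self):
        """Swapping which atom carries which parameters leaves E unchanged."""
        system, traj = ion_site_pair(0.35, q_site=-0.5, sigma_site=0.31,
                                     eps_site=0.8)
        e1 = interaction_energy(traj, system, np.array([0]), np.array([1])).total
        swapped = make_system(
            names=["ZN", "O1"], elements=["ZN", "O"], resids=[1, 2],
            resnames=["ZN", "GLU"], domains=["ion", "Cat"],
            charges=[-0.5, 2.0], sigmas=[0.31, ION_LJ["ZN"][0]],
            epsilons=[0.8, ION_LJ["ZN"][1]])
        e2 = interaction_energy(traj, swapped, np.array([0]), np.array([1])).total
        assert np.allclose(e1, e2, rtol=1e-12)


class TestSolvationTerms:
    def test_buried_ion_nonpolar_is_b(self):
        """A fully caged ion has SASA 0, so the nonpolar term reduces to b."""
        offsets = [np.array([i, j, k]) * 0.25
                   for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
        coords = np.array(offsets)
        n = len(offsets)
        center = [idx for idx, o in enumerate(offsets) if np.all(o == 0)][0]
        system = make_system(
            names=["ZN" if i == center else f"C{i}" for i in range(n)],
            elements=["ZN" if i == center else "C" for i in range(n)],
            resids=list(range(1, n + 1)), resnames=["ZN" if i == center else "LIG"
                                                    for i in range(n)],
            domains=["ion" if i == center else "Cat" for i in range(n)],
            charges=[2.0 if i == center else 0.0 for i in range(n)])
        traj = Trajectory(coords[None], np.array([0.0]))
        dg_pol, dg_np = solvation_terms(traj, system, np.array([center]),
                                        gamma=2.27, b_const=3.85)
        assert dg_np[0] == pytest.approx(3.85, abs=1e-6)
        # fully buried -> full Born desolvation penalty, positive
        assert dg_pol[0] == pytest.approx(
            abs(born_energy(2.0, 0.11)), rel=1e-6)

    def test_born_energy_sign_and_monotonicity(self):
        e_small = born_energy(2.0, 0.1)
        e_large = born_energy(2.0, 0.2)
        assert e_small < e_large < 0.0

    def test_burying_raises_polar_term(self):
        """Removing solvent exposure raises dG_polar (desolvation penalty)."""
        system = make_system(names=["ZN"], elements=["ZN"], resids=[1],
                             resnames=["ZN"], domains=["ion"], charges=[2.0])
        free = Trajectory(np.zeros((1, 1, 3)), np.array([0.0]))
        dg_free, _ = solvation_terms(free, system, np.array([0]))
        assert dg_free[0] == pytest.approx(0.0, abs=1e-6)  # fully exposed


class TestInteractionEntropy:
    def test_constant_series_zero(self):
        assert interaction_entropy(np.full(100, -250.0), 310.0) == 0.0

    def test_three_point_hand_computed(self):
        e = np.array([-1.0, 0.0, 1.0])
        T = 310.0
        beta = 1.0 / (R_GAS * T)
        expected = R_GAS * T * math.log(np.mean(np.exp(beta * (e - e.mean()))))
        assert interaction_entropy(e, T) == pytest.approx(expected, abs=1e-12)

    def test_gaussian_lognormal_limit(self):
        """For Gaussian dE with sd RT, -TdS -> RT/2 at large N."""
        T = 310.0
        sigma = R_GAS * T
        rng = np.random.default_rng(4)
        val = interaction_entropy(rng.normal(0, sigma, 100_000), T)
        assert val == pytest.approx(sigma / 2, rel=0.05)

    def test_overflow_guarded(self):
        e = np.array([0.0, 5000.0, -5000.0])
        val = interaction_entropy(e, 310.0)
        assert math.isfinite(val) and val > 0

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-500, 500), min_size=2, max_size=50))
    def test_jensen_nonnegative(self, values):
        assert interaction_entropy(np.array(values), 310.0) >= 0.0


class TestBootstrap:
    def test_constant_series_zero_se(self):
        assert bootstrap_se(np.full(50, 3.3), n_boot=200, seed=0) == 0.0

    def test_clt_scaling(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 2.0, 1000)
        se = bootstrap_se(x, n_boot=2000, seed=1)
        assert se == pytest.approx(2.0 / math.sqrt(1000), rel=0.1)

    def test_converged_in_n_boot(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=400)
        se1 = bootstrap_se(x, n_boot=5000, seed=2)
        se2 = bootstrap_se(x, n_boot=10000, seed=3)
        assert abs(se1 - se2) / se1 < 0.05

    def test_deterministic_given_seed(self):
        x = np.random.default_rng(7).normal(size=100)
        assert bootstrap_se(x, seed=9, n_boot=500) == \
            bootstrap_se(x, seed=9, n_boot=500)


class TestTukeyFences:
    def test_one_to_eight_linear_interpolation(self):
        # linear-interpolation quartiles of 1..8 are Q1=2.75, Q3=6.25,
        # so the k=1.5 fences are 2.75 - 5.25 = -2.5 and 6.25 + 5.25 = 11.5
        (lo, hi), flags = tukey_fences(np.arange(1.0, 9.0), k=1.5)
        assert (lo, hi) == pytest.approx((-2.5, 11.5))
        assert not flags.any()

    def test_gross_outlier_flagged(self):
        (_, _), flags = tukey_fences(np.array([0.0, 0, 0, 0, -100.0]))
        assert list(flags) == [False, False, False, False, True]

    def test_symmetric_data_symmetric_fences(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=501)
        x = np.concatenate([x, -x])   # exactly symmetric about 0
        (lo, hi), _ = tukey_fences(x, k=3.0)
        assert lo == pytest.approx(-hi, abs=1e-10)

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            tukey_fences(np.array([1.0, 2.0, 3.0]))

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 10_000), st.sampled_from([1.5, 3.0]))
    def test_agrees_with_sorted_quantile_oracle(self, seed, k):
        """Fence bounds and flags match an independent sort-based quantile."""
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 10, size=rng.integers(4, 60))
        (lo, hi), flags = tukey_fences(x, k=k)

        def quantile_sorted(sorted_x, q):
            h = (len(sorted_x) - 1) * q
            lo_i = int(math.floor(h))
            hi_i = min(lo_i + 1, len(sorted_x) - 1)
            return sorted_x[lo_i] + (h - lo_i) * (sorted_x[hi_i] - sorted_x[lo_i])

        s = np.sort(x)
        q1, q3 = quantile_sorted(s, 0.25), quantile_sorted(s, 0.75)
        assert lo == pytest.approx(q1 - k * (q3 - q1), abs=1e-9)
        assert hi == pytest.approx(q3 + k * (q3 - q1), abs=1e-9)
        assert np.array_equal(flags, (x <= lo) | (x >= hi))


class TestAssignGeometry:
    def geometry_system(self, ligand_positions):
        n = len(ligand_positions) + 1
        system = make_system(
            names=["ZN"] + [f"O{i}" for i in range(n - 1)],
            elements=["ZN"] + ["O"] * (n - 1),
            resids=list(range(1, n + 1)),
            resnames=["ZN"] + ["ASP"] * (n - 1),
            domains=["ion"] + ["Cat"] * (n - 1))
        coords = np.vstack([[0.0, 0, 0], np.asarray(ligand_positions)])
        return system, coords

    def test_tetrahedral(self):
        verts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                         float) * 0.2 / math.sqrt(3)
        system, coords = self.geometry_system(verts)
        a = assign_geometry(coords, 0, system)
        assert a.label == "tetrahedral"
        assert a.angle_rmsd == pytest.approx(0.0, abs=1e-6)

    def test_linear(self):
        system, coords = self.geometry_system([[0.2, 0, 0], [-0.2, 0, 0]])
        a = assign_geometry(coords, 0, system)
        assert a.label == "linear"

    def test_octahedral(self):
        verts = 0.21 * np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0],
                                 [0, 0, 1], [0, 0, -1]], float)
        system, coords = self.geometry_system(verts)
        assert assign_geometry(coords, 0, system).label == "octahedral"

    def test_square_planar_beats_seesaw_for_planar_ligands(self):
        verts = 0.22 * np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0]],
                                float)
        system, coords = self.geometry_system(verts)
        assert assign_geometry(coords, 0, system).label == "square planar"

    def test_trigonal_bipyramid_vacancy_arrangement(self):
        """Four ligands at tbp positions minus one axial: a vacancy match."""
        verts = 0.2 * np.array([[0, 0, 1], [1, 0, 0],
                                [-0.5, math.sqrt(3) / 2, 0],
                                [-0.5, -math.sqrt(3) / 2, 0]])
        system, coords = self.geometry_system(verts)
        a = assign_geometry(coords, 0, system)
        assert a.label == "trigonal bipyramidal"
        assert a.vacancy

    def test_not_coordinated_cases(self):
        system, coords = self.geometry_system([[0.2, 0, 0]])
        assert assign_geometry(coords, 0, system).label == "not-coordinated"
        system, coords = self.geometry_system([[0.5, 0, 0], [0, 0.5, 0]])
        assert assign_geometry(coords, 0, system).label == "not-coordinated"

    def test_distance_cutoff_selects_ligands(self):
        system, coords = self.geometry_system(
            [[0.2, 0, 0], [-0.2, 0, 0], [0, 0.6, 0]])
        a = assign_geometry(coords, 0, system, cutoff=0.35)
        assert a.ligand_atoms.size == 2
        assert a.label == "linear"


class TestIonSiteDistances:
    def test_single_frame_exact(self):
        system, traj = ion_site_pair(0.23)
        df = ion_site_distances(traj.slice_frames([0]), 0, np.array([1]))
        assert df["mean_nm"].iloc[0] == pytest.approx(0.23)
        assert df["sd_nm"].iloc[0] == 0.0

    def test_planted_mean_sd_recovered(self):
        rng = np.random.default_rng(9)
        F, mu, sd = 4000, 0.30, 0.02
        coords = np.zeros((F, 2, 3))
        coords[:, 1, 0] = rng.normal(mu, sd, F)
        traj = Trajectory(coords, np.arange(F, dtype=float))
        system, _ = ion_site_pair(0.3)
        df = ion_site_distances(traj, 0, np.array([1]))
        assert df["mean_nm"].iloc[0] == pytest.approx(mu, abs=4 * sd / math.sqrt(F))
        assert df["sd_nm"].iloc[0] == pytest.approx(sd, rel=0.1)


class TestBindingReport:
    def test_identities_and_entropy_sign(self):
        spec = SyntheticSpec("ion_pocket", 300, seed=10,
                             params={"sampling": "metropolis"})
        system, traj, oracle = gen_ion_pocket(spec)
        ions = select(system, "domain ion")
        prot = select(system, "domain Cat")
        rep = binding_report(traj, system, {"Zn_1": ions}, prot,
                             n_boot=300, seed=0)
        row = rep.table.loc["Zn_1"]
        assert row["dE_binding"] == pytest.approx(
            row["dE_vdw"] + row["dE_elec"] + row["dG_polar"] + row["dG_nonpolar"],
            rel=1e-9)
        assert row["dG_binding"] == pytest.approx(
            row["dE_binding"] + row["minus_TdS"], rel=1e-9)
        assert row["minus_TdS"] >= 0.0
        # MM mean agrees with the generator oracle
        assert row["dE_vdw"] + row["dE_elec"] == pytest.approx(oracle.mean(),
                                                               rel=1e-10)

    def test_entropy_grows_with_energy_variance(self):
        narrow = interaction_entropy(
            np.random.default_rng(0).normal(0, 0.5, 5000), 310.0)
        wide = interaction_entropy(
            np.random.default_rng(0).normal(0, 3.0, 5000), 310.0)
        assert wide > narrow


def test_significant_residues_flags_strong_contributor():
    spec = SyntheticSpec("ion_pocket", 100, seed=11)
    system, traj, _ = gen_ion_pocket(spec)
    # add a distant, weakly interacting shell of sites so the pocket sites
    # stand out as outliers
    series = interaction_energy(traj, system, select(system, "domain ion"),
                                select(system, "domain Cat"))
    contrib = series.per_residue.mean(0)
    df = significant_residues(series)
    assert set(df.columns) >= {"resid", "mean_contribution", "significant"}
    assert np.isclose(sorted(df["mean_contribution"]), sorted(contrib)).all()
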