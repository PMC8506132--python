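"""Superposition, RMSD/RMSF/Rg and nonbonded-energy observables."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from halokin import (
    ClashError,
    DegenerateGeometryError,
    InvalidParameterError,
    MissingParameterError,
    NonbondedParams,
    Selection,
    Trajectory,
    interaction_energy,
    kabsch_superpose,
    lj_from_ab,
    radius_of_gyration,
    read_trajectory_pdb,
    read_trajectory_xyz,
    replicate_stats,
    rg_series,
    rmsd_series,
    rmsf,
    write_trajectory_pdb,
)
from halokin.traj_analysis import COULOMB_CONSTANT, fraction_window
from halokin.synthetic_data import gen_random_cluster, gen_trajectory

FOUR_POINTS = np.array(
    [[0.0, 0.0, 0.0], [1.5, 0.2, -0.3], [-0.4, 1.1, 0.8], [0.6, -0.9, 1.3]]
)


def euler_grid_min_rmsd(P, Q, coarse_step=15.0, levels=7):
    """Exhaustive-rotation oracle: centre both sets, scan zyz Euler angles on
    a coarse global grid, then refine around the best cell down to ~1e-3 deg
    resolution.  Written independently of the Kabsch code path."""
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)

    def rmsd_for(angles):
        R = Rotation.from_euler("zyz", angles, degrees=True).as_matrix()
        rotated = np.einsum("kij,nj->kni", R, Pc)
        d = rotated - Qc[None]
        return np.sqrt(np.mean(np.sum(d * d, axis=2), axis=1))

    grids = [
        np.arange(0.0, 360.0, coarse_step),
        np.arange(0.0, 180.0 + coarse_step, coarse_step),
        np.arange(0.0, 360.0, coarse_step),
    ]
    A = np.stack(np.meshgrid(*grids, indexing="ij"), axis=-1).reshape(-1, 3)
    vals = rmsd_for(A)
    # refine every promising coarse cell: the best coarse point can sit in
    # the wrong basin of the multimodal RMSD landscape
    candidates = A[np.argsort(vals)[:30]]
    best_val = math.inf
    for cand in candidates:
        best, step = cand, coarse_step
        for _ in range(levels):
            grids = [np.linspace(b - step, b + step, 9) for b in best]
            G = np.stack(np.meshgrid(*grids, indexing="ij"), axis=-1).reshape(-1, 3)
            v = rmsd_for(G)
            best = G[int(np.argmin(v))]
            step /= 3.0
        best_val = min(best_val, float(rmsd_for(best[None])[0]))
    return best_val


class TestKabsch:
    def test_identity(self):
        res = kabsch_superpose(FOUR_POINTS, FOUR_POINTS)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-10)

    def test_recovers_rigid_motion(self):
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = FOUR_POINTS @ R.T + np.array([5.0, 0.0, 0.0])
        res = kabsch_superpose(moved, FOUR_POINTS)
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(res.rotation, R.T, atol=1e-10)

    def test_proper_rotation_always(self):
        # mirrored target would invite a reflection; determinant must stay +1
        mirrored = FOUR_POINTS * np.array([1.0, 1.0, -1.0])
        res = kabsch_superpose(FOUR_POINTS, mirrored)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0)

    def test_matches_euler_grid_oracle(self):
        rng = np.random.default_rng(11)
        perturbed = FOUR_POINTS + rng.normal(0, 0.1, FOUR_POINTS.shape)
        R = Rotation.from_euler("zyx", [40, -25, 70], degrees=True).as_matrix()
        mobile = perturbed @ R.T + np.array([1.0, -2.0, 0.5])
        kab = kabsch_superpose(mobile, FOUR_POINTS).rmsd
        oracle = euler_grid_min_rmsd(mobile, FOUR_POINTS)
        assert kab <= oracle + 1e-12
        assert abs(kab - oracle) <= 1e-6

    def test_mismatched_counts(self):
        with pytest.raises(InvalidParameterError):
            kabsch_superpose(FOUR_POINTS[:3], FOUR_POINTS)

    def test_collinear_degenerate(self):
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        with pytest.raises(DegenerateGeometryError, match="rank"):
            kabsch_superpose(line, line)


class TestRmsdSeries:
    def test_static_and_rigid_trajectories_are_zero(self):
        ref = gen_random_cluster(20, seed=1)
        static = gen_trajectory(ref, 0.0, 5, rigid_motion=False, seed=0)
        rigid = gen_trajectory(ref, 0.0, 5, rigid_motion=True, seed=0)
        assert np.allclose(rmsd_series(static), 0.0, atol=1e-12)
        assert np.allclose(rmsd_series(rigid), 0.0, atol=1e-9)

    def test_single_displaced_atom_formula(self):
        # displacing one of N atoms by d gives unaligned rmsd sqrt(d^2/N)
        # (hand formula vs direct evaluation on a fixed 3-atom case); the
        # optimal fit can only lower it, and a rigid-irreducible part remains
        base = np.array([[0.0, 0, 0], [4.0, 0, 0], [0.0, 4.0, 0]])
        moved = base.copy()
        d = 0.2
        moved[2, 2] += d
        direct = math.sqrt(np.mean(np.sum((moved - base) ** 2, axis=1)))
        assert direct == pytest.approx(math.sqrt(d**2 / 3))
        res = kabsch_superpose(moved, base)
        assert 0.0 < res.rmsd <= direct + 1e-12

    def test_superposition_never_increases_rmsd(self):
        ref = gen_random_cluster(15, seed=2)
        traj = gen_trajectory(ref, 0.3, 10, rigid_motion=True, seed=3)
        series = rmsd_series(traj)
        raw = np.sqrt(
            np.mean(np.sum((traj.frames - traj.frames[0]) ** 2, axis=2), axis=1)
        )
        assert np.all(series <= raw + 1e-9)

    def test_first_value_zero(self):
        traj = gen_trajectory(gen_random_cluster(10, seed=4), 0.2, 6, seed=5)
        assert rmsd_series(traj)[0] == pytest.approx(0.0, abs=1e-12)


class TestRmsf:
    def test_static_zero(self):
        traj = gen_trajectory(gen_random_cluster(10, seed=0), 0.0, 4, seed=0)
        assert np.allclose(rmsf(traj)["rmsf"], 0.0, atol=1e-12)

    def test_two_point_variance_no_alignment(self):
        base = gen_random_cluster(5, seed=6)
        d = 0.7
        frames = np.stack([base.coords.copy(), base.coords.copy()])
        frames[0, :, 0] -= d
        frames[1, :, 0] += d
        traj = Trajectory(topology=base, frames=frames)
        out = rmsf(traj, align=False)
        assert np.allclose(out["rmsf"], d, atol=1e-12)

    def test_gaussian_fluctuation_expectation(self):
        # isotropic per-coordinate sigma: E[RMSF] = sigma * sqrt(3)
        ref = gen_random_cluster(100, extent=25.0, seed=3)
        traj = gen_trajectory(ref, 0.5, 2000, rigid_motion=False, seed=7)
        mean_rmsf = rmsf(traj)["rmsf"].mean()
        assert mean_rmsf == pytest.approx(0.5 * math.sqrt(3), rel=0.03)

    def test_single_frame_error(self):
        ref = gen_random_cluster(5, seed=0)
        traj = Trajectory(topology=ref, frames=ref.coords[None])
        with pytest.raises(InvalidParameterError):
            rmsf(traj)


class TestRadiusOfGyration:
    def test_single_atom_zero(self):
        assert radius_of_gyration(np.zeros((1, 3))) == 0.0

    def test_two_equal_masses(self):
        assert radius_of_gyration(
            np.array([[0.0, 0, 0], [3.0, 0, 0]])
        ) == pytest.approx(1.5)

    def test_unit_cube_direct_evaluation(self):
        corners = np.array(
            [[x, y, z] for x in (0, 2) for y in (0, 2) for z in (0, 2)], float
        )
        assert radius_of_gyration(corners) == pytest.approx(math.sqrt(3))

    def test_rigid_motion_invariance(self):
        ref = gen_random_cluster(12, seed=8)
        R = Rotation.from_euler("xyz", [10, 20, 30], degrees=True).as_matrix()
        a = radius_of_gyration(ref.coords, ref.mass)
        b = radius_of_gyration(ref.coords @ R.T + 7.0, ref.mass)
        assert b == pytest.approx(a, rel=1e-12)

    def test_series_over_selection(self):
        ref = gen_random_cluster(10, seed=9)
        traj = gen_trajectory(ref, 0.0, 3, seed=0)
        sel = Selection(residue_ranges=((1, 5),))
        vals = rg_series(traj, sel)
        assert vals.shape == (3,)
        assert np.allclose(vals, vals[0])


def toy_params(n, charge=0.0, eps=0.1, sigma=3.0):
    return NonbondedParams(
        charge=np.full(n, charge), epsilon=np.full(n, eps), sigma=np.full(n, sigma)
    )


def brute_force_energy(coords, sel_a, sel_b, params):
    """Independent all-pairs summation (plain Python loops)."""
    elec = vdw = 0.0
    for i in sel_a:
        for j in sel_b:
            r = math.dist(coords[i], coords[j])
            elec += params.coulomb_constant * params.charge[i] * params.charge[j] / r
            sig = 0.5 * (params.sigma[i] + params.sigma[j])
            eps = math.sqrt(params.epsilon[i] * params.epsilon[j])
            vdw += 4 * eps * ((sig / r) ** 12 - (sig / r) ** 6)
    return elec, vdw


class TestInteractionEnergy:
    def test_unit_charges_coulomb_closed_form(self):
        coords = np.array([[0.0, 0, 0], [3.320636, 0, 0]])
        params = toy_params(2, charge=1.0)
        elec, _ = interaction_energy(coords, [0], [1], params)
        assert elec == pytest.approx(100.00, abs=1e-6)

    def test_lj_minimum_is_minus_eps(self):
        eps, sigma = 0.25, 3.0
        coords = np.array([[0.0, 0, 0], [2 ** (1 / 6) * sigma, 0, 0]])
        params = toy_params(2, eps=eps, sigma=sigma)
        _, vdw = interaction_energy(coords, [0], [1], params)
        assert vdw == pytest.approx(-eps, rel=1e-12)

    def test_brute_force_pair_sum_oracle(self):
        rng = np.random.default_rng(5)
        coords = rng.uniform(-4, 4, size=(5, 3))
        params = NonbondedParams(
            charge=rng.normal(0, 0.5, 5),
            epsilon=rng.uniform(0.05, 0.3, 5),
            sigma=rng.uniform(2.5, 3.5, 5),
        )
        sel_a, sel_b = [0, 1, 2], [3, 4]
        ours = interaction_energy(coords, sel_a, sel_b, params)
        ref = brute_force_energy(coords, sel_a, sel_b, params)
        assert ours[0] == pytest.approx(ref[0], abs=1e-10)
        assert ours[1] == pytest.approx(ref[1], abs=1e-10)

    def test_symmetry_and_charge_linearity(self):
        rng = np.random.default_rng(6)
        coords = rng.uniform(-4, 4, size=(6, 3))
        params = NonbondedParams(
            charge=rng.normal(0, 0.5, 6),
            epsilon=rng.uniform(0.05, 0.3, 6),
            sigma=rng.uniform(2.5, 3.5, 6),
        )
        ab = interaction_energy(coords, [0, 1, 2], [3, 4, 5], params)
        ba = interaction_energy(coords, [3, 4, 5], [0, 1, 2], params)
        assert ab == pytest.approx(ba)
        scaled = NonbondedParams(
            charge=params.charge * np.where(np.arange(6) == 0, 2.0, 1.0),
            epsilon=params.epsilon,
            sigma=params.sigma,
        )
        ab2 = interaction_energy(coords, [0], [3, 4, 5], scaled)
        ab1 = interaction_energy(coords, [0], [3, 4, 5], params)
        assert ab2[0] == pytest.approx(2 * ab1[0])
        assert ab2[1] == pytest.approx(ab1[1])  # vdw blind to charges

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(7)
        coords = rng.uniform(-4, 4, size=(5, 3))
        params = toy_params(5, charge=0.3)
        R = Rotation.from_euler("zyx", [15, 25, 35], degrees=True).as_matrix()
        a = interaction_energy(coords, [0, 1], [2, 3, 4], params)
        b = interaction_energy(coords @ R.T + 9.0, [0, 1], [2, 3, 4], params)
        assert a[0] == pytest.approx(b[0], rel=1e-12)
        assert a[1] == pytest.approx(b[1], rel=1e-12)

    def test_electrostatic_sign_convention(self):
        # phosphate-like negative probe vs acidic (negative) loop: repulsion;
        # vs basic (positive) loop: attraction
        probe = np.array([[0.0, 0.0, 0.0]])
        loop = np.array([[5.0, 0, 0], [5.5, 1.0, 0], [5.5, -1.0, 0]])
        coords = np.vstack([probe, loop])
        acidic = NonbondedParams(
            charge=np.array([-1.0, -0.5, -0.5, -0.5]),
            epsilon=np.full(4, 0.1), sigma=np.full(4, 3.0),
        )
        basic = NonbondedParams(
            charge=np.array([-1.0, 0.5, 0.5, 0.5]),
            epsilon=np.full(4, 0.1), sigma=np.full(4, 3.0),
        )
        e_acid, _ = interaction_energy(coords, [0], [1, 2, 3], acidic)
        e_base, _ = interaction_energy(coords, [0], [1, 2, 3], basic)
        assert e_acid > 0
        assert e_base < 0
        assert e_acid == pytest.approx(-e_base)

    def test_overlapping_selection_error(self):
        coords = np.zeros((3, 3)) + np.arange(3)[:, None]
        with pytest.raises(InvalidParameterError, match="disjoint"):
            interaction_energy(coords, [0, 1], [1, 2], toy_params(3))

    def test_missing_parameters_error(self):
        coords = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        params = NonbondedParams(
            charge=np.array([0.0, np.nan]),
            epsilon=np.array([0.1, np.nan]),
            sigma=np.array([3.0, np.nan]),
        )
        with pytest.raises(MissingParameterError):
            interaction_energy(coords, [0], [1], params)

    def test_clash_error(self):
        coords = np.array([[0.0, 0, 0], [0.05, 0, 0]])
        with pytest.raises(ClashError):
            interaction_energy(coords, [0], [1], toy_params(2))

    def test_ab_coefficient_conversion(self):
        eps, sigma = 0.21, 3.4
        A = 4 * eps * sigma**12
        B = 4 * eps * sigma**6
        eps2, sigma2 = lj_from_ab(A, B)
        assert eps2 == pytest.approx(eps)
        assert sigma2 == pytest.approx(sigma)


class TestReplicateStats:
    def test_identical_series_zero_sd(self):
        s = np.linspace(0, 1, 10)
        stats = replicate_stats([s, s, s])
        assert np.allclose(stats.sd, 0.0)
        assert np.allclose(stats.mean, s)

    def test_two_value_sd(self):
        stats = replicate_stats([np.array([1.0]), np.array([3.0])])
        assert stats.mean[0] == pytest.approx(2.0)
        assert stats.sd[0] == pytest.approx(math.sqrt(2))

    def test_full_window_reproduces_global_mean(self):
        rng = np.random.default_rng(0)
        series = [rng.normal(size=50) for _ in range(3)]
        stats = replicate_stats(series, window=(0, 50))
        assert stats.window_mean == pytest.approx(np.mean(series))

    def test_fraction_window_last_tenth(self):
        assert fraction_window(100, 0.9, 1.0) == (90, 100)

    def test_unequal_lengths_error(self):
        with pytest.raises(InvalidParameterError, match="unequal"):
            replicate_stats([np.zeros(5), np.zeros(6)])


class TestTrajectoryIO:
    def test_multi_model_pdb_round_trip(self):
        ref = gen_random_cluster(8, seed=10)
        traj = gen_trajectory(ref, 0.2, 4, seed=11)
        back = read_trajectory_pdb(write_trajectory_pdb(traj))
        assert back.n_frames == 4 and back.n_atoms == 8
        assert np.allclose(back.frames, traj.frames, atol=1e-3)

    def test_xyz_reader(self):
        text = "3\nframe 1\nC 0 0 0\nC 1 0 0\nO 0 1 0\n" \
               "3\nframe 2\nC 0 0 1\nC 1 0 1\nO 0 1 1\n"
        traj = read_trajectory_xyz(text)
        assert traj.n_frames == 2 and traj.n_atoms == 3
        assert list(traj.topology.element) == ["C", "C", "O"]
        assert traj.frames[1, 0, 2] == pytest.approx(1.0)

    def test_selection_parse_and_resolve(self):
        ref = gen_random_cluster(10, seed=12)
        sel = Selection.parse("chain A and resid 3-5")
        assert list(sel.resolve(ref)) == [2, 3, 4]
        with pytest.raises(Exception):
            Selection.parse("bogus clause here").resolve(ref)
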