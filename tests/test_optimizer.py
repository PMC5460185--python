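import numpy as np
import pytest

from hic3d.errors import ValidationError
from hic3d.io import BinTable
from hic3d.optimizer import (
    Conformation,
    OptimizerParams,
    adaptive_step,
    bond_energy,
    generate_ensemble,
    optimize,
    random_coil,
    restraint_energy,
    total_energy,
    total_gradient,
)
from hic3d.restraints import RestraintSet


def make_restraints(n_beads, i, j, target, d_eq=0.4, bin_size=50_000):
    i = np.asarray(i)
    target = np.asarray(target, dtype=float)
    bins = BinTable("chr1", bin_size, n_beads)
    return RestraintSet(i, np.asarray(j), target, 1.0 / target**2,
                        np.full(n_beads - 1, d_eq), bins)


class TestBondEnergy:
    def test_zero_at_equilibrium(self):
        assert bond_energy(0.4, 0.4, 5.0) == 0.0

    def test_unit_displacement(self):
        assert bond_energy(2.0, 1.0, 2.0) == pytest.approx(1.0)

    def test_two_units(self):
        assert bond_energy(3.0, 1.0, 1.0) == pytest.approx(2.0)


class TestRestraintEnergy:
    def test_zero_at_target(self):
        assert restraint_energy(1.5, 1.5, 1.0, 1.0) == pytest.approx(0.0)

    def test_upper_branch_quadratic(self):
        assert restraint_energy(3.0, 1.0, 1.0, 1.0) == pytest.approx(4.0)

    def test_lower_branch_closed_form(self):
        # d = 1/e, target 1: E = 1/e - ln(1/e) - 1 = 1/e
        assert restraint_energy(1 / np.e, 1.0, 1.0, 1.0) == pytest.approx(1 / np.e)

    def test_zero_distance_capped_finite(self):
        e = restraint_energy(0.0, 1.0, 1.0, 1.0)
        assert np.isfinite(e) and e > 10.0

    def test_nonnegative_everywhere(self):
        d = np.linspace(1e-6, 5.0, 500)
        e = restraint_energy(d, 1.3, 2.0, 2.0)
        assert np.all(e >= -1e-12)

    def test_continuous_at_junction(self):
        eps = 1e-8
        below = restraint_energy(1.0 - eps, 1.0, 3.0, 3.0)
        above = restraint_energy(1.0 + eps, 1.0, 3.0, 3.0)
        assert abs(below - above) < 1e-12


class TestTotalGradient:
    def test_zero_at_exact_targets(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        rs = make_restraints(3, [0, 0, 1], [1, 2, 2], [1.0, 2.0, 1.0], d_eq=1.0)
        conf = Conformation(coords, rs.bins)
        grad = total_gradient(conf, rs)
        np.testing.assert_allclose(grad, 0.0, atol=1e-12)

    def test_two_bead_harmonic_bond(self):
        bins = BinTable("chr1", 50_000, 2)
        delta = 0.3
        rs = RestraintSet(np.empty(0, dtype=int), np.empty(0, dtype=int),
                          np.empty(0), np.empty(0), np.array([1.0]), bins)
        conf = Conformation(np.array([[0.0, 0, 0], [1.0 + delta, 0, 0]]), bins)
        params = OptimizerParams(k_bond=2.0)
        grad = total_gradient(conf, rs, params)
        assert grad[1, 0] == pytest.approx(2.0 * delta)
        np.testing.assert_allclose(grad[0], -grad[1])

    @pytest.mark.parametrize("use_numba", [True, False])
    def test_matches_finite_differences(self, rng, use_numba):
        n = 10
        bins = BinTable("chr1", 50_000, n)
        iu, ju = np.triu_indices(n, k=1)
        keep = rng.random(len(iu)) < 0.6
        target = rng.uniform(0.5, 2.0, keep.sum())
        rs = RestraintSet(iu[keep], ju[keep], target, 1.0 / target**2,
                          np.full(n - 1, 0.4), bins)
        coords = rng.normal(size=(n, 3))
        conf = Conformation(coords, bins)
        params = OptimizerParams(use_numba=use_numba)
        grad = total_gradient(conf, rs, params)
        h = 1e-6
        num = np.zeros_like(grad)
        for b in range(n):
            for ax in range(3):
                for sign, store in ((1, 1.0), (-1, -1.0)):
                    shifted = coords.copy()
                    shifted[b, ax] += sign * h
                    num[b, ax] += store * total_energy(
                        Conformation(shifted, bins), rs, params)
        num /= 2 * h
        scale = np.abs(grad).max()
        np.testing.assert_allclose(grad, num, atol=scale * 1e-5)

    def test_numba_and_numpy_paths_agree(self, rng):
        n = 20
        bins = BinTable("chr1", 50_000, n)
        iu, ju = np.triu_indices(n, k=1)
        target = rng.uniform(0.3, 3.0, len(iu))
        rs = RestraintSet(iu, ju, target, 1.0 / target**2,
                          np.full(n - 1, 0.4), bins)
        conf = Conformation(rng.normal(size=(n, 3)), bins)
        g_fast = total_gradient(conf, rs, OptimizerParams(use_numba=True))
        g_ref = total_gradient(conf, rs, OptimizerParams(use_numba=False))
        np.testing.assert_allclose(g_fast, g_ref, rtol=1e-12, atol=1e-12)


class TestAdaptiveStep:
    def test_inverse_proportionality(self):
        f = np.array([[1.0, 0, 0], [0, 2.0, 0]])
        dt1 = adaptive_step(f, step_scale=0.1)
        dt2 = adaptive_step(2 * f, step_scale=0.1)
        assert dt1 == pytest.approx(2 * dt2)

    def test_zero_forces_give_dt_max(self):
        assert adaptive_step(np.zeros((5, 3)), 0.1, dt_max=7.0) == 7.0

    def test_clipped_at_boundaries(self):
        tiny = np.full((2, 3), 1e-12)
        assert adaptive_step(tiny, 0.1, dt_max=5.0) == 5.0
        huge = np.full((2, 3), 1e12)
        assert adaptive_step(huge, 0.1, dt_min=1e-6) == 1e-6


class TestOptimize:
    def test_achievable_triangle(self):
        rs = make_restraints(3, [0, 0, 1], [1, 2, 2], [1.0, 1.0, 1.0], d_eq=1.0)
        coil = random_coil(rs.bins, 1.0, 5.0, seed=3)
        params = OptimizerParams(n_steps=4000, k_bond=1.0)
        res = optimize(coil, rs, params, seed=3)
        d = res.conformation.pairwise_distances(rs.i, rs.j)
        np.testing.assert_allclose(d, rs.target, rtol=0.01)

    def test_satisfied_conformation_is_fixed_point(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        rs = make_restraints(3, [0, 0, 1], [1, 2, 2], [1.0, 2.0, 1.0], d_eq=1.0)
        conf = Conformation(coords, rs.bins)
        res = optimize(conf, rs, OptimizerParams(n_steps=500), seed=0)
        np.testing.assert_allclose(res.conformation.coords, coords, atol=1e-9)

    def test_same_seed_bitwise_identical(self):
        rs = make_restraints(5, [0, 1, 0], [2, 3, 4], [0.8, 0.8, 1.2], d_eq=0.4)
        coil = random_coil(rs.bins, 0.4, 3.0, seed=11)
        params = OptimizerParams(n_steps=300)
        r1 = optimize(coil, rs, params, seed=11)
        r2 = optimize(coil, rs, params, seed=11)
        np.testing.assert_array_equal(r1.conformation.coords, r2.conformation.coords)

    def test_final_violation_not_worse_than_initial(self, rng):
        n = 20
        bins = BinTable("chr1", 50_000, n)
        iu, ju = np.triu_indices(n, k=1)
        target = rng.uniform(0.3, 2.0, len(iu))
        rs = RestraintSet(iu, ju, target, 1.0 / target**2,
                          np.full(n - 1, 0.4), bins)
        coil = random_coil(bins, 0.4, 3.0, seed=5)
        res = optimize(coil, rs, OptimizerParams(n_steps=1000), seed=5)
        assert res.final_violation <= res.initial_violation

    def test_size_mismatch_rejected(self):
        rs = make_restraints(5, [0], [4], [1.0])
        conf = Conformation(np.zeros((3, 3)), BinTable("chr1", 50_000, 3))
        with pytest.raises(ValidationError):
            optimize(conf, rs, OptimizerParams(n_steps=10), seed=0)


class TestGenerateEnsemble:
    @pytest.fixture
    def small_restraints(self, rng):
        n = 30
        bins = BinTable("chr1", 50_000, n)
        iu, ju = np.triu_indices(n, k=1)
        keep = rng.random(len(iu)) < 0.5
        target = rng.uniform(0.4, 2.5, keep.sum())
        return RestraintSet(iu[keep], ju[keep], target, 1.0 / target**2,
                            np.full(n - 1, 0.4), bins)

    def test_single_model_equals_optimize(self, small_restraints):
        from hic3d.restraints import ScalingModel

        params = OptimizerParams(n_steps=200)
        ens = generate_ensemble(small_restraints, params, n_models=1, base_seed=9)
        coil = random_coil(small_restraints.bins,
                           float(small_restraints.d_eq.mean()),
                           ScalingModel().distance(small_restraints.bins.total_bp),
                           seed=9)
        direct = optimize(coil, small_restraints, params, seed=9)
        np.testing.assert_array_equal(ens[0].coords, direct.conformation.coords)

    def test_reproducible(self, small_restraints):
        params = OptimizerParams(n_steps=200)
        e1 = generate_ensemble(small_restraints, params, n_models=3, base_seed=2)
        e2 = generate_ensemble(small_restraints, params, n_models=3, base_seed=2)
        for a, b in zip(e1, e2):
            np.testing.assert_array_equal(a.coords, b.coords)

    def test_models_beat_initial_coil(self, small_restraints):
        from hic3d.ensemble import satisfaction
        from hic3d.restraints import ScalingModel

        params = OptimizerParams(n_steps=2000)
        radius = ScalingModel().distance(small_restraints.bins.total_bp)
        ens = generate_ensemble(small_restraints, params, n_models=4, base_seed=0)
        for k, conf in enumerate(ens):
            coil = random_coil(small_restraints.bins, 0.4, radius, seed=k)
            s_opt = satisfaction([conf], small_restraints).satisfaction_fraction
            s_coil = satisfaction([coil], small_restraints).satisfaction_fraction
            assert s_opt > s_coil


class TestLateTrajectoryDrift:
    def test_rms_drift_below_one_percent_of_rg(self, rng):
        # feasible targets (distances of an actual geometry), the regime the
        # convergence claim is about
        n = 25
        bins = BinTable("chr1", 50_000, n)
        truth = np.cumsum(rng.normal(0, 0.3, size=(n, 3)), axis=0)
        iu, ju = np.triu_indices(n, k=1)
        target = np.sqrt(((truth[iu] - truth[ju]) ** 2).sum(axis=1))
        rs = RestraintSet(iu, ju, target, 1.0 / target**2,
                          np.full(n - 1, 0.4), bins)
        coil = random_coil(bins, 0.4, 3.0, seed=1)
        res = optimize(coil, rs, OptimizerParams(n_steps=4000), seed=1)
        assert res.late_drift_rms < 0.01 * res.conformation.radius_of_gyration()
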