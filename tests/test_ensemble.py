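import numpy as np
import pytest

from hic3d.ensemble import (
    cluster_ensemble,
    inverse_map,
    local_density,
    rmsd,
    satisfaction,
)
from hic3d.errors import ValidationError
from hic3d.io import BinTable
from hic3d.optimizer import Conformation
from hic3d.restraints import (
    DecayCurve,
    RestraintSet,
    ScalingModel,
    contact_to_distance,
    distance_to_contact,
)


def conf_from(coords, bin_size=50_000):
    coords = np.asarray(coords, dtype=float)
    return Conformation(coords, BinTable("chr1", bin_size, len(coords)))


def restraints_for(coords, targets=None):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    iu, ju = np.triu_indices(n, k=1)
    if targets is None:
        targets = np.sqrt(((coords[iu] - coords[ju]) ** 2).sum(axis=1))
    return RestraintSet(iu, ju, targets, 1.0 / targets**2,
                        np.full(n - 1, 1.0), BinTable("chr1", 50_000, n))


class TestSatisfaction:
    def test_exact_targets_give_one(self, rng):
        coords = rng.normal(size=(6, 3)) * 2
        rs = restraints_for(coords)
        s = satisfaction([conf_from(coords)], rs)
        assert s.satisfaction_fraction == 1.0

    def test_direct_count(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [3.0, 0, 0]])
        # targets: pair (0,1) at 2.5 -> ratio 0.4 (out); (0,2) at 3 -> 1.0 (in);
        # (1,2) at 2 -> exactly 1.0 (in)
        rs = RestraintSet([0, 0, 1], [1, 2, 2], [2.5, 3.0, 2.0],
                          [1.0, 1.0, 1.0], [1.0, 1.0],
                          BinTable("chr1", 50_000, 3))
        s = satisfaction([conf_from(coords)], rs)
        assert s.satisfaction_fraction == pytest.approx(2 / 3)

    def test_inclusive_upper_bound(self, rng):
        coords = rng.normal(size=(5, 3))
        rs = restraints_for(coords)
        doubled = conf_from(2.0 * coords)
        s = satisfaction([doubled], rs)
        assert s.satisfaction_fraction == 1.0

    def test_invariant_to_rigid_motion(self, rng):
        coords = rng.normal(size=(8, 3))
        rs = restraints_for(coords, targets=rng.uniform(0.5, 2, 28))
        from scipy.spatial.transform import Rotation

        R = Rotation.random(random_state=4).as_matrix()
        moved = conf_from(coords @ R.T + np.array([5.0, -2.0, 1.0]))
        s1 = satisfaction([conf_from(coords)], rs).satisfaction_fraction
        s2 = satisfaction([moved], rs).satisfaction_fraction
        assert s1 == pytest.approx(s2)

    def test_empty_restraints_rejected(self, rng):
        coords = rng.normal(size=(3, 3))
        rs = RestraintSet(np.empty(0, dtype=int), np.empty(0, dtype=int),
                          np.empty(0), np.empty(0), [1.0, 1.0],
                          BinTable("chr1", 50_000, 3))
        with pytest.raises(ValidationError):
            satisfaction([conf_from(coords)], rs)


class TestInverseMap:
    @pytest.fixture
    def curve(self):
        l = np.arange(1, 30) * 50_000.0
        return DecayCurve(l, 100.0 / (l / 50_000.0))

    def test_knot_distances_give_knot_contacts(self, curve, scaling):
        d_knots = scaling.distance(curve.l)
        # chain positioned so consecutive-pair distances equal knot distances
        coords = np.zeros((4, 3))
        coords[1, 0] = d_knots[0]
        coords[2, 0] = d_knots[0] + d_knots[1]
        coords[3, 0] = d_knots[0] + d_knots[1] + d_knots[2]
        m = inverse_map([conf_from(coords)], curve, scaling)
        for i in range(3):
            d = coords[i + 1, 0] - coords[i, 0]
            expect = distance_to_contact(d, curve, scaling)
            assert m.C[i, i + 1] == pytest.approx(expect, rel=1e-9)

    def test_roundtrip_through_contact_to_distance(self, curve, scaling, rng):
        contacts = rng.uniform(5.0, 90.0, size=3)
        d = contact_to_distance(contacts, curve, scaling)
        coords = np.zeros((3, 3))
        coords[1] = [d[0], 0, 0]
        # place bead 2 to satisfy d(0,2)=d[1], d(1,2)=d[2] (triangle)
        x = (d[0] ** 2 + d[1] ** 2 - d[2] ** 2) / (2 * d[0])
        y = np.sqrt(d[1] ** 2 - x**2)
        coords[2] = [x, y, 0]
        m = inverse_map([conf_from(coords)], curve, scaling)
        assert m.C[0, 1] == pytest.approx(contacts[0], rel=1e-6)
        assert m.C[0, 2] == pytest.approx(contacts[1], rel=1e-6)
        assert m.C[1, 2] == pytest.approx(contacts[2], rel=1e-6)

    def test_two_identical_models_average_to_same(self, curve, scaling, rng):
        coords = rng.normal(size=(6, 3))
        one = inverse_map([conf_from(coords)], curve, scaling)
        two = inverse_map([conf_from(coords), conf_from(coords)], curve, scaling)
        np.testing.assert_allclose(one.C, two.C)

    def test_symmetric_nonnegative(self, curve, scaling, rng):
        m = inverse_map([conf_from(rng.normal(size=(7, 3)))], curve, scaling)
        np.testing.assert_allclose(m.C, m.C.T)
        assert np.all(m.C >= 0)

    def test_shrinking_distances_never_decreases_contacts(self, curve, scaling, rng):
        coords = rng.normal(size=(6, 3)) * 2
        m1 = inverse_map([conf_from(coords)], curve, scaling)
        m2 = inverse_map([conf_from(0.5 * coords)], curve, scaling)
        iu = np.triu_indices(6, k=1)
        assert np.all(m2.C[iu] >= m1.C[iu] - 1e-12)


class TestRmsd:
    def test_self_zero(self, rng):
        a = conf_from(rng.normal(size=(10, 3)))
        assert rmsd(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self, rng):
        from scipy.spatial.transform import Rotation

        coords = rng.normal(size=(12, 3))
        R = Rotation.random(random_state=7).as_matrix()
        b = coords @ R.T + np.array([1.0, 2.0, 3.0])
        assert rmsd(conf_from(coords), conf_from(b)) < 1e-10

    def test_reflection_only_matched_with_flag(self, rng):
        coords = rng.normal(size=(10, 3))
        mirrored = coords * np.array([-1.0, 1.0, 1.0])
        a, b = conf_from(coords), conf_from(mirrored)
        assert rmsd(a, b, allow_reflection=True) < 1e-10
        assert rmsd(a, b, allow_reflection=False) > 0.1

    def test_matches_rotation_grid_oracle(self):
        a = conf_from([[0.0, 0, 0], [2.0, 0, 0], [0.0, 1.5, 0]])
        b = conf_from([[0.1, 0.2, 0], [1.8, -0.1, 0.3], [0.2, 1.2, -0.2]])
        got = rmsd(a, b, allow_reflection=False)
        # brute force over a fine grid of proper rotations
        from scipy.spatial.transform import Rotation

        A = a.coords - a.coords.mean(axis=0)
        B = b.coords - b.coords.mean(axis=0)
        best = np.inf
        grid = np.linspace(0, 2 * np.pi, 60, endpoint=False)
        half = np.linspace(0, np.pi, 30)
        for z1 in grid:
            for x in half:
                for z2 in grid:
                    R = Rotation.from_euler("zxz", [z1, x, z2]).as_matrix()
                    v = np.sqrt(((A @ R.T - B) ** 2).sum(axis=1).mean())
                    best = min(best, v)
        assert got == pytest.approx(best, abs=2e-3)
        assert got <= best + 1e-12  # analytic optimum can only be better

    def test_symmetry_and_triangle_inequality(self, rng):
        confs = [conf_from(rng.normal(size=(8, 3))) for _ in range(4)]
        for a in confs:
            for b in confs:
                assert rmsd(a, b) == pytest.approx(rmsd(b, a), abs=1e-10)
        for a in confs:
            for b in confs:
                for c in confs:
                    assert rmsd(a, c) <= rmsd(a, b) + rmsd(b, c) + 1e-9

    def test_size_mismatch(self, rng):
        with pytest.raises(ValidationError):
            rmsd(conf_from(rng.normal(size=(5, 3))),
                 conf_from(rng.normal(size=(6, 3))))


class TestClusterEnsemble:
    def test_identical_models_all_zero(self, rng):
        coords = rng.normal(size=(6, 3))
        ens = [conf_from(coords) for _ in range(4)]
        result = cluster_ensemble(ens, n_clusters=2)
        assert np.all(result.rmsd_matrix < 1e-12)

    def test_planted_two_families(self, rng):
        base1 = rng.normal(size=(10, 3)) * 2
        base2 = rng.normal(size=(10, 3)) * 2 + 10
        ens = []
        truth = []
        for k in range(6):
            base = base1 if k % 2 == 0 else base2
            ens.append(conf_from(base + rng.normal(0, 0.01, size=(10, 3))))
            truth.append(k % 2)
        result = cluster_ensemble(ens, n_clusters=2)
        labels = result.labels
        truth = np.array(truth)
        agreement = max((labels == labels[truth == 0][0]).sum(), 0)
        # all members of each family share a label
        assert len(set(labels[truth == 0])) == 1
        assert len(set(labels[truth == 1])) == 1
        assert labels[truth == 0][0] != labels[truth == 1][0]

    def test_representative_minimizes_mean_rmsd(self, rng):
        ens = [conf_from(rng.normal(size=(7, 3))) for _ in range(6)]
        result = cluster_ensemble(ens, n_clusters=1)
        M = result.rmsd_matrix
        members = np.arange(6)
        means = M.sum(axis=1) / 5
        assert means[result.representative] == pytest.approx(means.min())

    def test_too_many_clusters_rejected(self, rng):
        ens = [conf_from(rng.normal(size=(5, 3))) for _ in range(3)]
        with pytest.raises(ValidationError):
            cluster_ensemble(ens, n_clusters=4)


class TestLocalDensity:
    def test_two_distant_beads(self):
        t = local_density(conf_from([[0.0, 0, 0], [10.0, 0, 0]]), radius_um=1.0)
        np.testing.assert_array_equal(t.values, [0.0, 0.0])

    def test_equilateral_triangle(self):
        s = 0.5
        coords = [[0.0, 0, 0], [s, 0, 0], [s / 2, s * np.sqrt(3) / 2, 0]]
        t = local_density(conf_from(coords), radius_um=1.0)
        np.testing.assert_array_equal(t.values, [2.0, 2.0, 2.0])

    def test_matches_bruteforce(self, rng):
        coords = rng.normal(size=(100, 3))
        t = local_density(conf_from(coords), radius_um=0.8)
        for i in range(100):
            count = sum(1 for j in range(100) if j != i
                        and np.linalg.norm(coords[i] - coords[j]) <= 0.8)
            assert t.values[i] == count
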