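import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sbtip import (TargetAtoms, cell_assign, cell_masses,
                   cluster_terminal_loss, ot_energy_grad, solve_heights,
                   split_by_target_clusters)


def disk_samples(n=20000, seed=0):
    rng = np.random.default_rng(seed)
    r = np.sqrt(rng.random(n))
    th = rng.uniform(0, 2 * np.pi, n)
    return np.stack([r * np.cos(th), r * np.sin(th)], axis=1)


TWO_ATOMS = TargetAtoms([[1.0, 0.0], [-1.0, 0.0]], [0.5, 0.5])


class TestCellAssign:
    def test_inner_product_argmax(self):
        assert cell_assign(np.array([0.5, 0.0]), TWO_ATOMS, [0.0, 0.0]) == 0
        assert cell_assign(np.array([-0.5, 0.0]), TWO_ATOMS, [0.0, 0.0]) == 1

    def test_tie_breaks_to_lowest_index(self):
        assert cell_assign(np.array([0.0, 0.7]), TWO_ATOMS, [0.0, 0.0]) == 0

    def test_raising_height_captures_point(self):
        x = np.array([0.9, 0.0])
        # needs h_1 > max_i <x, y_i - y_1> = <x, y_0 - y_1> = 1.8
        assert cell_assign(x, TWO_ATOMS, [0.0, 1.9]) == 1

    @given(st.floats(-5, 5), st.integers(0, 2 ** 31 - 1))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_gauge_invariance(self, c, seed):
        rng = np.random.default_rng(seed)
        atoms = TargetAtoms(rng.normal(0, 1, (5, 2)),
                            np.full(5, 0.2))
        h = rng.normal(0, 1, 5)
        x = rng.normal(0, 2, (20, 2))
        assert np.array_equal(cell_assign(x, atoms, h),
                              cell_assign(x, atoms, h + c))


class TestCellMasses:
    def test_single_atom_takes_all(self):
        atoms = TargetAtoms([[0.3, 0.3]], [1.0])
        assert cell_masses(disk_samples(100), atoms, [0.0]) == pytest.approx([1.0])

    def test_symmetric_disk_splits_evenly(self):
        om = cell_masses(disk_samples(), TWO_ATOMS, [0.0, 0.0])
        assert np.allclose(om, [0.5, 0.5], atol=0.02)

    def test_conservation_under_random_heights(self):
        rng = np.random.default_rng(4)
        atoms = TargetAtoms(rng.normal(0, 1, (7, 2)), np.full(7, 1 / 7))
        for _ in range(5):
            h = rng.normal(0, 2, 7)
            om = cell_masses(disk_samples(3000, seed=1), atoms, h)
            assert om.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_source_rejected(self):
        with pytest.raises(ValueError):
            cell_masses(np.empty((0, 2)), TWO_ATOMS, [0.0, 0.0])


class TestEnergy:
    def test_gradient_is_mass_mismatch(self):
        X = disk_samples(5000, seed=2)
        h = np.array([0.3, -0.1])
        _, grad = ot_energy_grad(X, TWO_ATOMS, h)
        om = cell_masses(X, TWO_ATOMS, h)
        assert np.allclose(grad, om - TWO_ATOMS.nu)

    def test_finite_difference_check(self):
        X = disk_samples(20000, seed=3)
        atoms = TargetAtoms([[1.0, 0.2], [-0.5, 0.8], [0.1, -1.0]],
                            [0.3, 0.3, 0.4])
        h = np.array([0.05, -0.1, 0.0])
        eps = 0.05
        for i in range(3):
            e = np.zeros(3)
            e[i] = eps
            Ep, _ = ot_energy_grad(X, atoms, h + e, n_quad=256)
            Em, _ = ot_energy_grad(X, atoms, h, n_quad=256)
            fd = (Ep - Em) / eps
            om = cell_masses(X, atoms, h + 0.5 * e)
            assert fd == pytest.approx(om[i] - atoms.nu[i], abs=0.02)

    def test_additive_constant_invariance(self):
        X = disk_samples(2000, seed=4)
        h = np.array([0.4, -0.2])
        E0, _ = ot_energy_grad(X, TWO_ATOMS, h)
        E1, _ = ot_energy_grad(X, TWO_ATOMS, h + 3.0)
        # E(h + c 1) - E(h) = c (sum omega) - c (sum nu) = 0
        assert E1 == pytest.approx(E0, abs=1e-9)


class TestSolveHeights:
    def test_symmetric_problem_keeps_zero_heights(self):
        h = solve_heights(disk_samples(), TWO_ATOMS, tol=0.01)
        assert np.allclose(h, 0.0, atol=0.05)

    def test_asymmetric_masses_match(self):
        atoms = TargetAtoms([[1.0, 0.0], [-1.0, 0.0]], [0.75, 0.25])
        X = disk_samples()
        h = solve_heights(X, atoms, tol=0.01)
        om = cell_masses(X, atoms, h)
        assert np.allclose(om, [0.75, 0.25], atol=0.02)
        assert h[-1] == 0.0  # gauge

    def test_single_atom_trivial(self):
        atoms = TargetAtoms([[0.0, 0.0]], [1.0])
        h = solve_heights(disk_samples(50), atoms)
        assert np.array_equal(h, [0.0])

    def test_nonconvergence_reports_residual(self):
        atoms = TargetAtoms([[1.0, 0.0], [-1.0, 0.0]], [0.9, 0.1])
        with pytest.raises(RuntimeError, match="residual"):
            solve_heights(disk_samples(500, seed=5), atoms, tol=1e-6,
                          max_iters=3)


class TestSplit:
    def test_single_cluster_covers_everything(self):
        rng = np.random.default_rng(0)
        r0 = rng.normal(0, 1, (300, 2))
        r1 = rng.normal(3, 1, (300, 2))
        res = split_by_target_clusters(r0, r1, 1)
        assert len(res.pairs) == 1
        assert res.pairs[0][0].size == 300
        assert res.pairs[0][1].size == 300

    def test_mass_preservation_60_40(self):
        rng = np.random.default_rng(1)
        n = 3000
        comp = (rng.random(n) < 0.4).astype(int)
        r1 = np.where(comp[:, None] == 0,
                      np.array([3.0, 2.0]) + 0.4 * rng.standard_normal((n, 2)),
                      np.array([3.0, -2.0]) + 0.4 * rng.standard_normal((n, 2)))
        r0 = np.array([-3.0, 0.0]) + 0.8 * rng.standard_normal((n, 2))
        res = split_by_target_clusters(r0, r1, 2, seed=0)
        target_w = np.bincount(res.labels1) / n
        assert np.allclose(np.sort(res.source_masses), np.sort(target_w),
                           atol=0.03)

    def test_partition_is_disjoint_and_exhaustive(self):
        rng = np.random.default_rng(2)
        r0 = rng.normal(0, 1, (500, 2))
        r1 = np.vstack([np.array([4.0, 3.0]) + 0.3 * rng.standard_normal((250, 2)),
                        np.array([4.0, -3.0]) + 0.3 * rng.standard_normal((250, 2))])
        res = split_by_target_clusters(r0, r1, 2, seed=1)
        union = np.concatenate([p[0] for p in res.pairs])
        assert np.array_equal(np.sort(union), np.arange(500))

    def test_caller_labels_respected(self):
        rng = np.random.default_rng(3)
        r0 = rng.normal(0, 1, (200, 2))
        r1 = rng.normal(2, 1, (200, 2))
        labels = (np.arange(200) % 2)
        res = split_by_target_clusters(r0, r1, 2, labels1=labels, seed=0)
        assert np.array_equal(res.labels1, labels)


class TestClusterTerminalLoss:
    def test_zero_at_targets(self):
        X = np.array([[1.0, 2.0], [0.0, -1.0]])
        assert cluster_terminal_loss(X, X) == 0.0

    def test_hand_summed_three_paths(self):
        X = np.array([[1.0, 0.0], [0.0, 2.0], [-1.0, -1.0]])
        Y = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        hand = (1.0 + 4.0 + (4.0 + 4.0)) / 3.0
        assert cluster_terminal_loss(X, Y) == pytest.approx(hand, abs=1e-12)

    def test_quadratic_scaling(self):
        rng = np.random.default_rng(5)
        Y = rng.normal(0, 1, (10, 2))
        R = rng.normal(0, 1, (10, 2))
        l1 = cluster_terminal_loss(Y + R, Y)
        l2 = cluster_terminal_loss(Y + 2 * R, Y)
        assert l2 == pytest.approx(4 * l1, rel=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cluster_terminal_loss(np.zeros((3, 2)), np.zeros((4, 2)))


class TestTargetAtoms:
    def test_weight_validation(self):
        with pytest.raises(ValueError):
            TargetAtoms([[0.0, 0.0]], [0.0])
        with pytest.raises(ValueError):
            TargetAtoms([[0.0, 0.0], [1.0, 1.0]], [0.4, 0.4])
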