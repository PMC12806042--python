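import numpy as np
import pytest

from sbtip import (BridgeModel, ConstantField, NoiseSchedule, TrainConfig,
                   TrajectoryEnsemble, ZERO_DRIFT, ZeroField,
                   alternating_train, gaussian_bridge_score,
                   gaussian_sb_closed_form, kde_density, likelihood_loss,
                   load_model, marginal_consistency, propagate_backward,
                   propagate_forward, save_model)


def brownian_model(g=0.5, T=1.0, N=50, dim=1):
    return BridgeModel(ZERO_DRIFT, NoiseSchedule(g), ZeroField(dim),
                       ZeroField(dim), T=T, N=N)


class TestNoiseSchedule:
    def test_constant_linear_cosine(self):
        assert NoiseSchedule(0.3).value(0.7) == 0.3
        lin = NoiseSchedule(1.0, "linear", 0.0)
        assert lin.value(0.25) == pytest.approx(0.75)
        cos = NoiseSchedule(1.0, "cosine", 0.0)
        assert cos.value(0.0) == pytest.approx(1.0)
        assert cos.value(1.0) == pytest.approx(0.0)
        assert cos.value(0.5) == pytest.approx(0.5)

    def test_validation(self):
        with pytest.raises(ValueError):
            NoiseSchedule(-0.1)
        with pytest.raises(ValueError):
            NoiseSchedule(0.1, kind="bogus")


class TestPropagation:
    def test_brownian_terminal_variance(self):
        g, T, n = 0.7, 2.0, 5000
        m = brownian_model(g, T, N=50)
        x0 = np.zeros((1, 1))
        ens = propagate_forward(m, x0, n, seed=3)
        incr = ens.states[:, -1, 0] - ens.states[:, 0, 0]
        var = incr.var()
        # Var(X_T - X_0) = g^2 T; MC standard error of a variance ~ var*sqrt(2/n)
        se = g * g * T * np.sqrt(2.0 / n)
        assert abs(var - g * g * T) < 3 * se

    def test_backward_brownian_variance_growth(self):
        g, T, n = 0.5, 1.0, 5000
        m = brownian_model(g, T, N=40)
        ens = propagate_backward(m, np.zeros((1, 1)), n, seed=4)
        # integrated from t=T: variance at time t is g^2 (T - t)
        for k in (0, 10, 20, 30):
            t = ens.times[k]
            var = ens.states[:, k, 0].var()
            expect = g * g * (T - t)
            se = max(expect, 1e-3) * np.sqrt(2.0 / n)
            assert abs(var - expect) < 4 * se

    def test_deterministic_single_path_ignores_seed(self):
        m = BridgeModel(ZERO_DRIFT, NoiseSchedule(0.0), ConstantField([1.0]),
                        ZeroField(1), T=1.0, N=20)
        a = propagate_forward(m, np.array([[0.5]]), 1, seed=1)
        b = propagate_forward(m, np.array([[0.5]]), 1, seed=99)
        assert np.array_equal(a.states, b.states)

    def test_empty_marginal_rejected(self):
        m = brownian_model()
        with pytest.raises(ValueError):
            propagate_forward(m, np.empty((0, 1)), 10, seed=0)

    def test_oracle_score_reproduces_closed_form_marginals(self, gaussian_specs):
        a, b = gaussian_specs
        g, n = 0.5, 5000
        score = gaussian_bridge_score(a, b, g)
        m = BridgeModel(ZERO_DRIFT, NoiseSchedule(g), score, ZeroField(1),
                        T=1.0, N=100)
        rng = np.random.default_rng(7)
        rho0 = a.mean + a.sd * rng.standard_normal((n, 1))
        ens = propagate_forward(m, rho0, n, seed=8)
        mean_cf, var_cf = gaussian_sb_closed_form(a, b, g, m.tau_grid)
        emp_m = ens.states[:, :, 0].mean(axis=0)
        emp_v = ens.states[:, :, 0].var(axis=0)
        se_m = np.sqrt(var_cf / n)
        se_v = var_cf * np.sqrt(2.0 / n)
        # small Euler bias allowance on top of 3 MC standard errors
        assert np.all(np.abs(emp_m - mean_cf) < 3 * se_m + 5e-3)
        assert np.all(np.abs(emp_v - var_cf) < 3 * se_v + 5e-3)


class TestLikelihoodLoss:
    def test_zero_scores_reduce_to_terminal_term(self):
        m = brownian_model(g=0.4, N=20)
        ens = propagate_forward(m, np.zeros((1, 1)), 10, seed=5)

        def log_std_normal(x):
            x = np.atleast_2d(x)
            return -0.5 * np.sum(x * x, axis=1) - 0.5 * x.shape[1] * np.log(2 * np.pi)

        loss = likelihood_loss(m, ens, terminal_log_density=log_std_normal)
        xT = ens.states[:, -1, 0]
        hand = np.mean(0.5 * xT ** 2 + 0.5 * np.log(2 * np.pi))
        assert loss == pytest.approx(hand, abs=1e-10)

    def test_constant_backward_field_has_zero_divergence_term(self):
        m = BridgeModel(ZERO_DRIFT, NoiseSchedule(0.4), ZeroField(1),
                        ConstantField([2.0]), T=1.0, N=20)
        ens = propagate_forward(m, np.zeros((1, 1)), 10, seed=5)
        loss = likelihood_loss(m, ens)
        # only the quadratic term survives: 1/2 * |0 + 2|^2 integrated over [0,1]
        assert loss == pytest.approx(0.5 * 4.0, abs=1e-12)

    def test_quadratic_scaling_of_score_term(self):
        mk = lambda c: BridgeModel(ZERO_DRIFT, NoiseSchedule(0.4),
                                   ConstantField([c]), ConstantField([c]),
                                   T=1.0, N=20)
        ens = propagate_forward(mk(1.0), np.zeros((1, 1)), 10, seed=5)
        l1 = likelihood_loss(mk(1.0), ens)
        l2 = likelihood_loss(mk(2.0), ens)
        assert l2 == pytest.approx(4.0 * l1, rel=1e-12)

    def test_terminal_targets_penalty(self):
        m = brownian_model(N=10)
        ens = propagate_forward(m, np.zeros((3, 1)), 3, seed=1)
        y = np.array([[1.0], [2.0], [3.0]])
        loss = likelihood_loss(m, ens, terminal_targets=y)
        hand = np.mean(np.sum((ens.states[:, -1] - y) ** 2, axis=1))
        assert loss == pytest.approx(hand, abs=1e-12)

    def test_grid_mismatch_rejected(self):
        m = brownian_model(N=10)
        other = brownian_model(N=20)
        ens = propagate_forward(other, np.zeros((1, 1)), 5, seed=0)
        with pytest.raises(ValueError):
            likelihood_loss(m, ens)


class TestTraining:
    def test_zero_stages_returns_initialized_model(self, gaussian_pair_samples):
        rho0, rho1 = gaussian_pair_samples
        cfg = TrainConfig(stages=0)
        model, report = alternating_train(cfg, rho0, rho1,
                                          schedule=NoiseSchedule(0.5), seed=0)
        assert report.records == []
        # displacement initialisation: constant fields, opposite directions
        x = np.linspace(-2, 2, 5)[:, None]
        z0 = model.z_fwd(np.full(5, 0.3), x)
        z1 = model.z_bwd(np.full(5, 0.3), x)
        assert np.allclose(z0, z0[0])
        assert np.allclose(z0, -z1)

    def test_recovers_terminal_moments(self, trained_gaussian_bridge,
                                       gaussian_pair_samples):
        model, _ = trained_gaussian_bridge
        rho0, rho1 = gaussian_pair_samples
        fwd = propagate_forward(model, rho0, 2000, seed=11)
        bwd = propagate_backward(model, rho1, 2000, seed=12)
        assert abs(fwd.states[:, -1, 0].mean() - 2.0) < 0.2
        assert abs(bwd.states[:, 0, 0].mean() - (-2.0)) < 0.2

    def test_forward_backward_midtime_consistency(self, trained_gaussian_bridge,
                                                  gaussian_pair_samples):
        model, _ = trained_gaussian_bridge
        rho0, rho1 = gaussian_pair_samples
        fwd = propagate_forward(model, rho0, 2000, seed=21)
        bwd = propagate_backward(model, rho1, 2000, seed=22)
        l1 = marginal_consistency(fwd, bwd, [0.5])[0]
        assert l1 < 0.3

    def test_loss_decreases_through_first_stage(self, gaussian_pair_samples):
        """Window-averaged likelihood loss decreases while the first stage
        optimises (slow learning rate so the descent spans the stage)."""
        rho0, rho1 = gaussian_pair_samples
        cfg = TrainConfig(stages=1, iters=200, lr=1e-3)
        _, report = alternating_train(cfg, rho0, rho1,
                                      schedule=NoiseSchedule(0.5), seed=0)
        windows = report.losses(stage=0).reshape(-1, 20).mean(axis=1)
        frac = np.mean(np.diff(windows) < 0)
        assert frac >= 0.8

    def test_mismatched_marginal_dims_rejected(self):
        with pytest.raises(ValueError):
            alternating_train(TrainConfig(stages=0), np.zeros((5, 1)),
                              np.zeros((5, 2)))


class TestKDE:
    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, (2000, 2))
        axes, vals = kde_density(x, bandwidth=0.3)
        cell = np.prod([a[1] - a[0] for a in axes])
        assert vals.sum() * cell == pytest.approx(1.0, abs=1e-2)

    def test_mode_location_tight_cluster(self):
        rng = np.random.default_rng(1)
        x = np.array([3.0, -1.0]) + 0.01 * rng.standard_normal((100, 2))
        axes, vals = kde_density(x, grid_spec=[(2, 4, 41), (-2, 0, 41)],
                                 bandwidth=0.1)
        i, j = np.unravel_index(np.argmax(vals), vals.shape)
        assert abs(axes[0][i] - 3.0) <= 0.05 + 1e-9
        assert abs(axes[1][j] + 1.0) <= 0.05 + 1e-9

    def test_matches_analytic_normal_at_mode(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((5000, 1))
        axes, vals = kde_density(x, grid_spec=[(-0.2, 0.2, 21)], bandwidth=0.15)
        peak = vals.max()
        assert peak == pytest.approx(1.0 / np.sqrt(2 * np.pi), rel=0.15)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            kde_density(np.zeros((1, 2)))
        with pytest.raises(ValueError):
            kde_density(np.zeros((10, 2)), bandwidth=0.0)


class TestMarginalConsistency:
    def test_self_comparison_is_zero(self):
        m = brownian_model()
        ens = propagate_forward(m, np.zeros((1, 1)), 200, seed=0)
        d = marginal_consistency(ens, ens, [0.5])
        assert d[0] == pytest.approx(0.0, abs=1e-12)

    def test_equal_law_below_bootstrap_floor(self):
        m = brownian_model(g=0.6, N=40)
        a = propagate_forward(m, np.zeros((1, 1)), 1500, seed=1)
        b = propagate_forward(m, np.zeros((1, 1)), 1500, seed=2)
        b = TrajectoryEnsemble(b.states, b.times, direction="backward")
        d = marginal_consistency(a, b, [0.5])[0]
        # bootstrap floor: L1 between same-law halves of a single ensemble
        rng = np.random.default_rng(3)
        floors = []
        for _ in range(20):
            idx = rng.permutation(1500)
            h1 = TrajectoryEnsemble(a.states[idx[:750]], a.times)
            h2 = TrajectoryEnsemble(a.states[idx[750:]], a.times)
            floors.append(marginal_consistency(h1, h2, [0.5])[0])
        floor = np.mean(floors) + 4 * np.std(floors)
        # halves use 750 paths vs 1500: scale the floor by sqrt(2)
        assert d < floor

    def test_mismatched_grids_rejected(self):
        a = propagate_forward(brownian_model(N=10), np.zeros((1, 1)), 5, seed=0)
        b = propagate_forward(brownian_model(N=20), np.zeros((1, 1)), 5, seed=0)
        with pytest.raises(ValueError):
            marginal_consistency(a, b, [0.5])
        with pytest.raises(ValueError):
            marginal_consistency(a, a, [0.123456])


class TestCheckpoint:
    def test_roundtrip_is_bit_stable(self, trained_gaussian_bridge,
                                     gaussian_pair_samples, tmp_path):
        model, _ = trained_gaussian_bridge
        rho0, rho1 = gaussian_pair_samples
        p1 = tmp_path / "m1.npz"
        p2 = tmp_path / "m2.npz"
        save_model(model, p1, rho0=rho0, rho1=rho1)
        loaded, r0, r1 = load_model(p1)
        save_model(loaded, p2, rho0=r0, rho1=r1)
        assert p1.read_bytes() == p2.read_bytes()
        x = np.linspace(-2, 2, 7)[:, None]
        t = np.full(7, 0.4)
        assert np.array_equal(model.z_fwd(t, x), loaded.z_fwd(t, x))
        assert np.array_equal(model.z_bwd(t, x), loaded.z_bwd(t, x))
        assert loaded.T == model.T and loaded.N == model.N
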