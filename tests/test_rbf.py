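import numpy as np
import pytest

from qspr.rbf import (
    RBFNetwork,
    RBFTrainConfig,
    greedy_trajectory,
    optimize_goal,
    rbf_predict,
    train_greedy,
)
from qspr.synthetic import SyntheticSpec, generate_rbf_qspr


def identity_net(centers, weights, bias=0.0, b=1.0, d=None):
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    d = d or centers.shape[1]
    return RBFNetwork(
        centers=centers,
        widths=np.full(len(centers), b),
        output_weights=np.asarray(weights, dtype=float),
        output_bias=bias,
        input_means=np.zeros(d),
        input_scales=np.ones(d),
    )


class TestPredict:
    def test_hand_built_single_neuron(self):
        # w=2, bias=1, b=1, mu=0 evaluated at x=1: 1 + 2 e^-1
        net = identity_net([[0.0]], [2.0], bias=1.0, b=1.0)
        assert rbf_predict(net, [[1.0]])[0] == pytest.approx(1 + 2 * np.exp(-1), rel=1e-12)

    def test_basis_is_one_at_center(self):
        net = identity_net([[0.3, -0.7]], [5.0], bias=0.0, b=2.0)
        assert rbf_predict(net, [[0.3, -0.7]])[0] == pytest.approx(5.0, rel=1e-12)

    def test_gaussian_tail_vanishes(self):
        net = identity_net([[0.0]], [5.0], bias=1.5, b=1.0)
        assert rbf_predict(net, [[100.0]])[0] == pytest.approx(1.5, abs=1e-12)

    def test_dimension_mismatch_rejected(self):
        net = identity_net([[0.0, 0.0]], [1.0])
        with pytest.raises(ValueError):
            rbf_predict(net, [[1.0]])


class TestTrainGreedy:
    def test_interpolation_limit(self, rng):
        X = rng.normal(size=(30, 3))
        y = rng.normal(size=30)
        cfg = RBFTrainConfig(goal=0.0, max_neuron_fraction=1.0, spread=1.0)
        net = train_greedy(X, y, cfg)
        assert np.mean((rbf_predict(net, X) - y) ** 2) < 1e-10

    def test_chosen_center_matches_exhaustive_refit_oracle(self, rng):
        """Every greedy step must pick the candidate whose full output-layer
        refit minimises training MSE (brute-force lstsq per candidate)."""
        n = 40
        X = rng.normal(size=(n, 2))
        y = np.sin(X[:, 0]) + 0.5 * X[:, 1] ** 2 + 0.1 * rng.normal(size=n)
        cfg = RBFTrainConfig(goal=1e-8, max_neuron_fraction=0.25, spread=1.5)
        traj = greedy_trajectory(X, y, cfg)
        Z, y_std, b = traj.Z, traj.y_std, traj.b
        K = np.exp(-(b**2) * np.sum((Z[:, None] - Z[None, :]) ** 2, axis=-1))
        used: list[int] = []
        for step, picked in enumerate(traj.chosen):
            best_mse, best_j = None, None
            for j in range(n):
                if j in used:
                    continue
                A = np.column_stack([np.ones(n), K[:, used + [j]]])
                beta, *_ = np.linalg.lstsq(A, y_std, rcond=None)
                mse = float(np.mean((y_std - A @ beta) ** 2))
                if best_mse is None or mse < best_mse - 1e-12:
                    best_mse, best_j = mse, j
            assert picked == best_j, f"step {step}"
            assert traj.mse_path[step + 1] == pytest.approx(best_mse, abs=1e-10)
            used.append(picked)

    def test_training_mse_non_increasing(self, rng):
        X = rng.normal(size=(50, 3))
        y = rng.normal(size=50)
        traj = greedy_trajectory(X, y, RBFTrainConfig(goal=0.0, max_neuron_fraction=1.0, spread=1.0))
        assert all(b <= a + 1e-12 for a, b in zip(traj.mse_path, traj.mse_path[1:]))

    def test_planted_three_center_zero_noise(self):
        spec = SyntheticSpec(
            n_compounds=80, n_descriptors=4, support=(0, 1, 2, 3),
            coefficients=(0, 0, 0, 0), noise_sd=0.0, seed=11,
        )
        m, y, truth = generate_rbf_qspr(spec)
        spread = truth["widths"][0] * np.sqrt(np.log(2.0))
        cfg = RBFTrainConfig(goal=1e-10, max_neuron_fraction=1.0, spread=float(spread))
        net = train_greedy(m.values, y, cfg)
        assert net.n_neurons <= 6
        assert np.mean((rbf_predict(net, m.values) - y) ** 2) <= 1e-8

    def test_degenerate_identical_inputs_rejected(self):
        X = np.ones((10, 2))
        with pytest.raises(ValueError, match="degenerate"):
            train_greedy(X, np.arange(10.0), RBFTrainConfig(spread=1.0))

    def test_neuron_cap_respected(self, rng):
        X = rng.normal(size=(40, 2))
        y = rng.normal(size=40)
        net = train_greedy(X, y, RBFTrainConfig(goal=0.0, max_neuron_fraction=0.30, spread=1.0))
        assert net.n_neurons <= int(np.ceil(0.30 * 40))


class TestOptimizeGoal:
    def test_single_goal_grid(self, rng):
        X = rng.normal(size=(30, 2))
        y = X[:, 0] + rng.normal(scale=0.1, size=30)
        Xv = rng.normal(size=(10, 2))
        yv = Xv[:, 0]
        cfg = RBFTrainConfig(goal_grid=[1e-2], spread=1.5)
        net, goal, report = optimize_goal(X, y, Xv, yv, cfg)
        assert goal == 1e-2
        assert len(report) == 1

    def test_chosen_net_attains_report_minimum(self, rng):
        X = rng.normal(size=(60, 2))
        y = np.sin(X[:, 0]) + rng.normal(scale=0.2, size=60)
        Xv = rng.normal(size=(30, 2))
        yv = np.sin(Xv[:, 0]) + rng.normal(scale=0.2, size=30)
        net, goal, report = optimize_goal(X, y, Xv, yv, RBFTrainConfig(spread=1.5))
        pred = rbf_predict(net, Xv)
        assert np.mean((pred - yv) ** 2) == pytest.approx(
            min(r["val_mse"] for r in report), rel=1e-9
        )

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            RBFTrainConfig(goal_grid=[])

    def test_goal_selection_guards_against_overfitting(self):
        """With noisy data the validation-tuned goal must beat the
        interpolating (goal -> 0) network nearly always."""
        wins = 0
        for seed in range(20):
            spec = SyntheticSpec(
                n_compounds=150, n_descriptors=3, support=(0, 1, 2),
                coefficients=(0, 0, 0), nonlinear_width=2.0, noise_sd=0.3, seed=seed,
            )
            m, y, truth = generate_rbf_qspr(spec)
            X = m.values
            idx = np.random.default_rng(seed).permutation(150)
            tr, va = idx[:100], idx[100:]
            spread = float(truth["widths"][0] * np.sqrt(np.log(2.0)))
            net, _, _ = optimize_goal(X[tr], y[tr], X[va], y[va], RBFTrainConfig(spread=spread))
            interp = train_greedy(
                X[tr], y[tr], RBFTrainConfig(goal=0.0, max_neuron_fraction=1.0, spread=spread)
            )
            v_opt = np.mean((rbf_predict(net, X[va]) - y[va]) ** 2)
            v_int = np.mean((rbf_predict(interp, X[va]) - y[va]) ** 2)
            wins += v_opt <= v_int
        assert wins >= 18


class TestInvariances:
    def test_affine_input_rescaling_absorbed(self, rng):
        X = rng.normal(size=(50, 3))
        y = np.cos(X[:, 0]) + rng.normal(scale=0.1, size=50)
        Xq = rng.normal(size=(20, 3))
        cfg = RBFTrainConfig(goal=1e-3, spread=1.5)
        net1 = train_greedy(X, y, cfg)
        scale = np.array([3.0, 0.2, 40.0])
        shift = np.array([-5.0, 100.0, 0.7])
        net2 = train_greedy(X * scale + shift, y, cfg)
        p1 = rbf_predict(net1, Xq)
        p2 = rbf_predict(net2, Xq * scale + shift)
        assert np.allclose(p1, p2, atol=1e-8)

    def test_median_spread_default_used_when_unset(self, rng):
        X = rng.normal(size=(30, 2))
        y = X[:, 0] ** 2 + 0.1 * rng.normal(size=30)
        traj = greedy_trajectory(X, y, RBFTrainConfig())
        from scipy.spatial.distance import pdist

        Z = (X - X.mean(0)) / X.std(0)
        expected = np.sqrt(np.log(2.0)) / np.median(pdist(Z))
        assert traj.b == pytest.approx(expected, rel=1e-12)
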