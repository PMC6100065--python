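"""Greedy radial-basis-function network regression.

The network is a Gaussian hidden layer plus a linear output layer:

    y(x) = bias + sum_j w_j * exp(-b_j^2 * ||z - mu_j||^2)

where z is the input standardized by the training mean/scale.  Training is
the classic greedy construction: starting from a bias-only model, every
unused training input is tried as the next center, the output layer is
refit by least squares with the candidate appended, and the candidate that
lowers the training mean-squared error the most is kept.  Neurons are added
until the MSE falls below a goal or a maximum neuron count (a fraction of
the training-set size, default 30%) is reached.

Because the greedy path does not depend on the goal, a whole goal grid is
scanned from a single construction run: the network for a given goal is the
prefix of the run at the first step whose MSE meets that goal.  The goal is
chosen to minimise the validation-set MSE, the usual guard against
overfitting the training data.

Inputs are z-scored on training statistics (Euclidean distances across
mixed-unit descriptors are meaningless otherwise) and the target is
standardized during training and de-standardized on output; the ``goal``
is therefore expressed in standardized-target units squared.  The shared
width is derived from a ``spread`` parameter as b = sqrt(ln 2)/spread, i.e.
the basis function falls to 0.5 at distance ``spread``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class RBFNetwork:
    """Trained network: centers live in standardized input space."""

    centers: np.ndarray  # (m, d)
    widths: np.ndarray  # b_j per neuron, usually all equal
    output_weights: np.ndarray  # (m,)
    output_bias: float
    input_means: np.ndarray
    input_scales: np.ndarray
    target_mean: float = 0.0
    target_scale: float = 1.0

    def __post_init__(self) -> None:
        self.input_means = np.asarray(self.input_means, dtype=float).ravel()
        self.input_scales = np.asarray(self.input_scales, dtype=float).ravel()
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if self.centers.size == 0:
            self.centers = self.centers.reshape(0, len(self.input_means))
        self.widths = np.asarray(self.widths, dtype=float).ravel()
        self.output_weights = np.asarray(self.output_weights, dtype=float).ravel()
        if len(self.widths) == 1 and len(self.output_weights) > 1:
            self.widths = np.full(len(self.output_weights), self.widths[0])
        if not (len(self.centers) == len(self.widths) == len(self.output_weights)):
            raise ValueError("centers, widths and output_weights must align")
        if np.any(self.widths <= 0):
            raise ValueError("widths must be positive")
        if np.any(self.input_scales <= 0):
            raise ValueError("input_scales must be positive")

    @property
    def n_neurons(self) -> int:
        return len(self.output_weights)


@dataclass
class RBFTrainConfig:
    """Greedy-training settings.

    ``goal`` is the training MSE stop threshold in standardized-target
    units squared; ``spread`` the distance at which a basis function falls
    to one half — ``None`` (default) selects the median pairwise distance
    of the standardized training inputs, the usual kernel-width heuristic,
    which adapts the width to the input dimension; ``max_neuron_fraction``
    caps the hidden layer at ceil(fraction * n_train) neurons (default 30%
    as is conventional for this construction); ``goal_grid`` is the list of
    goals scanned by :func:`optimize_goal` (default: 12 log-spaced values
    in [1e-4, 1] times the standardized-target variance)."""

    goal: float = 1e-3
    spread: float | None = None
    max_neuron_fraction: float = 0.30
    goal_grid: list[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.goal < 0:
            raise ValueError("goal must be >= 0")
        if self.spread is not None and self.spread <= 0:
            raise ValueError("spread must be positive")
        if not 0 < self.max_neuron_fraction <= 1:
            raise ValueError("max_neuron_fraction must be in (0, 1]")
        if self.goal_grid is not None and len(self.goal_grid) == 0:
            raise ValueError("goal_grid must be nonempty")


def _basis(net_or_b, Z: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Gaussian design matrix exp(-b^2 ||z - mu||^2), rows = samples."""
    b = np.asarray(net_or_b, dtype=float).ravel()
    d2 = np.sum((Z[:, None, :] - centers[None, :, :]) ** 2, axis=-1)
    return np.exp(-(b**2)[None, :] * d2)


def rbf_predict(net: RBFNetwork, X: np.ndarray) -> np.ndarray:
    """Evaluate the network on raw (unstandardized) inputs."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != net.centers.shape[1]:
        raise ValueError(
            f"input has {X.shape[1]} columns but centers have {net.centers.shape[1]}"
        )
    Z = (X - net.input_means) / net.input_scales
    G = _basis(net.widths, Z, net.centers)
    y_std = net.output_bias + G @ net.output_weights
    return net.target_mean + net.target_scale * y_std


@dataclass
class GreedyTrajectory:
    """One greedy construction run: chosen training-row indices in order,
    the training MSE after each addition (standardized units), and the
    standardization constants needed to cut prefix networks."""

    chosen: list[int]
    mse_path: list[float]  # mse_path[k] = MSE with k neurons; [0] = bias-only
    Z: np.ndarray
    y_std: np.ndarray
    b: float
    input_means: np.ndarray
    input_scales: np.ndarray
    target_mean: float
    target_scale: float

    def network(self, n_neurons: int) -> RBFNetwork:
        """Refit the output layer for the first ``n_neurons`` centers."""
        idx = self.chosen[:n_neurons]
        centers = self.Z[idx]  # (k, d), possibly k = 0
        G = _basis(np.full(len(idx), self.b), self.Z, centers)
        A = np.column_stack([np.ones(len(self.Z)), G])
        beta, *_ = np.linalg.lstsq(A, self.y_std, rcond=None)
        return RBFNetwork(
            centers=centers,
            widths=np.full(len(idx), self.b),
            output_weights=beta[1:],
            output_bias=float(beta[0]),
            input_means=self.input_means,
            input_scales=self.input_scales,
            target_mean=self.target_mean,
            target_scale=self.target_scale,
        )


def _standardize(Xtr: np.ndarray, ytr: np.ndarray):
    Xtr = np.atleast_2d(np.asarray(Xtr, dtype=float))
    ytr = np.asarray(ytr, dtype=float).ravel()
    means = Xtr.mean(axis=0)
    scales = Xtr.std(axis=0, ddof=0)
    if np.all(scales <= 0):
        raise ValueError("degenerate training inputs: all rows identical")
    scales = np.where(scales > 0, scales, 1.0)
    y_mean = float(ytr.mean())
    y_scale = float(ytr.std(ddof=0))
    if y_scale <= 0:
        y_scale = 1.0
    return (Xtr - means) / scales, (ytr - y_mean) / y_scale, means, scales, y_mean, y_scale


def greedy_trajectory(Xtr: np.ndarray, ytr: np.ndarray, cfg: RBFTrainConfig) -> GreedyTrajectory:
    """Run the greedy construction to the neuron cap (or exact fit).

    At each step the candidate center is the training input whose inclusion
    minimises the refit training MSE; the exhaustive refit over candidates
    is evaluated through an orthonormal-basis update, which is algebraically
    identical to refitting the output layer per candidate.  Ties break by
    training-row order.
    """
    Z, y_std, means, scales, y_mean, y_scale = _standardize(Xtr, ytr)
    n = len(Z)
    if n < 2:
        raise ValueError("need at least 2 training points")
    spread = cfg.spread
    if spread is None:
        from scipy.spatial.distance import pdist

        spread = float(np.median(pdist(Z)))
        if spread <= 0:
            raise ValueError("degenerate training inputs: zero median pairwise distance")
    b = np.sqrt(np.log(2.0)) / spread
    max_neurons = int(np.ceil(cfg.max_neuron_fraction * n))

    K = _basis(np.full(n, b), Z, Z)  # all-candidates kernel, n x n
    Q = np.ones((n, 1)) / np.sqrt(n)  # orthonormal basis of current design
    r = y_std - Q @ (Q.T @ y_std)
    chosen: list[int] = []
    mse_path = [float(r @ r) / n]
    available = np.ones(n, dtype=bool)

    for _ in range(max_neurons):
        U = K - Q @ (Q.T @ K)  # residual parts of every candidate column
        norms2 = np.sum(U**2, axis=0)
        proj = r @ K  # equals r.T U because r is orthogonal to Q
        with np.errstate(divide="ignore", invalid="ignore"):
            gain = np.where(norms2 > 1e-12, proj**2 / norms2, -np.inf)
        gain[~available] = -np.inf
        best = int(np.argmax(gain))
        if not np.isfinite(gain[best]) or gain[best] <= 0:
            break
        u = U[:, best]
        u = u / np.linalg.norm(u)
        Q = np.column_stack([Q, u])
        r = r - u * (u @ r)
        chosen.append(best)
        available[best] = False
        mse_path.append(float(r @ r) / n)
        if mse_path[-1] < 1e-15:
            break

    return GreedyTrajectory(
        chosen=chosen,
        mse_path=mse_path,
        Z=Z,
        y_std=y_std,
        b=float(b),
        input_means=means,
        input_scales=scales,
        target_mean=y_mean,
        target_scale=y_scale,
    )


def _neurons_for_goal(traj: GreedyTrajectory, goal: float) -> int:
    for k, mse in enumerate(traj.mse_path):
        if mse <= goal:
            return k
    return len(traj.chosen)


def train_greedy(Xtr: np.ndarray, ytr: np.ndarray, cfg: RBFTrainConfig | None = None) -> RBFNetwork:
    """Greedy construction stopped at ``cfg.goal`` or the neuron cap."""
    cfg = cfg or RBFTrainConfig()
    traj = greedy_trajectory(Xtr, ytr, cfg)
    return traj.network(_neurons_for_goal(traj, cfg.goal))


def default_goal_grid(ytr_std_var: float = 1.0, n_points: int = 12) -> list[float]:
    """Log-spaced goals spanning [1e-4, 1] x the standardized-target variance."""
    return list(ytr_std_var * np.logspace(-4, 0, n_points))


def optimize_goal(
    Xtr: np.ndarray,
    ytr: np.ndarray,
    Xval: np.ndarray,
    yval: np.ndarray,
    cfg: RBFTrainConfig | None = None,
) -> tuple[RBFNetwork, float, list[dict]]:
    """Scan the goal grid and keep the network with the lowest validation MSE.

    Returns (best network, chosen goal, report); the report has one row per
    grid point with goal, n_neurons, train MSE and validation MSE (the MSEs
    in property units).  Ties prefer the larger goal (fewer neurons).
    """
    cfg = cfg or RBFTrainConfig()
    grid = cfg.goal_grid if cfg.goal_grid is not None else default_goal_grid()
    if not grid:
        raise ValueError("goal_grid must be nonempty")
    yval = np.asarray(yval, dtype=float).ravel()
    traj = greedy_trajectory(Xtr, ytr, cfg)

    report = []
    best = None
    for goal in sorted(grid, reverse=True):
        k = _neurons_for_goal(traj, goal)
        net = traj.network(k)
        pred_tr = rbf_predict(net, Xtr)
        pred_val = rbf_predict(net, Xval)
        train_mse = float(np.mean((pred_tr - np.asarray(ytr, dtype=float).ravel()) ** 2))
        val_mse = float(np.mean((pred_val - yval) ** 2))
        report.append(
            {"goal": float(goal), "n_neurons": k, "train_mse": train_mse, "val_mse": val_mse}
        )
        if best is None or val_mse < best[2]:
            best = (net, float(goal), val_mse)
    net, chosen_goal, _ = best
    return net, chosen_goal, report
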