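"""Levenberg-Marquardt training of a single-hidden-layer trajectory surrogate.

The surrogate maps time ``t`` to the five compartment values through one
hidden layer of log-sigmoid units and a linear output layer:

    y_hat(t) = W_out . logsig(w_in t + b_h) + b_out

Inputs and each output channel are min-max scaled to [-1, 1] before training.
Training minimises the sum of squared residuals on a randomly chosen training
subset with the Levenberg-Marquardt update ``(J'J + mu I) step = -J'e``; the
damping ``mu`` shrinks after accepted steps and grows after rejected ones.
Early stopping watches a validation subset: six consecutive epochs whose
validation MSE fails to improve on the previous epoch end the run, and the
weights returned are those of the epoch with the smallest validation MSE.

Caputo trajectories carry a ``t^alpha`` boundary layer at the origin, so the
default initialization places half of the hidden-unit transitions
geometrically close to the start of the time window with correspondingly
sharp slopes (:func:`initialize_weights_boundary_layer`); the classical
Nguyen-Widrow layout remains available via ``TrainingConfig.init_scheme``.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg

__all__ = [
    "NetworkWeights",
    "ScalingSpec",
    "TrainingConfig",
    "SplitIndices",
    "TrainingRecord",
    "initialize_weights",
    "initialize_weights_boundary_layer",
    "split_data",
    "forward",
    "jacobian",
    "train_lm",
    "predict",
    "save_model",
    "load_model",
]

_N_OUT = 5


@dataclass(frozen=True)
class NetworkWeights:
    """Parameters of the 1 -> H -> 5 feed-forward network."""

    input_weights: np.ndarray  # (H,)
    hidden_biases: np.ndarray  # (H,)
    output_weights: np.ndarray  # (5, H)
    output_biases: np.ndarray  # (5,)

    def __post_init__(self) -> None:
        iw = np.asarray(self.input_weights, dtype=float).ravel()
        hb = np.asarray(self.hidden_biases, dtype=float).ravel()
        ow = np.asarray(self.output_weights, dtype=float)
        ob = np.asarray(self.output_biases, dtype=float).ravel()
        H = iw.size
        if H < 1:
            raise ValueError("network needs at least one hidden unit")
        if hb.size != H or ow.shape != (_N_OUT, H) or ob.size != _N_OUT:
            raise ValueError(
                f"inconsistent weight shapes: iw {iw.shape}, hb {hb.shape}, "
                f"ow {ow.shape}, ob {ob.shape}"
            )
        for name, arr in (("input_weights", iw), ("hidden_biases", hb),
                          ("output_weights", ow), ("output_biases", ob)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in {name}")
        object.__setattr__(self, "input_weights", iw)
        object.__setattr__(self, "hidden_biases", hb)
        object.__setattr__(self, "output_weights", ow)
        object.__setattr__(self, "output_biases", ob)

    @property
    def n_hidden(self) -> int:
        return self.input_weights.size

    @property
    def n_parameters(self) -> int:
        return 2 * self.n_hidden + _N_OUT * self.n_hidden + _N_OUT

    def to_vector(self) -> np.ndarray:
        return np.concatenate([
            self.input_weights,
            self.hidden_biases,
            self.output_weights.ravel(),
            self.output_biases,
        ])

    @classmethod
    def from_vector(cls, theta: np.ndarray, n_hidden: int) -> "NetworkWeights":
        H = n_hidden
        theta = np.asarray(theta, dtype=float)
        if theta.size != 2 * H + _N_OUT * H + _N_OUT:
            raise ValueError("parameter vector has the wrong length")
        return cls(
            input_weights=theta[:H].copy(),
            hidden_biases=theta[H : 2 * H].copy(),
            output_weights=theta[2 * H : 2 * H + _N_OUT * H].reshape(_N_OUT, H).copy(),
            output_biases=theta[2 * H + _N_OUT * H :].copy(),
        )

    def to_dict(self) -> dict:
        return {
            "input_weights": self.input_weights.tolist(),
            "hidden_biases": self.hidden_biases.tolist(),
            "output_weights": self.output_weights.tolist(),
            "output_biases": self.output_biases.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkWeights":
        return cls(
            input_weights=np.array(d["input_weights"]),
            hidden_biases=np.array(d["hidden_biases"]),
            output_weights=np.array(d["output_weights"]),
            output_biases=np.array(d["output_biases"]),
        )


@dataclass(frozen=True)
class ScalingSpec:
    """Per-channel linear maps onto [-1, 1] for the input and the 5 outputs.

    A channel with zero observed range (constant targets) falls back to a
    unit-width map so that scaling stays invertible; the constant maps to -1.
    """

    t_min: float
    t_max: float
    y_min: np.ndarray  # (5,)
    y_max: np.ndarray  # (5,)

    def __post_init__(self) -> None:
        y_min = np.asarray(self.y_min, dtype=float).ravel()
        y_max = np.asarray(self.y_max, dtype=float).ravel()
        object.__setattr__(self, "y_min", y_min)
        object.__setattr__(self, "y_max", y_max)
        if not self.t_max > self.t_min:
            raise ValueError("input channel has zero range")
        if y_min.size != _N_OUT or y_max.size != _N_OUT:
            raise ValueError("expected 5 output channels")
        if np.any(y_max < y_min):
            raise ValueError("channel maxima below minima")

    @classmethod
    def fit(cls, t: np.ndarray, y: np.ndarray) -> "ScalingSpec":
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        return cls(
            t_min=float(t.min()),
            t_max=float(t.max()),
            y_min=y.min(axis=0),
            y_max=y.max(axis=0),
        )

    @property
    def _y_range(self) -> np.ndarray:
        r = self.y_max - self.y_min
        return np.where(r > 0, r, 1.0)

    def scale_t(self, t: np.ndarray) -> np.ndarray:
        return 2.0 * (np.asarray(t, dtype=float) - self.t_min) / (self.t_max - self.t_min) - 1.0

    def scale_y(self, y: np.ndarray) -> np.ndarray:
        return 2.0 * (np.asarray(y, dtype=float) - self.y_min) / self._y_range - 1.0

    def unscale_y(self, y_scaled: np.ndarray) -> np.ndarray:
        return (np.asarray(y_scaled, dtype=float) + 1.0) * self._y_range / 2.0 + self.y_min

    def to_dict(self) -> dict:
        return {
            "t_min": self.t_min,
            "t_max": self.t_max,
            "y_min": self.y_min.tolist(),
            "y_max": self.y_max.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingSpec":
        return cls(t_min=d["t_min"], t_max=d["t_max"],
                   y_min=np.array(d["y_min"]), y_max=np.array(d["y_max"]))


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the LM training protocol.

    The defaults are the standard fitting-toolbox constants: 15 hidden units,
    at most 1000 epochs, an MSE goal of 0, minimum gradient 1e-7, damping
    multiplied by 10 on rejection and 0.1 on acceptance up to a ceiling of
    1e10, six validation failures to stop, an 82/9/9 random data division,
    and an initial damping (the "adaptive parameter") of 7e-5.
    """

    hidden_units: int = 15
    max_epochs: int = 1000
    mse_goal: float = 0.0
    min_gradient: float = 1e-7
    mu_initial: float = 7e-5
    mu_increase: float = 10.0
    mu_decrease: float = 0.1
    mu_max: float = 1e10
    max_validation_failures: int = 6
    split_fractions: tuple[float, float, float] = (0.82, 0.09, 0.09)
    seed: int = 0
    n_restarts: int = 1
    #: "boundary-layer" (default) or "nguyen-widrow"
    init_scheme: str = "boundary-layer"
    #: report/monitor MSE in the scaled [-1, 1] space instead of original units
    scaled_space_mse: bool = False

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be >= 0")
        if not math.isclose(sum(self.split_fractions), 1.0, abs_tol=1e-9):
            raise ValueError("split fractions must sum to 1")
        if not (self.mu_increase > 1.0 > self.mu_decrease > 0.0):
            raise ValueError("need mu_increase > 1 > mu_decrease > 0")
        if not (self.mu_max > self.mu_initial > 0.0):
            raise ValueError("need mu_max > mu_initial > 0")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.init_scheme not in ("boundary-layer", "nguyen-widrow"):
            raise ValueError(f"unknown init_scheme {self.init_scheme!r}")

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: getattr(self, k) for k in type(self).__dataclass_fields__},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass(frozen=True)
class SplitIndices:
    """Disjoint training/validation/test index sets covering the dataset."""

    training: np.ndarray
    validation: np.ndarray
    test: np.ndarray

    def __post_init__(self) -> None:
        tr = np.asarray(self.training, dtype=int)
        va = np.asarray(self.validation, dtype=int)
        te = np.asarray(self.test, dtype=int)
        object.__setattr__(self, "training", tr)
        object.__setattr__(self, "validation", va)
        object.__setattr__(self, "test", te)
        n = tr.size + va.size + te.size
        combined = np.concatenate([tr, va, te])
        if not np.array_equal(np.sort(combined), np.arange(n)):
            raise ValueError("split index sets must be disjoint and cover 0..n-1")

    @property
    def n_points(self) -> int:
        return self.training.size + self.validation.size + self.test.size


@dataclass
class TrainingRecord:
    """Per-epoch history of one LM training run.

    Epoch 0 is the initial (untrained) network.  MSE traces are stored both
    in original units and in the scaled training space; the accept/reject
    rule acts on the scaled training SSE, so ``train_mse_scaled`` is
    non-increasing over epochs by construction.  ``best_epoch`` is the epoch
    with the smallest monitored validation MSE (earliest on ties);
    ``stop_reason`` is one of ``epochs``, ``goal``, ``min_gradient``,
    ``mu_max``, ``validation_failures``.
    """

    train_mse: list[float] = field(default_factory=list)
    validation_mse: list[float] = field(default_factory=list)
    test_mse: list[float] = field(default_factory=list)
    train_mse_scaled: list[float] = field(default_factory=list)
    gradient: list[float] = field(default_factory=list)
    mu: list[float] = field(default_factory=list)
    stop_reason: str | None = None
    best_epoch: int = 0
    restart_index: int = 0
    #: best validation MSE of every restart (winner selection trace)
    restart_validation_mse: list[float] = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        """Number of LM epochs run (excluding the epoch-0 baseline)."""
        return max(len(self.train_mse) - 1, 0)

    @property
    def best_validation_mse(self) -> float:
        return self.validation_mse[self.best_epoch]

    def to_dict(self) -> dict:
        return {
            "train_mse": self.train_mse,
            "validation_mse": self.validation_mse,
            "test_mse": self.test_mse,
            "train_mse_scaled": self.train_mse_scaled,
            "gradient": self.gradient,
            "mu": self.mu,
            "stop_reason": self.stop_reason,
            "best_epoch": self.best_epoch,
            "restart_index": self.restart_index,
            "restart_validation_mse": self.restart_validation_mse,
        }


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def initialize_weights(n_hidden: int, seed: int | np.random.Generator) -> NetworkWeights:
    """Nguyen-Widrow initialization for inputs scaled to [-1, 1].

    Input-layer weight magnitudes are the Nguyen-Widrow scale
    ``0.7 * H^(1/n_in)`` (here ``n_in = 1``) with random signs, and hidden
    biases spread the sigmoid transition centers uniformly over the input
    range.  Output-layer weights start small and uniform.
    """
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")
    rng = _as_rng(seed)
    scale = 0.7 * float(n_hidden) ** 1.0  # n_in = 1
    signs = rng.choice([-1.0, 1.0], size=n_hidden)
    iw = scale * signs
    centers = rng.uniform(-1.0, 1.0, size=n_hidden)
    hb = -iw * centers  # transition at t = center
    ow = rng.uniform(-0.5, 0.5, size=(_N_OUT, n_hidden))
    ob = rng.uniform(-0.1, 0.1, size=_N_OUT)
    return NetworkWeights(iw, hb, ow, ob)


def initialize_weights_boundary_layer(
    n_hidden: int, seed: int | np.random.Generator
) -> NetworkWeights:
    """Initialization adapted to the power-law boundary layer of Caputo flows.

    Solutions of ``D^alpha y = f(y)`` with ``alpha < 1`` behave like
    ``y0 + c t^alpha`` near ``t = 0``: an unbounded derivative concentrated
    at the start of the window.  Half the hidden units follow the
    Nguyen-Widrow layout (uniform transition centers over the scaled input
    range); the other half place their transition centers geometrically
    close to the window start (physical offsets spanning roughly 1e-3 to 0.2
    of the window) with slopes inversely proportional to that offset, so the
    network starts with resolving power where the trajectory is steepest.
    """
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")
    rng = _as_rng(seed)
    n_uniform = n_hidden // 2
    n_layer = n_hidden - n_uniform

    scale = 0.7 * float(n_hidden)
    signs = rng.choice([-1.0, 1.0], size=n_uniform)
    iw_u = scale * signs
    hb_u = -iw_u * rng.uniform(-1.0, 1.0, size=n_uniform)

    # fractional offsets of the window, log-uniform; scaled center = 2 c - 1
    offsets = 10.0 ** rng.uniform(-3.0, -0.7, size=n_layer)
    slopes = np.clip(
        (2.0 / (offsets + 1e-3)) * rng.uniform(0.5, 1.5, size=n_layer), 2.0, 2000.0
    ) * rng.choice([-1.0, 1.0], size=n_layer)
    iw_c = slopes
    hb_c = -iw_c * (2.0 * offsets - 1.0)

    iw = np.concatenate([iw_u, iw_c])
    hb = np.concatenate([hb_u, hb_c])
    ow = rng.uniform(-0.5, 0.5, size=(_N_OUT, n_hidden))
    ob = rng.uniform(-0.1, 0.1, size=_N_OUT)
    return NetworkWeights(iw, hb, ow, ob)


_INITIALIZERS = {
    "nguyen-widrow": initialize_weights,
    "boundary-layer": initialize_weights_boundary_layer,
}


def split_data(n_points: int, config: TrainingConfig) -> SplitIndices:
    """Random disjoint train/validation/test assignment of dataset indices.

    Validation and test sizes are ``round(f * n)`` for their fractions; the
    training set takes the remainder.  Reproducible from ``config.seed``.
    """
    if n_points < 12:
        raise ValueError(f"need at least 12 points to split, got {n_points}")
    _, f_val, f_test = config.split_fractions
    n_val = round(f_val * n_points)
    n_test = round(f_test * n_points)
    n_train = n_points - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(
            f"split of {n_points} points by {config.split_fractions} leaves an empty subset"
        )
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(n_points)
    return SplitIndices(
        training=np.sort(perm[:n_train]),
        validation=np.sort(perm[n_train : n_train + n_val]),
        test=np.sort(perm[n_train + n_val :]),
    )


def _logsig(x: np.ndarray) -> np.ndarray:
    # numerically safe log-sigmoid
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def forward(weights: NetworkWeights, inputs) -> np.ndarray:
    """Evaluate the network on scaled inputs; returns an ``(N, 5)`` array."""
    t = np.atleast_1d(np.asarray(inputs, dtype=float))
    hidden = _logsig(np.outer(t, weights.input_weights) + weights.hidden_biases)
    return hidden @ weights.output_weights.T + weights.output_biases


def jacobian(
    weights: NetworkWeights, inputs, targets
) -> tuple[np.ndarray, np.ndarray]:
    """Residuals and their analytic Jacobian with respect to all weights.

    Residuals are ``e = y_hat - y`` stacked sample-major (row ``i * 5 + c``
    for sample ``i``, channel ``c``); the Jacobian columns follow the
    parameter-vector order of :meth:`NetworkWeights.to_vector`.
    """
    t = np.atleast_1d(np.asarray(inputs, dtype=float))
    y = np.asarray(targets, dtype=float)
    if t.size == 0:
        raise ValueError("empty dataset")
    if y.shape != (t.size, _N_OUT):
        raise ValueError(f"targets must have shape ({t.size}, {_N_OUT}), got {y.shape}")

    H = weights.n_hidden
    N = t.size
    A = _logsig(np.outer(t, weights.input_weights) + weights.hidden_biases)  # (N, H)
    Aprime = A * (1.0 - A)
    pred = A @ weights.output_weights.T + weights.output_biases
    e = (pred - y).ravel()

    P = weights.n_parameters
    J = np.zeros((N * _N_OUT, P))
    # d y_c / d w_in_k = W_out[c,k] A'[i,k] t_i ; d y_c / d b_h_k drops t_i
    g = Aprime[:, None, :] * weights.output_weights[None, :, :]  # (N, 5, H)
    J[:, :H] = (g * t[:, None, None]).reshape(N * _N_OUT, H)
    J[:, H : 2 * H] = g.reshape(N * _N_OUT, H)
    # output weights: block-diagonal in the channel index
    rows = np.arange(N * _N_OUT)
    c_idx = rows % _N_OUT
    i_idx = rows // _N_OUT
    col0 = 2 * H
    for c in range(_N_OUT):
        sel = c_idx == c
        J[np.ix_(sel, range(col0 + c * H, col0 + (c + 1) * H))] = A[i_idx[sel]]
    J[rows, 2 * H + _N_OUT * H + c_idx] = 1.0
    return e, J


def _lm_step(JtJ: np.ndarray, Jte: np.ndarray, mu: float) -> np.ndarray | None:
    A = JtJ + mu * np.eye(Jte.size)
    try:
        cho = scipy.linalg.cho_factor(A, check_finite=False)
        step = scipy.linalg.cho_solve(cho, -Jte, check_finite=False)
    except scipy.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(step)):
        return None
    return step


def _train_single(
    t_scaled: np.ndarray,
    y_scaled: np.ndarray,
    scaling: ScalingSpec,
    split: SplitIndices,
    config: TrainingConfig,
    seed: int,
    initial_weights: NetworkWeights | None = None,
) -> tuple[NetworkWeights, TrainingRecord]:
    rng = np.random.default_rng(seed)
    if initial_weights is None:
        weights = _INITIALIZERS[config.init_scheme](config.hidden_units, rng)
    else:
        if initial_weights.n_hidden != config.hidden_units:
            raise ValueError("initial_weights hidden count does not match config")
        weights = initial_weights
    theta = weights.to_vector()
    H = config.hidden_units

    t_tr = t_scaled[split.training]
    y_tr = y_scaled[split.training]

    def subset_mse(w: NetworkWeights, idx: np.ndarray) -> float:
        if idx.size == 0:
            return float("nan")
        pred = forward(w, t_scaled[idx])
        if config.scaled_space_mse:
            resid = pred - y_scaled[idx]
        else:
            resid = scaling.unscale_y(pred) - scaling.unscale_y(y_scaled[idx])
        return float(np.mean(resid**2))

    record = TrainingRecord()
    mu = config.mu_initial

    e, J = jacobian(weights, t_tr, y_tr)
    sse = float(e @ e)
    grad_inf = float(np.max(np.abs(2.0 * (J.T @ e))))

    def log_epoch(w: NetworkWeights) -> tuple[float, float]:
        m_tr = subset_mse(w, split.training)
        m_val = subset_mse(w, split.validation)
        record.train_mse.append(m_tr)
        record.validation_mse.append(m_val)
        record.test_mse.append(subset_mse(w, split.test))
        record.train_mse_scaled.append(sse / e.size)
        record.gradient.append(grad_inf)
        record.mu.append(mu)
        return m_tr, m_val

    m_tr, m_val = log_epoch(weights)
    best_val = m_val
    best_epoch = 0
    best_theta = theta.copy()
    prev_val = m_val
    val_failures = 0
    epoch = 0
    stop: str | None = "epochs" if config.max_epochs == 0 else None

    while stop is None:
        if m_tr <= config.mse_goal:
            stop = "goal"
            break
        if grad_inf < config.min_gradient:
            stop = "min_gradient"
            break

        # one LM epoch: escalate mu until a step reduces the training SSE
        JtJ = J.T @ J
        Jte = J.T @ e
        accepted = False
        while mu <= config.mu_max:
            step = _lm_step(JtJ, Jte, mu)
            if step is not None:
                theta_new = theta + step
                w_new = NetworkWeights.from_vector(theta_new, H)
                e_new = (forward(w_new, t_tr) - y_tr).ravel()
                sse_new = float(e_new @ e_new)
                if sse_new < sse:
                    theta, weights = theta_new, w_new
                    mu = max(mu * config.mu_decrease, 1e-20)
                    accepted = True
                    break
            mu *= config.mu_increase
        if not accepted:
            stop = "mu_max"
            break

        epoch += 1
        e, J = jacobian(weights, t_tr, y_tr)
        sse = float(e @ e)
        grad_inf = float(np.max(np.abs(2.0 * (J.T @ e))))
        m_tr, m_val = log_epoch(weights)

        if m_val < best_val:
            best_val = m_val
            best_epoch = epoch
            best_theta = theta.copy()
        # failure = no improvement on the previous epoch; reset on improvement
        if m_val < prev_val:
            val_failures = 0
        else:
            val_failures += 1
            if val_failures >= config.max_validation_failures:
                stop = "validation_failures"
        prev_val = m_val

        if stop is None and epoch >= config.max_epochs:
            stop = "epochs"

    record.stop_reason = stop
    record.best_epoch = best_epoch
    return NetworkWeights.from_vector(best_theta, H), record


def train_lm(
    dataset: tuple[np.ndarray, np.ndarray],
    split: SplitIndices,
    config: TrainingConfig,
    seed: int | None = None,
    initial_weights: NetworkWeights | None = None,
) -> tuple[NetworkWeights, ScalingSpec, TrainingRecord]:
    """Train the surrogate with Levenberg-Marquardt and early stopping.

    Parameters
    ----------
    dataset
        ``(times, targets)`` with ``times`` of shape ``(N,)`` and ``targets``
        of shape ``(N, 5)`` in original units.
    split
        Train/validation/test division over the ``N`` points.
    config
        Protocol constants; ``config.n_restarts`` independent initializations
        are trained and the restart with the smallest validation MSE wins.
    seed
        Base seed for the weight initializations (defaults to
        ``config.seed``); restart ``r`` uses ``seed + r``.
    initial_weights
        Optional warm start: every restart begins from these weights instead
        of a random initialization (mainly useful with ``n_restarts = 1``).

    Returns
    -------
    (weights, scaling, record)
        Winning weights (those of the best-validation epoch of the winning
        restart), the scaling fitted on the full dataset, and that restart's
        :class:`TrainingRecord` with the per-restart validation trace
        attached.
    """
    t, y = dataset
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.ndim != 1 or y.shape != (t.size, _N_OUT):
        raise ValueError(
            f"dataset must be (times (N,), targets (N, 5)); got {t.shape} and {y.shape}"
        )
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
        raise ValueError("dataset contains non-finite values")
    if split.n_points != t.size:
        raise ValueError("split does not cover the dataset")
    if seed is None:
        seed = config.seed

    scaling = ScalingSpec.fit(t, y)
    t_scaled = scaling.scale_t(t)
    y_scaled = scaling.scale_y(y)

    results: list[tuple[NetworkWeights, TrainingRecord]] = []
    for r in range(config.n_restarts):
        w, rec = _train_single(
            t_scaled, y_scaled, scaling, split, config, seed + r, initial_weights
        )
        rec.restart_index = r
        results.append((w, rec))

    val_scores = [rec.best_validation_mse for _, rec in results]
    winner = int(np.argmin(val_scores))
    weights, record = results[winner]
    record.restart_validation_mse = [float(v) for v in val_scores]
    return weights, scaling, record


def predict(weights: NetworkWeights, scaling: ScalingSpec, times) -> np.ndarray:
    """Evaluate the trained surrogate at unscaled times, in original units."""
    return scaling.unscale_y(forward(weights, scaling.scale_t(times)))


def save_model(path: str | Path, weights: NetworkWeights, scaling: ScalingSpec,
               config: TrainingConfig) -> None:
    """Serialize weights + scaling + a hash of the training config to JSON."""
    payload = {
        "weights": weights.to_dict(),
        "scaling": scaling.to_dict(),
        "config_hash": config.config_hash(),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_model(path: str | Path) -> tuple[NetworkWeights, ScalingSpec]:
    payload = json.loads(Path(path).read_text())
    return (
        NetworkWeights.from_dict(payload["weights"]),
        ScalingSpec.from_dict(payload["scaling"]),
    )
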