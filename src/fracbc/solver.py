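"""Fractional Adams-Bashforth-Moulton (PECE) solver and its oracles.

Solves Caputo initial-value problems ``D^alpha y = f(y)``, ``y(0) = y0`` on a
uniform grid with the predictor-corrector scheme: a fractional rectangle-rule
(Adams-Bashforth) predictor followed by one fractional trapezoid-rule
(Adams-Moulton) corrector evaluation per step.  At ``alpha = 1`` the scheme
degenerates to an explicit trapezoidal (Heun-type) predictor-corrector, which
:func:`solve_classical` implements directly as the integer-order reference.

The full quadrature history is kept at every step (O(N^2) work overall); no
short-memory truncation is applied.  :func:`mittag_leffler` provides the
analytic solution of the linear test equation for validation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping

import mpmath
import numpy as np
import pandas as pd

from .model import STATE_NAMES

__all__ = [
    "TimeGrid",
    "Trajectory",
    "SolverBlowUpError",
    "predictor_weights",
    "corrector_weights",
    "solve_caputo",
    "solve_classical",
    "mittag_leffler",
]


class SolverBlowUpError(RuntimeError):
    """A non-finite state was produced during integration."""

    def __init__(self, step: int, stage: str):
        self.step = step
        self.stage = stage
        super().__init__(
            f"non-finite state at step {step} ({stage}); the trajectory has blown up"
        )


@dataclass(frozen=True)
class TimeGrid:
    """Uniform grid ``t_j = t0 + j h`` with ``n_steps + 1`` nodes."""

    t0: float = 0.0
    h: float = 0.01
    n_steps: int = 100

    def __post_init__(self) -> None:
        if not (math.isfinite(self.h) and self.h > 0):
            raise ValueError(f"step h must be finite and > 0, got {self.h!r}")
        if self.n_steps < 1:
            raise ValueError(f"n_steps must be >= 1, got {self.n_steps!r}")

    @property
    def t_end(self) -> float:
        return self.t0 + self.h * self.n_steps

    @property
    def nodes(self) -> np.ndarray:
        return self.t0 + self.h * np.arange(self.n_steps + 1)

    @classmethod
    def from_span(cls, t_end: float, h: float, t0: float = 0.0) -> "TimeGrid":
        """Grid covering ``[t0, t_end]``; the span must be a whole number of steps."""
        n = (t_end - t0) / h
        n_round = round(n)
        if n_round < 1 or abs(n - n_round) > 1e-9 * max(1.0, abs(n)):
            raise ValueError(f"span [{t0}, {t_end}] is not a whole number of steps of {h}")
        return cls(t0=t0, h=h, n_steps=n_round)


@dataclass(frozen=True)
class Trajectory:
    """Solution samples on a :class:`TimeGrid`, one state row per node."""

    grid: TimeGrid
    states: np.ndarray  # (n_steps + 1, n_dim)

    def __post_init__(self) -> None:
        states = np.atleast_2d(np.asarray(self.states, dtype=float))
        object.__setattr__(self, "states", states)
        if states.shape[0] != self.grid.n_steps + 1:
            raise ValueError(
                f"expected {self.grid.n_steps + 1} state rows, got {states.shape[0]}"
            )
        if not np.all(np.isfinite(states)):
            raise ValueError("trajectory contains non-finite values")

    @property
    def t(self) -> np.ndarray:
        return self.grid.nodes

    def to_frame(self) -> pd.DataFrame:
        names = STATE_NAMES if self.states.shape[1] == 5 else [
            f"y{i}" for i in range(self.states.shape[1])
        ]
        frame = pd.DataFrame(self.states, columns=list(names))
        frame.insert(0, "t", self.t)
        return frame

    def write_csv(self, path: str | Path, metadata: Mapping | None = None) -> None:
        """Write ``t,C,T,H,I,E`` CSV; metadata goes to a JSON sidecar."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        if metadata is not None:
            sidecar = path.with_suffix(path.suffix + ".meta.json")
            sidecar.write_text(json.dumps(dict(metadata), indent=2, sort_keys=True))

    @classmethod
    def read_csv(cls, path: str | Path) -> "Trajectory":
        frame = pd.read_csv(path)
        t = frame["t"].to_numpy()
        if len(t) < 2:
            raise ValueError("trajectory CSV needs at least two rows")
        h = t[1] - t[0]
        if not np.allclose(np.diff(t), h, rtol=1e-9, atol=1e-12):
            raise ValueError("trajectory CSV grid is not uniform")
        grid = TimeGrid(t0=float(t[0]), h=float(h), n_steps=len(t) - 1)
        return cls(grid=grid, states=frame.drop(columns="t").to_numpy())


def _check_alpha(alpha: float) -> float:
    alpha = getattr(alpha, "alpha", alpha)
    if not (0.0 < alpha <= 1.0) or not math.isfinite(alpha):
        raise ValueError(f"fractional order must lie in (0, 1], got {alpha!r}")
    return float(alpha)


def predictor_weights(alpha: float, h: float, n: int) -> np.ndarray:
    """Fractional rectangle-rule weights ``b[j]`` for the step to node ``n + 1``.

    ``b_j = (h^alpha / alpha) * ((n + 1 - j)^alpha - (n - j)^alpha)`` for
    ``j = 0..n``.  All weights are positive and telescope to
    ``(h^alpha / alpha) * (n + 1)^alpha``.
    """
    alpha = _check_alpha(alpha)
    if not (math.isfinite(h) and h > 0):
        raise ValueError(f"step h must be finite and > 0, got {h!r}")
    if n < 0:
        raise ValueError(f"node index n must be >= 0, got {n!r}")
    k = np.arange(n + 2, dtype=float)  # 0..n+1
    powers = k**alpha
    # j -> (n+1-j)^a - (n-j)^a is the reversed first difference of powers
    return (h**alpha / alpha) * np.diff(powers)[::-1]


def corrector_weights(alpha: float, n: int) -> np.ndarray:
    """Fractional trapezoid-rule history weights ``a[j]`` for node ``n + 1``.

    ``a_0 = n^(alpha+1) - (n - alpha) (n + 1)^alpha`` and, for ``1 <= j <= n``,
    ``a_j = (n - j + 2)^(alpha+1) + (n - j)^(alpha+1) - 2 (n - j + 1)^(alpha+1)``.
    The weight of the predicted node (equal to 1) is applied by the solver and
    not included here.
    """
    alpha = _check_alpha(alpha)
    if n < 0:
        raise ValueError(f"node index n must be >= 0, got {n!r}")
    a = np.empty(n + 1)
    a[0] = n ** (alpha + 1.0) - (n - alpha) * (n + 1.0) ** alpha
    if n >= 1:
        m = np.arange(n, dtype=float)  # m = n - j for j = n..1
        interior = (m + 2.0) ** (alpha + 1.0) + m ** (alpha + 1.0) - 2.0 * (m + 1.0) ** (
            alpha + 1.0
        )
        a[1:] = interior[::-1]
    return a


def _as_state(y0) -> np.ndarray:
    y0 = np.atleast_1d(np.asarray(y0, dtype=float))
    if y0.ndim != 1:
        raise ValueError("initial state must be one-dimensional")
    if not np.all(np.isfinite(y0)):
        raise ValueError(f"non-finite initial state: {y0!r}")
    return y0


def solve_caputo(
    fun: Callable[[np.ndarray], np.ndarray],
    y0,
    alpha: float,
    grid: TimeGrid,
) -> Trajectory:
    """Integrate ``D^alpha y = fun(y)`` with the PECE predictor-corrector.

    Each step predicts with the fractional rectangle rule over the full
    history, evaluates the right-hand side at the prediction, and corrects
    once with the fractional trapezoid rule:

    ``y^P_{n+1} = y0 + (h^alpha/Gamma(alpha+1)) * sum_j c_{n-j} f(y_j)``
    ``y_{n+1} = y0 + (h^alpha/Gamma(alpha+2)) * (f(y^P_{n+1}) + sum_j a_j f(y_j))``

    The scheme is deterministic; identical inputs give bitwise-identical
    trajectories.

    Raises
    ------
    SolverBlowUpError
        If a predicted or corrected state is non-finite (reports the step).
    """
    alpha = _check_alpha(alpha)
    y0 = _as_state(y0)
    n_steps, h = grid.n_steps, grid.h

    y = np.empty((n_steps + 1, y0.size))
    f = np.empty_like(y)
    y[0] = y0
    f[0] = fun(y[0])

    pred_scale = h**alpha / math.gamma(alpha + 1.0)
    corr_scale = h**alpha / math.gamma(alpha + 2.0)
    # c[k] = (k+1)^alpha - k^alpha ; interior corrector weights by lag m = n - j
    k = np.arange(n_steps + 1, dtype=float)
    c = np.diff(np.concatenate(([0.0], (k + 1.0) ** alpha)))
    m = np.arange(n_steps, dtype=float)
    w_interior = (m + 2.0) ** (alpha + 1.0) + m ** (alpha + 1.0) - 2.0 * (m + 1.0) ** (
        alpha + 1.0
    )

    for n in range(n_steps):
        hist = f[: n + 1]
        y_pred = y0 + pred_scale * (c[: n + 1][::-1] @ hist)
        if not np.all(np.isfinite(y_pred)):
            raise SolverBlowUpError(n + 1, "predictor")
        f_pred = fun(y_pred)
        a0 = n ** (alpha + 1.0) - (n - alpha) * (n + 1.0) ** alpha
        corr_sum = a0 * f[0]
        if n >= 1:
            corr_sum = corr_sum + w_interior[:n][::-1] @ f[1 : n + 1]
        y[n + 1] = y0 + corr_scale * (f_pred + corr_sum)
        if not np.all(np.isfinite(y[n + 1])):
            raise SolverBlowUpError(n + 1, "corrector")
        f[n + 1] = fun(y[n + 1])

    return Trajectory(grid=grid, states=y)


def solve_classical(
    fun: Callable[[np.ndarray], np.ndarray],
    y0,
    grid: TimeGrid,
) -> Trajectory:
    """Integer-order reference: explicit trapezoidal (Heun-type) PECE.

    Written in the same cumulative-quadrature form as :func:`solve_caputo`
    (Euler rectangle predictor over the history, trapezoid corrector from the
    initial point), so it coincides with the fractional scheme at
    ``alpha = 1`` step for step.  Second-order accurate and deterministic.
    """
    y0 = _as_state(y0)
    n_steps, h = grid.n_steps, grid.h

    y = np.empty((n_steps + 1, y0.size))
    f = np.empty_like(y)
    y[0] = y0
    f[0] = fun(y[0])
    ones = np.ones(n_steps + 1)

    for n in range(n_steps):
        hist = f[: n + 1]
        y_pred = y0 + h * (ones[: n + 1] @ hist)
        if not np.all(np.isfinite(y_pred)):
            raise SolverBlowUpError(n + 1, "predictor")
        f_pred = fun(y_pred)
        corr_sum = 1.0 * f[0]
        if n >= 1:
            corr_sum = corr_sum + (2.0 * ones[:n]) @ f[1 : n + 1]
        y[n + 1] = y0 + (h / 2.0) * (f_pred + corr_sum)
        if not np.all(np.isfinite(y[n + 1])):
            raise SolverBlowUpError(n + 1, "corrector")
        f[n + 1] = fun(y[n + 1])

    return Trajectory(grid=grid, states=y)


def mittag_leffler(alpha: float, z: float, tol: float = 1e-12, max_terms: int = 2000) -> float:
    """One-parameter Mittag-Leffler function ``E_alpha(z)``.

    ``E_alpha(z) = sum_k z^k / Gamma(alpha k + 1)``, evaluated with
    arbitrary-precision arithmetic so that alternating-series cancellation
    (severe for negative ``z`` and small ``alpha``) does not corrupt the
    double-precision result.  ``E_alpha(-t^alpha)`` solves the linear Caputo
    test equation ``D^alpha y = -y``, ``y(0) = 1``.

    Raises
    ------
    ArithmeticError
        If the series has not met ``tol`` after ``max_terms`` terms.
    """
    if not (alpha > 0 and math.isfinite(alpha)):
        raise ValueError(f"alpha must be > 0, got {alpha!r}")
    if not math.isfinite(z):
        raise ValueError(f"z must be finite, got {z!r}")
    # Working precision sized to the largest intermediate term.
    with mpmath.workdps(40 + int(3 * abs(z))):
        zz = mpmath.mpf(z)
        total = mpmath.mpf(0)
        term_bound = None
        for k_idx in range(max_terms):
            term = zz**k_idx / mpmath.gamma(alpha * k_idx + 1)
            total += term
            term_bound = abs(term)
            if k_idx > 0 and term_bound < tol * 1e-4:
                return float(total)
        raise ArithmeticError(
            f"Mittag-Leffler series for alpha={alpha}, z={z} did not reach "
            f"tolerance {tol} in {max_terms} terms (last term {term_bound})"
        )
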