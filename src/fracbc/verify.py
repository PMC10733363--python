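"""Self-verification suite: solver and training property checks.

Machine-checkable properties that must hold for any healthy build: the
integer-order degeneration of the PECE scheme, agreement with the
Mittag-Leffler oracle on the linear test equation, the empirical convergence
order of the solver, the predictor-weight telescoping identity, and
teacher-student recovery by the LM trainer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .solver import (
    TimeGrid,
    mittag_leffler,
    predictor_weights,
    solve_caputo,
    solve_classical,
)
from .surrogate import (
    NetworkWeights,
    TrainingConfig,
    forward,
    split_data,
    train_lm,
)

__all__ = ["CheckResult", "run_verification_suite", "CHECKS"]


@dataclass(frozen=True)
class CheckResult:
    name: str
    passed: bool
    value: float
    bound: float
    detail: str = ""


def _check_alpha_one_limit(solver: Callable = solve_caputo) -> CheckResult:
    """PECE at alpha = 1 must coincide with the classical trapezoidal PECE."""
    grid = TimeGrid(h=1e-3, n_steps=1000)

    def fun(y):
        return -y

    frac = solver(fun, 1.0, 1.0, grid).states
    classical = solve_classical(fun, 1.0, grid).states
    err = float(np.max(np.abs(frac - classical)))
    return CheckResult("alpha_one_limit", err <= 1e-12, err, 1e-12,
                       "max per-step deviation from the integer-order reference")


def _check_mittag_leffler(solver: Callable = solve_caputo) -> CheckResult:
    """Linear test equation D^a y = -y vs the Mittag-Leffler solution."""
    worst = 0.0
    for alpha in (0.5, 0.7, 0.9):
        grid = TimeGrid(h=1e-3, n_steps=500)
        traj = solver(lambda y: -y, 1.0, alpha, grid).states[:, 0]
        for t_idx in (100, 250, 500):
            t = grid.nodes[t_idx]
            exact = mittag_leffler(alpha, -(t**alpha))
            worst = max(worst, abs(traj[t_idx] - exact))
    return CheckResult("mittag_leffler_oracle", worst <= 1e-3, worst, 1e-3,
                       "max |numeric - E_alpha(-t^alpha)| over alpha in {0.5,0.7,0.9}")


def _check_convergence_order(solver: Callable = solve_caputo) -> CheckResult:
    """Empirical order on the linear test equation, halving h over 4 levels."""
    worst_margin = np.inf
    detail = []
    for alpha in (0.5, 0.7, 0.9):
        exact = mittag_leffler(alpha, -1.0)
        hs = [0.1 / 2**k for k in range(4)]
        errs = []
        for h in hs:
            grid = TimeGrid(h=h, n_steps=round(1.0 / h))
            errs.append(abs(solver(lambda y: -y, 1.0, alpha, grid).states[-1, 0] - exact))
        p = float(np.polyfit(np.log(hs), np.log(errs), 1)[0])
        bound = min(2.0, 1.0 + alpha) - 0.2
        worst_margin = min(worst_margin, p - bound)
        detail.append(f"alpha={alpha}: p={p:.3f} (>= {bound})")
    return CheckResult("convergence_order", worst_margin >= 0.0, worst_margin, 0.0,
                       "; ".join(detail))


def _check_weight_telescoping(solver: Callable = solve_caputo) -> CheckResult:
    """Predictor weights must sum to (h^a/a) (n+1)^a exactly."""
    worst = 0.0
    for alpha in (0.3, 0.5, 0.7, 0.9, 1.0):
        for h in (0.01, 0.1, 1.0):
            for n in (0, 1, 5, 50):
                b = predictor_weights(alpha, h, n)
                target = (h**alpha / alpha) * (n + 1) ** alpha
                worst = max(worst, abs(b.sum() - target) / target)
    return CheckResult("predictor_weight_telescoping", worst <= 1e-12, worst, 1e-12,
                       "max relative telescoping defect")


def _check_teacher_student(solver: Callable = solve_caputo) -> CheckResult:
    """LM must recover a realizable 15-unit target to <= 1e-10 training MSE."""
    rng = np.random.default_rng(2024)
    # moderate hidden slopes keep the exact-recovery basin reachable by LM
    teacher = NetworkWeights(
        rng.uniform(-3.0, 3.0, 15), rng.uniform(-3.0, 3.0, 15),
        rng.uniform(-1.0, 1.0, (5, 15)), rng.uniform(-0.5, 0.5, 5),
    )
    t = np.linspace(0.0, 1.0, 101)
    # teacher is evaluated on the scaled input, so the student's problem is
    # exactly realizable (the linear output layer absorbs the target scaling)
    targets = forward(teacher, 2.0 * t - 1.0)
    config = TrainingConfig(seed=7, max_epochs=1000, n_restarts=3,
                            init_scheme="nguyen-widrow")
    split = split_data(101, config)
    _, _, record = train_lm((t, targets), split, config, seed=11)
    final_train = float(record.train_mse[-1])
    return CheckResult("teacher_student_recovery", final_train <= 1e-10,
                       final_train, 1e-10, "final training MSE on realizable targets")


CHECKS: Mapping[str, Callable[..., CheckResult]] = {
    "alpha_one_limit": _check_alpha_one_limit,
    "mittag_leffler_oracle": _check_mittag_leffler,
    "convergence_order": _check_convergence_order,
    "predictor_weight_telescoping": _check_weight_telescoping,
    "teacher_student_recovery": _check_teacher_student,
}


def run_verification_suite(
    selection: Sequence[str] | None = None,
    solver: Callable = solve_caputo,
) -> dict[str, CheckResult]:
    """Run the named property checks (all by default).

    ``solver`` may be swapped for a wrapped/corrupted variant; the
    solver-facing checks then exercise that variant (used to confirm the
    checks actually detect a broken scheme).

    Raises
    ------
    ValueError
        If ``selection`` is empty or names an unknown check.
    """
    if selection is None:
        names = list(CHECKS)
    else:
        names = list(selection)
        if not names:
            raise ValueError("empty verification selection")
        unknown = [n for n in names if n not in CHECKS]
        if unknown:
            raise ValueError(f"unknown checks: {unknown}; available: {list(CHECKS)}")
    return {name: CHECKS[name](solver) for name in names}
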