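"""Fit-quality metrics and the per-case evaluation report.

Collects everything a fitting-toolbox session reports about a trained
surrogate: per-subset mean squared error, the regression coefficient R
between outputs and targets, the residual histogram with its zero-error bin,
per-channel absolute error against the reference trajectory, and the
training-record summary (gradient, damping, epochs, stop reason).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import STATE_NAMES
from .solver import Trajectory
from .surrogate import (
    NetworkWeights,
    ScalingSpec,
    SplitIndices,
    TrainingRecord,
    predict,
)

__all__ = [
    "EvaluationReport",
    "mse",
    "regression_R",
    "error_histogram",
    "absolute_error",
    "build_report",
]


def mse(predictions, targets) -> float:
    """Mean squared error over all samples and channels."""
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(targets, dtype=float)
    if p.size == 0 or t.size == 0:
        raise ValueError("empty input to mse")
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    return float(np.mean((p - t) ** 2))


def regression_R(predictions, targets) -> float:
    """Pearson correlation between flattened predictions and targets.

    This is the R of the regression panel in fitting toolboxes: 1 means the
    outputs reproduce the targets up to an exact positive affine map.
    """
    p = np.asarray(predictions, dtype=float).ravel()
    t = np.asarray(targets, dtype=float).ravel()
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    if p.size < 2:
        raise ValueError("regression_R needs at least 2 samples")
    if np.ptp(t) == 0.0:
        raise ValueError("regression R undefined: targets have zero variance")
    r = np.corrcoef(p, t)[0, 1]
    return float(np.clip(r, -1.0, 1.0))


def error_histogram(
    residuals, n_bins: int = 20
) -> tuple[np.ndarray, np.ndarray, float]:
    """Equal-width residual histogram and the midpoint of the zero-error bin.

    Returns ``(edges, counts, center_bin_midpoint)`` where the midpoint is
    that of the bin containing zero (clipped to the nearest bin when zero
    lies outside the residual range) -- the value annotated on toolbox
    error-histogram panels.
    """
    r = np.asarray(residuals, dtype=float).ravel()
    if r.size == 0:
        raise ValueError("empty residuals")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    lo, hi = float(r.min()), float(r.max())
    if lo == hi:
        # degenerate range: one populated bin centered on the common value
        width = max(abs(lo), 1.0) * 1e-9
        edges = np.array([lo - width / 2.0, lo + width / 2.0])
        counts = np.array([r.size])
    else:
        counts, edges = np.histogram(r, bins=n_bins, range=(lo, hi))
    zero_bin = int(np.clip(np.searchsorted(edges, 0.0, side="right") - 1, 0, len(counts) - 1))
    midpoint = float((edges[zero_bin] + edges[zero_bin + 1]) / 2.0)
    return edges, counts, midpoint


def absolute_error(
    surrogate_traj: Trajectory, reference_traj: Trajectory
) -> tuple[np.ndarray, np.ndarray]:
    """Elementwise |surrogate - reference| per channel, plus per-channel maxima.

    Both trajectories must live on the same grid.
    """
    if surrogate_traj.grid != reference_traj.grid:
        raise ValueError(
            f"grid mismatch: {surrogate_traj.grid} vs {reference_traj.grid}"
        )
    if surrogate_traj.states.shape != reference_traj.states.shape:
        raise ValueError("trajectory shape mismatch")
    ae = np.abs(surrogate_traj.states - reference_traj.states)
    return ae, ae.max(axis=0)


@dataclass
class EvaluationReport:
    """Aggregated metric bundle for one trained case."""

    case_id: int
    train_mse: float
    validation_mse: float
    test_mse: float
    best_validation_mse: float
    gradient_at_stop: float
    mu_at_stop: float
    epochs: int
    stop_reason: str
    regression_overall: float
    regression_train: float
    regression_validation: float
    regression_test: float
    regression_per_channel: dict[str, float]
    histogram_edges: list[float]
    histogram_counts: list[int]
    histogram_zero_bin_midpoint: float
    max_abs_error: dict[str, float]
    n_points: int

    def validate(self) -> None:
        for name in ("train_mse", "validation_mse", "test_mse", "best_validation_mse"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("regression_overall", "regression_train",
                     "regression_validation", "regression_test"):
            if not -1.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} outside [-1, 1]")
        if sum(self.histogram_counts) != self.n_points * len(STATE_NAMES):
            raise ValueError("histogram counts do not conserve the residual count")

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    def to_table_row(self) -> pd.DataFrame:
        """One flat row in the style of the toolbox summary table."""
        return pd.DataFrame(
            [
                {
                    "case": self.case_id,
                    "mse_training": self.train_mse,
                    "mse_validation": self.validation_mse,
                    "mse_test": self.test_mse,
                    "performance": self.best_validation_mse,
                    "gradient": self.gradient_at_stop,
                    "mu": self.mu_at_stop,
                    "epoch": self.epochs,
                    "regression": self.regression_overall,
                }
            ]
        )


def build_report(
    case_id: int,
    record: TrainingRecord,
    weights: NetworkWeights,
    scaling: ScalingSpec,
    dataset: tuple[np.ndarray, np.ndarray],
    split: SplitIndices,
    reference: Trajectory,
    n_bins: int = 20,
) -> EvaluationReport:
    """Assemble the full metric bundle for one training run.

    Deterministic in its inputs.  MSE and R are computed in original data
    units from the returned (best-validation-epoch) weights; the
    "performance" entry is the best validation MSE seen during training.
    """
    if record.n_epochs < 0 or not record.train_mse:
        raise ValueError("empty training record")
    t, y = dataset
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)

    pred = predict(weights, scaling, t)
    residuals = pred - y

    def subset(op, idx):
        return op(pred[idx], y[idx])

    surrogate_traj = Trajectory(grid=reference.grid, states=pred)
    _, max_ae = absolute_error(surrogate_traj, reference)
    edges, counts, zero_mid = error_histogram(residuals, n_bins=n_bins)

    per_channel = {
        name: regression_R(pred[:, i], y[:, i]) for i, name in enumerate(STATE_NAMES)
    }
    report = EvaluationReport(
        case_id=case_id,
        train_mse=subset(mse, split.training),
        validation_mse=subset(mse, split.validation),
        test_mse=subset(mse, split.test),
        best_validation_mse=float(record.best_validation_mse),
        gradient_at_stop=float(record.gradient[-1]),
        mu_at_stop=float(record.mu[-1]),
        epochs=int(record.n_epochs),
        stop_reason=str(record.stop_reason),
        regression_overall=regression_R(pred, y),
        regression_train=subset(regression_R, split.training),
        regression_validation=subset(regression_R, split.validation),
        regression_test=subset(regression_R, split.test),
        regression_per_channel=per_channel,
        histogram_edges=[float(v) for v in edges],
        histogram_counts=[int(v) for v in counts],
        histogram_zero_bin_midpoint=float(zero_mid),
        max_abs_error={name: float(max_ae[i]) for i, name in enumerate(STATE_NAMES)},
        n_points=int(t.size),
    )
    report.validate()
    return report
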