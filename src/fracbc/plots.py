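"""Figure emitters: training curves, fit/error panels, regression, overlap.

Matplotlib renderings of the standard toolbox panels for a finished run.
Each function takes a :class:`~fracbc.pipeline.RunResult` and writes one PNG.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .model import STATE_NAMES
from .pipeline import RunResult
from .surrogate import predict

__all__ = [
    "plot_training_curves",
    "plot_fit_and_histogram",
    "plot_regression",
    "plot_absolute_error",
    "plot_overlap",
    "write_all_figures",
]


def _save(fig, path):
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_training_curves(result: RunResult, path: str | Path) -> None:
    """Per-epoch MSE (train/validation/test), gradient and damping traces."""
    rec = result.record
    epochs = np.arange(len(rec.train_mse))
    fig, (ax0, ax1) = plt.subplots(1, 2, figsize=(10, 4))
    ax0.semilogy(epochs, rec.train_mse, label="training")
    ax0.semilogy(epochs, rec.validation_mse, label="validation")
    ax0.semilogy(epochs, rec.test_mse, label="test")
    ax0.axvline(rec.best_epoch, color="k", ls=":", lw=1,
                label=f"best epoch {rec.best_epoch}")
    ax0.set_xlabel("epoch")
    ax0.set_ylabel("MSE")
    ax0.legend(fontsize=8)
    ax0.set_title(f"case {result.config.case_id}: MSE")
    ax1.semilogy(epochs, rec.gradient, label="gradient")
    ax1.semilogy(epochs, rec.mu, label="mu")
    ax1.set_xlabel("epoch")
    ax1.legend(fontsize=8)
    ax1.set_title("training state")
    _save(fig, path)


def plot_fit_and_histogram(result: RunResult, path: str | Path) -> None:
    """Function fit over time plus the residual error histogram."""
    t = result.reference.t
    y = result.reference.states
    pred = predict(result.weights, result.scaling, t)
    fig, (ax0, ax1) = plt.subplots(1, 2, figsize=(10, 4))
    for i, name in enumerate(STATE_NAMES):
        ax0.plot(t, y[:, i], lw=1, label=f"{name} reference")
        ax0.plot(t, pred[:, i], "--", lw=1)
    ax0.set_xlabel("t")
    ax0.set_ylabel("state")
    ax0.legend(fontsize=7)
    ax0.set_title("function fit (dashed: network)")
    rep = result.report
    edges = np.asarray(rep.histogram_edges)
    ax1.bar(
        (edges[:-1] + edges[1:]) / 2.0,
        rep.histogram_counts,
        width=np.diff(edges),
        edgecolor="k",
    )
    ax1.axvline(rep.histogram_zero_bin_midpoint, color="orange", lw=2,
                label=f"zero-error bin {rep.histogram_zero_bin_midpoint:.2e}")
    ax1.set_xlabel("residual")
    ax1.set_ylabel("count")
    ax1.legend(fontsize=8)
    ax1.set_title("error histogram")
    _save(fig, path)


def plot_regression(result: RunResult, path: str | Path) -> None:
    """Network outputs against targets with the fitted regression line."""
    t = result.reference.t
    y = result.reference.states.ravel()
    pred = predict(result.weights, result.scaling, t).ravel()
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(y, pred, ".", ms=3)
    lims = [min(y.min(), pred.min()), max(y.max(), pred.max())]
    ax.plot(lims, lims, "k--", lw=1)
    ax.set_xlabel("target")
    ax.set_ylabel("output")
    ax.set_title(f"regression R = {result.report.regression_overall:.6f}")
    _save(fig, path)


def plot_absolute_error(result: RunResult, path: str | Path) -> None:
    """Per-channel |surrogate - reference| over time (log scale)."""
    t = result.reference.t
    y = result.reference.states
    pred = predict(result.weights, result.scaling, t)
    fig, ax = plt.subplots(figsize=(6, 4))
    for i, name in enumerate(STATE_NAMES):
        ax.semilogy(t, np.abs(pred[:, i] - y[:, i]) + 1e-18, lw=1, label=name)
    ax.set_xlabel("t")
    ax.set_ylabel("absolute error")
    ax.legend(fontsize=8)
    ax.set_title(f"case {result.config.case_id}: absolute error")
    _save(fig, path)


def plot_overlap(result: RunResult, path: str | Path) -> None:
    """Reference and surrogate trajectories overlaid per channel."""
    t = result.reference.t
    y = result.reference.states
    pred = predict(result.weights, result.scaling, t)
    fig, axes = plt.subplots(1, 5, figsize=(15, 3), sharex=True)
    for i, (ax, name) in enumerate(zip(axes, STATE_NAMES)):
        ax.plot(t, y[:, i], lw=1.5, label="reference")
        ax.plot(t, pred[:, i], "--", lw=1.5, label="network")
        ax.set_title(name)
        ax.set_xlabel("t")
    axes[0].legend(fontsize=7)
    _save(fig, path)


def write_all_figures(result: RunResult, out_dir: str | Path) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for fn, name in [
        (plot_training_curves, "training_curves.png"),
        (plot_fit_and_histogram, "fit_and_histogram.png"),
        (plot_regression, "regression.png"),
        (plot_absolute_error, "absolute_error.png"),
        (plot_overlap, "overlap.png"),
    ]:
        path = out / name
        fn(result, path)
        written.append(path)
    return written
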