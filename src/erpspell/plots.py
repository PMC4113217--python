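"""Figure analogues for synthetic runs: accuracy bars, error rasters,
ssAUC maps and extended-session sub-block curves."""

from __future__ import annotations

from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .evaluation import RunRecord, selection_accuracy, subblock_correct_counts

__all__ = [
    "plot_block_accuracies",
    "plot_error_raster",
    "plot_ssauc_map",
    "plot_extended_subblocks",
]


def plot_block_accuracies(records: Sequence[RunRecord], path: Optional[str] = None):
    """Per-run block accuracies for each method (bar groups per run)."""
    methods = ["supervised", "unsupervised", "posthoc"]
    fig, axes = plt.subplots(len(methods), 1, figsize=(8, 7), sharey=True)
    for ax, method in zip(axes, methods):
        src = "posthoc" if method == "posthoc" else "online"
        tag = "unsupervised" if method == "posthoc" else method
        for r, rec in enumerate(records):
            accs = []
            for b in rec.method_blocks(tag):
                preds = b.posthoc if src == "posthoc" else b.online
                if preds is not None:
                    accs.append(selection_accuracy(b.truth, preds))
            x = r + np.linspace(-0.3, 0.3, max(len(accs), 1))
            ax.bar(x, accs, width=0.6 / max(len(accs), 1))
        ax.axhline(1 / 6, color="k", ls=":", lw=0.8, label="chance")
        ax.set_ylabel(method)
        ax.set_ylim(0, 1)
    axes[-1].set_xlabel("simulated subject (run)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_error_raster(records: Sequence[RunRecord], which: str = "online",
                      path: Optional[str] = None):
    """Green/black per-trial raster (rows = runs) for the unsupervised blocks."""
    rows = []
    for rec in records:
        truth, preds = rec.concat("unsupervised", which)
        rows.append((truth == preds).astype(int))
    grid = np.array(rows)
    fig, ax = plt.subplots(figsize=(9, 0.35 * len(rows) + 1.5))
    ax.imshow(grid, aspect="auto", cmap="RdYlGn", vmin=0, vmax=1,
              interpolation="nearest")
    ax.set_xlabel("trial")
    ax.set_ylabel("run")
    ax.set_title(f"unsupervised selection errors ({which}); dark = error")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_ssauc_map(ssauc: np.ndarray, channel_names: Sequence[str],
                   interval_labels: Sequence[str], path: Optional[str] = None):
    fig, ax = plt.subplots(figsize=(7, 8))
    im = ax.imshow(ssauc, aspect="auto", cmap="RdBu_r", vmin=-1, vmax=1)
    ax.set_xticks(range(len(interval_labels)), interval_labels, rotation=90)
    ax.set_yticks(range(len(channel_names)), channel_names, fontsize=6)
    fig.colorbar(im, label="ssAUC (2*AUC - 1)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_extended_subblocks(records: Sequence[RunRecord], subblock_size: int = 10,
                            path: Optional[str] = None):
    """Grand-average correct trials per 10-trial sub-block over the extended
    simulation, for the three decoding approaches."""
    curves = {}
    for which, tag, label in (
        ("online", "supervised", "supervised"),
        ("online", "unsupervised", "unsupervised"),
        ("posthoc", "unsupervised", "posthoc"),
    ):
        counts = [
            subblock_correct_counts(*rec.concat(tag, which), subblock_size)
            for rec in records
        ]
        curves[label] = np.mean(counts, axis=0)
    fig, ax = plt.subplots(figsize=(8, 4))
    styles = {"supervised": "b-o", "unsupervised": "g-s", "posthoc": "r:^"}
    for label, curve in curves.items():
        ax.plot(np.arange(1, len(curve) + 1), curve, styles[label], label=label)
    ax.set_xlabel(f"sub-block ({subblock_size} trials each)")
    ax.set_ylabel("correct trials")
    ax.set_ylim(0, subblock_size)
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
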