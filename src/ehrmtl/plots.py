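"""Figure helpers for protocol and complexity output."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .complexity import ComplexityReport

_FAMILY_COLORS = {"MTNN": "tab:blue", "STNN": "tab:red", "LR": "tab:green"}


def plot_split_performance(runs: pd.DataFrame, best: pd.DataFrame, path: str | Path) -> None:
    """Test AUPRC of every grid point per split, best-by-validation emphasized."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for family, g in runs[runs["status"] == "ok"].groupby("family"):
        jitter = {"STNN": -0.15, "MTNN": 0.15, "LR": 0.0}[family]
        ax.scatter(
            g["split_id"] + jitter, g["test_auprc"],
            s=12, alpha=0.35, color=_FAMILY_COLORS[family], label=None,
        )
    for family, g in best.groupby("family"):
        jitter = {"STNN": -0.15, "MTNN": 0.15, "LR": 0.0}[family]
        ax.scatter(
            g["split_id"] + jitter, g["test_auprc"],
            s=45, color=_FAMILY_COLORS[family], label=family, edgecolor="k",
        )
    ax.set_xlabel("split")
    ax.set_ylabel("test AUPRC")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_pairwise_differences(pairwise: pd.DataFrame, path: str | Path) -> None:
    """Per-split best-MTNN minus best-STNN test AUPRC, by auxiliary-set size."""
    fig, ax = plt.subplots(figsize=(5, 4))
    sizes = sorted(pairwise["aux_set_size"].unique())
    data = [pairwise[pairwise["aux_set_size"] == s]["mtnn_minus_stnn"] for s in sizes]
    ax.boxplot(data, tick_labels=[str(s) for s in sizes])
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("number of auxiliary tasks")
    ax.set_ylabel("MTNN − STNN test AUPRC")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_signature_histogram(report: ComplexityReport, path: str | Path) -> None:
    """Two-series bucket histogram of oracle-signature combinations."""
    hist = report.histogram
    x = np.arange(hist.n_buckets)
    fig, ax = plt.subplots(figsize=(7, 3.5))
    width = 0.4
    ax.bar(x - width / 2, hist.counts_pos / hist.counts_pos.sum(),
           width, color="gold", label="cases")
    ax.bar(x + width / 2, hist.counts_neg / hist.counts_neg.sum(),
           width, color="tab:blue", label="controls")
    ax.set_xlabel("signature bucket")
    ax.set_ylabel("fraction")
    ax.set_title(
        f"{report.rule_id}: H={report.entropy_pos:.3f}, "
        f"KL={report.kl_pos_vs_neg:.3f}"
    )
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
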