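"""Optional matplotlib views of ordination and coverage results."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .diversity import NMDSResult


def plot_nmds(result: NMDSResult, sample_ids: list[str], path: str) -> None:
    """Scatter of the first two NMDS axes, annotated with sample ids."""
    fig, ax = plt.subplots(figsize=(5, 4))
    xy = result.coords[:, :2]
    ax.scatter(xy[:, 0], xy[:, 1], s=25, color="tab:blue")
    for sid, (x, y) in zip(sample_ids, xy):
        ax.annotate(sid, (x, y), fontsize=7, xytext=(2, 2), textcoords="offset points")
    ax.set_xlabel("NMDS1")
    ax.set_ylabel("NMDS2")
    ax.set_title(f"NMDS (stress-1 = {result.stress:.3f})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_coverage(aggregate: pd.DataFrame, path: str) -> None:
    """Grouped bars of per-site mean coverage percentages with sd whiskers."""
    groups = sorted(aggregate["group"].unique())
    sites = sorted(aggregate["site"].unique())
    fig, ax = plt.subplots(figsize=(max(6, len(groups)), 4))
    width = 0.8 / max(len(sites), 1)
    x = np.arange(len(groups))
    for k, site in enumerate(sites):
        sub = aggregate[aggregate["site"] == site].set_index("group")
        means = [sub["mean"].get(g, 0.0) for g in groups]
        sds = [sub["sd"].get(g, 0.0) for g in groups]
        ax.bar(x + k * width, means, width, yerr=sds, capsize=2, label=str(site))
    ax.set_xticks(x + width * (len(sites) - 1) / 2)
    ax.set_xticklabels(groups, rotation=45, ha="right", fontsize=7)
    ax.set_ylabel("coverage (% of profile area)")
    ax.legend(title="site", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
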