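"""Matplotlib figures for the three diagnostic views of a run.

These are deliberately minimal: a threshold-by-ratio heatmap of binned
vertex counts, a histogram of low-ratio vertex mass per threshold, and a
scatter of per-component expansion (member gain vs frequency gain) with
candidates highlighted.
"""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .dynamics import ComponentDynamics
from .threshold import BIN_EDGES, SweepRecord


def sweep_heatmap(records: Sequence[SweepRecord], path=None):
    ts = [r.t for r in records]
    mat = np.array([[r.bins[e] for e in BIN_EDGES] for r in records]).T
    fig, ax = plt.subplots(figsize=(0.45 * len(ts) + 2, 4))
    im = ax.imshow(mat, aspect="auto", origin="lower", cmap="viridis")
    ax.set_xticks(range(len(ts)), [str(t) for t in ts])
    ax.set_yticks(range(len(BIN_EDGES)), [f"{lo:.1f}–{hi:.1f}" for lo, hi in BIN_EDGES])
    ax.set_xlabel("LD threshold")
    ax.set_ylabel("HCDR3 ratio")
    fig.colorbar(im, ax=ax, label="vertices")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def low_ratio_histogram(records: Sequence[SweepRecord], cutoff: float = 0.3, path=None):
    ts = [r.t for r in records]
    fig, ax = plt.subplots(figsize=(0.45 * len(ts) + 2, 3.5))
    ax.bar(ts, [r.vertices_low_ratio for r in records], color="#31688e")
    ax.set_xlabel("LD threshold")
    ax.set_ylabel(f"vertices in components with ratio < {cutoff:g}")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def dynamics_scatter(
    dynamics_list: Sequence[ComponentDynamics],
    candidates: Sequence[ComponentDynamics] = (),
    path=None,
):
    cand_ids = {d.component_id for d in candidates}
    xs = [d.delta_vertices for d in dynamics_list]
    ys = [d.delta_avg_freq for d in dynamics_list]
    colors = ["#b5443b" if d.component_id in cand_ids else "black" for d in dynamics_list]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(xs, ys, c=colors, s=18, alpha=0.8)
    for d in dynamics_list:
        if d.component_id in cand_ids:
            ax.annotate(str(d.component_id), (d.delta_vertices, d.delta_avg_freq),
                        fontsize=8, xytext=(3, 3), textcoords="offset points")
    ax.set_xlabel("Δ active vertices (last − first)")
    ax.set_ylabel("Δ average clonal frequency")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
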