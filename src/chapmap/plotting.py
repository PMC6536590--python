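"""Minimal figures: a coverage/peak track and an MA plot."""

from __future__ import annotations

from typing import Iterable, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .expression import ExpressionRecord
from .model import CoverageTrack
from .peaks import PeakSet

__all__ = ["plot_coverage", "plot_ma"]


def plot_coverage(track: CoverageTrack, peaks: PeakSet | None = None, path=None):
    """Raw coverage with called peak spans shaded."""
    fig, ax = plt.subplots(figsize=(10, 3))
    ax.plot(track.values, lw=0.5, color="firebrick")
    if peaks is not None:
        for p in peaks:
            ax.axvspan(p.start, p.end, color="grey", alpha=0.3)
        if peaks.genome_mean:
            ax.axhline(3 * peaks.genome_mean, color="black", ls="--", lw=0.8)
    ax.set_xlabel("position (bp)")
    ax.set_ylabel("coverage")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_ma(
    records: Sequence[ExpressionRecord],
    bound_genes: Iterable[str] = (),
    path=None,
):
    """M (log2 ratio) against A (mean log intensity); bound genes in red."""
    bound = set(bound_genes)
    fig, ax = plt.subplots(figsize=(5, 5))
    a = [r.A for r in records if r.gene_id not in bound]
    m = [r.M for r in records if r.gene_id not in bound]
    ax.scatter(a, m, s=5, color="grey", alpha=0.5, label="unbound")
    ab = [r.A for r in records if r.gene_id in bound]
    mb = [r.M for r in records if r.gene_id in bound]
    if ab:
        ax.scatter(ab, mb, s=10, color="firebrick", label="bound")
        ax.legend(frameon=False)
    ax.axhline(0, color="black", lw=0.5)
    ax.set_xlabel("A (mean log2 intensity)")
    ax.set_ylabel("M (log2 ratio)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
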