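"""Static track plot: signed strand coverage with shaded call regions."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .calls import ClusterCall
from .labels import StateTrack
from .te import CoverageTrack

__all__ = ["plot_tracks"]

_STATE_COLORS = {1: "#f2a0c0", 2: "#9fb4c7"}  # pink cluster, grey-blue centromere


def plot_tracks(
    cov: CoverageTrack,
    pred: StateTrack | None = None,
    calls: Sequence[ClusterCall] | None = None,
    path: str | Path = "tracks.png",
) -> None:
    """Render coverage and calls across all contigs, concatenated.

    Plus-strand coverage is drawn upward and minus-strand downward;
    predicted or called regions are shaded by state, and contig breaks are
    marked with vertical lines. Output format follows the file extension.
    """
    grid = cov.grid
    if pred is not None and pred.grid.n_bins != grid.n_bins:
        raise ValueError("prediction track is on a different grid")
    # genome-concatenated x coordinates (bin midpoints)
    offsets: dict[str, int] = {}
    running = 0
    for name, length in grid.contigs:
        offsets[name] = running
        running += length
    off = np.array([offsets[grid.contigs.names[i]] for i in grid.contig_index])
    x = off + (grid.starts + grid.ends) / 2

    fig, ax = plt.subplots(figsize=(12, 3))
    ax.fill_between(x, cov.plus_frac, 0, step="mid", color="0.15", linewidth=0)
    ax.fill_between(x, -cov.minus_frac, 0, step="mid", color="0.45", linewidth=0)

    if calls is None and pred is not None:
        from .calls import merge_state_runs

        calls = merge_state_runs(pred)
    for c in calls or []:
        ax.axvspan(
            offsets[c.contig] + c.start,
            offsets[c.contig] + c.end,
            color=_STATE_COLORS[c.state],
            alpha=0.6,
            linewidth=0,
        )
    for name, length in grid.contigs:
        ax.axvline(offsets[name], color="black", linewidth=0.6)
    ax.axvline(running, color="black", linewidth=0.6)
    ax.axhline(0, color="black", linewidth=0.4)
    ax.set_xlim(0, running)
    ax.set_ylim(-1.05, 1.05)
    ax.set_xlabel("concatenated genome position (bp)")
    ax.set_ylabel("Gypsy TE coverage\n(+ up / − down)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
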