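"""Profile plots: marker values with segment means and calls overlaid."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .io import SignalMatrix, chromosome_rank  # noqa: E402

__all__ = ["plot_profile"]

_LABEL_COLORS = {"loss": "#d62728", "normal": "#2ca02c", "gain": "#1f77b4"}


def plot_profile(signal: SignalMatrix, segments: pd.DataFrame | None,
                 sample: str, path=None):
    """Scatter one sample's profile along the genome, segments overlaid.

    Chromosomes are concatenated on a single axis with alternating shading;
    segment means are drawn as horizontal lines, colored by call label when
    present.  Returns the matplotlib figure; saves to ``path`` if given.
    """
    values = signal.column(sample)
    markers = signal.markers
    slices = markers.chromosome_slices()

    # cumulative genomic coordinate
    offset, offsets = 0, {}
    for chrom in markers.chromosomes:
        offsets[chrom] = offset
        sl = slices[chrom]
        offset += int(markers.position[sl][-1])
    x = np.array([offsets[c] for c in markers.chromosome]) + markers.position

    fig, ax = plt.subplots(figsize=(11, 3.2))
    for i, chrom in enumerate(markers.chromosomes):
        sl = slices[chrom]
        if i % 2:
            ax.axvspan(offsets[chrom], offsets[chrom] + markers.position[sl][-1],
                       color="0.93", zorder=0)
        ax.annotate(chrom, ((offsets[chrom] + markers.position[sl][-1] / 2), 1.02),
                    xycoords=("data", "axes fraction"), ha="center", fontsize=8)
    ax.plot(x, values, ".", ms=2, color="0.55", zorder=1)

    if segments is not None:
        sub = segments[segments["sample"] == str(sample)]
        for _, row in sub.iterrows():
            color = _LABEL_COLORS.get(row.get("label"), "#000000")
            x0 = offsets.get(row["chromosome"], 0)
            ax.hlines(row["mean"], x0 + row["start"] + 1, x0 + row["end"],
                      color=color, lw=2.2, zorder=2)

    ax.set_xlim(0, offset)
    ax.set_xlabel("genomic position")
    ax.set_ylabel(signal.signal_kind.replace("_", " "))
    ax.set_title(str(sample))
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
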