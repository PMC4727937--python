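"""Minimal track figure helper (matplotlib is imported lazily)."""

from __future__ import annotations

from typing import Sequence

from .enrichment import EnrichmentTrack, Peak


def plot_track(
    track: EnrichmentTrack,
    peaks: Sequence[Peak] = (),
    out_path=None,
    threshold: float | None = None,
):
    """Plot the enrichment track per chromosome, marking called peaks.

    Returns the matplotlib figure; saves to ``out_path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    chroms = list(dict.fromkeys(track.df["chrom"]))
    fig, axes = plt.subplots(
        1, len(chroms), figsize=(3 * len(chroms), 2.5), sharey=True, squeeze=False
    )
    for ax, chrom in zip(axes[0], chroms):
        grp = track.df[track.df["chrom"] == chrom]
        ax.plot(grp["center"] / 1e6, grp["value"], lw=0.8, color="firebrick")
        if threshold is not None:
            ax.axhline(threshold, ls=":", color="grey", lw=0.8)
        for p in peaks:
            if p.chromosome == chrom:
                ax.axvline(p.position_bp / 1e6, ls="--", color="black", lw=0.8)
        ax.set_title(f"chr{chrom}", fontsize=9)
        ax.set_xlabel("Mb", fontsize=8)
    axes[0][0].set_ylabel("enrichment")
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
    return fig
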