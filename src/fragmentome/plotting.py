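"""Optional plotting helpers (never load-bearing for any analysis)."""
from __future__ import annotations

import numpy as np


def plot_copy_number(profile, segments=None, path=None):
    """Genome-wide bin log2 scatter with optional segment overlay."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bins = profile.bins
    fig, ax = plt.subplots(figsize=(10, 3))
    offset = 0
    ticks, labels = [], []
    for contig, grp in bins.groupby("contig", sort=False):
        x = offset + (grp["start"] + grp["end"]).to_numpy() / 2
        ax.scatter(x[~grp["masked"]], grp.loc[~grp["masked"], "log2"],
                   s=4, alpha=0.6)
        if segments is not None:
            for seg in segments.loc[segments["contig"] == contig].itertuples():
                ax.hlines(seg.mean_log2, offset + seg.start, offset + seg.end,
                          colors="red", linewidth=2)
        ticks.append(offset + grp["end"].max() / 2)
        labels.append(str(contig))
        offset += grp["end"].max()
        ax.axvline(offset, color="grey", linewidth=0.5)
    ax.set_xticks(ticks, labels)
    ax.set_ylabel("log2 ratio")
    ax.axhline(0, color="black", linewidth=0.5)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig


def plot_size_histogram(hist, path=None):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3))
    lengths = np.arange(1, hist.l_max + 1)
    ax.plot(lengths, hist.density[1:])
    ax.set_xlabel("fragment size (bp)")
    ax.set_ylabel("density")
    ax.set_xlim(0, min(hist.l_max, 1000))
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
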