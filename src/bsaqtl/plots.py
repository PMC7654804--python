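"""Genome-wide scan figures: SNP-index per pool, delta(SNP-index) with
simulated confidence bands, and the L1AFD profile."""

from __future__ import annotations

from typing import Optional

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .qtlseq import NullModel


def _genome_axis(df: pd.DataFrame, ax) -> pd.Series:
    """Cumulative genome coordinate for a windowed table; draws
    chromosome boundaries and returns the x positions."""
    offsets = {}
    off = 0
    for chrom, sub in df.groupby("chrom", sort=False):
        offsets[chrom] = off
        off += int(sub["end"].max())
        ax.axvline(off / 1e6, color="0.85", lw=0.6, zorder=0)
    return (df["start"] + df["chrom"].map(offsets)) / 1e6


def plot_scan(
    windows: pd.DataFrame,
    null: Optional[NullModel] = None,
    afd_profile: Optional[pd.DataFrame] = None,
    path=None,
):
    """Stacked panels: pool SNP-indexes, delta with 95%/99% bands, and
    (optionally) the L1AFD profile."""
    n_panels = 3 if afd_profile is not None else 2
    fig, axes = plt.subplots(n_panels, 1, figsize=(11, 2.6 * n_panels), sharex=True)
    x = _genome_axis(windows, axes[0])
    axes[0].plot(x, windows["index_T"], ".", ms=1.5, color="tab:blue", label="T-pool")
    axes[0].plot(x, windows["index_S"], ".", ms=1.5, color="tab:orange", label="S-pool")
    axes[0].set_ylabel("SNP-index")
    axes[0].legend(loc="upper right", markerscale=4, frameon=False)

    axes[1].plot(x, windows["delta"], ".", ms=1.5, color="0.3")
    if null is not None and "median_depth" in windows:
        d = windows["median_depth"].to_numpy()
        bands = {k: np.array([
            null.thresholds_at(v)[k] if np.isfinite(v) else np.nan for v in d])
            for k in ("lo95", "hi95", "lo99", "hi99")}
        axes[1].plot(x, bands["lo95"], color="green", lw=0.6)
        axes[1].plot(x, bands["hi95"], color="green", lw=0.6, label="95% CI")
        axes[1].plot(x, bands["lo99"], color="red", lw=0.6)
        axes[1].plot(x, bands["hi99"], color="red", lw=0.6, label="99% CI")
        axes[1].legend(loc="upper right", frameon=False)
    axes[1].axhline(0, color="0.6", lw=0.5)
    axes[1].set_ylabel("$\\Delta$(SNP-index)")

    if afd_profile is not None:
        xa = _genome_axis(afd_profile, axes[2])
        axes[2].plot(xa, afd_profile["l1afd"], ".", ms=1.5, color="purple")
        axes[2].axhline(0, color="0.6", lw=0.5)
        axes[2].set_ylabel("L1AFD")
    axes[-1].set_xlabel("genome position (Mb)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
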