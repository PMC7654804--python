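"""Tolerant-parent allele-frequency-difference (L1AFD) profile and
donor-parent assignment.

With sites oriented so the L1 allele is REF, the L1 allele frequency
of a pool inside a window is the depth-weighted ref-read fraction, and

    L1AFD = freq(T-pool) - freq(S-pool)

on the same 1-Mb / 10-kb grid as the delta(SNP-index) scan.  A
positive L1AFD over a QTL region means the tolerant bulk is enriched
for the L1 allele, i.e. the tolerance allele was donated by L1; a
negative value points to the sensitive parent L6.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .qtlseq import STEP, WINDOW, _window_starts

UNDETERMINED = "undetermined"


def l1_freq(l1_reads, depths) -> float:
    """Depth-weighted L1-allele frequency: total L1 reads / total depth."""
    l1_reads = np.asarray(l1_reads, dtype=float)
    depths = np.asarray(depths, dtype=float)
    total = depths.sum()
    if l1_reads.size == 0 or total < 1:
        raise ValueError("L1 frequency undefined without covered sites")
    return float(l1_reads.sum() / total)


def l1afd_profile(
    oriented: pd.DataFrame,
    window: int = WINDOW,
    step: int = STEP,
    chrom_lengths: Optional[Dict[str, int]] = None,
) -> pd.DataFrame:
    """Sliding-window L1AFD on the scan grid.

    Input is an L1-oriented site table (ref counts = L1 reads).  Empty
    windows get NaN frequencies.
    """
    if window % step != 0:
        raise ValueError("window must be a multiple of step")
    frames = []
    chrom_all = oriented["chrom"].to_numpy()
    for chrom in pd.unique(chrom_all):
        mask = chrom_all == chrom
        pos = oriented.loc[mask, "pos"].to_numpy()
        t_l1 = oriented.loc[mask, "T_ref"].to_numpy(dtype=np.int64)
        t_d = t_l1 + oriented.loc[mask, "T_alt"].to_numpy(dtype=np.int64)
        s_l1 = oriented.loc[mask, "S_ref"].to_numpy(dtype=np.int64)
        s_d = s_l1 + oriented.loc[mask, "S_alt"].to_numpy(dtype=np.int64)
        length = (chrom_lengths or {}).get(chrom, int(pos.max()) if pos.size else 1)
        starts = _window_starts(length, step)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, starts + window, side="left")
        cum = lambda a: np.concatenate([[0], np.cumsum(a)])
        ct_l1, ct_d = cum(t_l1), cum(t_d)
        cs_l1, cs_d = cum(s_l1), cum(s_d)
        n = hi - lo
        with np.errstate(invalid="ignore", divide="ignore"):
            ft = (ct_l1[hi] - ct_l1[lo]) / (ct_d[hi] - ct_d[lo])
            fs = (cs_l1[hi] - cs_l1[lo]) / (cs_d[hi] - cs_d[lo])
        ft = np.where(n > 0, ft, np.nan)
        fs = np.where(n > 0, fs, np.nan)
        frames.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": starts + window,
            "n_snps": n.astype(np.int64), "freq_T": ft, "freq_S": fs,
            "l1afd": ft - fs,
        }))
    return pd.concat(frames, ignore_index=True)


def donor_parent(
    region, profile: pd.DataFrame
) -> Tuple[str, float]:
    """Assign the donor parent of a QTL region from its mean L1AFD.

    ``region`` needs ``chrom``, ``start`` and ``end`` (1-based
    inclusive) attributes or keys.  The region value is the mean l1afd
    over overlapping windows with sites, rounded to two decimals
    (printed-table convention); a positive value assigns L1, negative
    L6, exactly zero is left undetermined.
    """
    get = region.get if hasattr(region, "get") else lambda k: getattr(region, k)
    chrom, start, end = get("chrom"), int(get("start")), int(get("end"))
    m = ((profile["chrom"] == chrom)
         & (profile["start"] <= end) & (profile["end"] - 1 >= start)
         & (profile["n_snps"] > 0))
    vals = profile.loc[m, "l1afd"].dropna()
    if vals.empty:
        raise ValueError(f"no covered L1AFD windows overlap {chrom}:{start}-{end}")
    mean_afd = round(float(vals.mean()), 2)
    if mean_afd > 0:
        return "L1", mean_afd
    if mean_afd < 0:
        return "L6", mean_afd
    return UNDETERMINED, mean_afd


def annotate_regions(regions: pd.DataFrame, profile: pd.DataFrame) -> pd.DataFrame:
    """Fill each region's ``l1afd`` and ``donor_parent`` columns; also
    records the peak-window l1afd value."""
    out = regions.copy()
    donors, afds, peaks = [], [], []
    for _, r in out.iterrows():
        donor, afd_val = donor_parent(r, profile)
        donors.append(donor)
        afds.append(afd_val)
        m = ((profile["chrom"] == r["chrom"])
             & (profile["start"] <= r["end"]) & (profile["end"] - 1 >= r["start"])
             & (profile["n_snps"] > 0))
        vals = profile.loc[m, "l1afd"].dropna()
        peaks.append(float(vals.loc[vals.abs().idxmax()]) if not vals.empty else np.nan)
    out["l1afd"] = afds
    out["l1afd_peak"] = peaks
    out["donor_parent"] = donors
    return out
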