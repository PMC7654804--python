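"""SNP-index scan statistics for QTL-seq.

Per site, the SNP-index of a pool is the fraction of reads carrying
the alternate allele; with sites oriented to the tolerant parent
(L1 = REF), the index is the sensitive-parent allele fraction, and

    delta(SNP-index) = index(S-pool) - index(T-pool)

is ~0 genome-wide under the null of no linked QTL and rises toward +1
where the tolerant bulk is enriched for the L1 allele.  Profiles are
smoothed by an unweighted mean over 1-Mb windows sliding on a 10-kb
grid.  Significance comes from Monte-Carlo simulation of the null: per
replicate each bulk independently draws its members' F2 genotypes
(1/4 : 1/2 : 1/4), forms the pool allele frequency, and samples
binomial read counts at the observed depths; windows whose observed
|delta| falls in the simulated tail (P < 0.01 by default) are merged
into QTL regions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

WINDOW = 1_000_000
STEP = 10_000


# ---------------------------------------------------------------------------
# Per-site statistics

def snp_index(alt_count: int, depth: int) -> float:
    """Alternate-allele read fraction at one site: ``alt / depth``."""
    if depth < 1:
        raise ValueError("SNP-index undefined at zero depth; depth-filter first")
    if not (0 <= alt_count <= depth):
        raise ValueError(f"alt count {alt_count} outside [0, {depth}]")
    return alt_count / depth


def delta_snp_index(index_t: float, index_s: float) -> float:
    """``index_S - index_T``: the S-pool minus T-pool SNP-index."""
    for x in (index_t, index_s):
        if not (0.0 <= x <= 1.0):
            raise ValueError(f"SNP-index {x} outside [0, 1]")
    return index_s - index_t


def site_indexes(oriented: pd.DataFrame) -> pd.DataFrame:
    """Per-site index table from an L1-oriented, depth-filtered site table.

    Columns: chrom, pos, depth_T, depth_S, index_T, index_S, delta.
    """
    out = oriented[["chrom", "pos"]].copy()
    for pool in ("T", "S"):
        depth = (oriented[f"{pool}_ref"] + oriented[f"{pool}_alt"]).to_numpy()
        if (depth < 1).any():
            raise ValueError("zero-depth site present; apply the depth filter first")
        out[f"depth_{pool}"] = depth
        out[f"index_{pool}"] = oriented[f"{pool}_alt"].to_numpy() / depth
    out["delta"] = out["index_S"] - out["index_T"]
    return out


# ---------------------------------------------------------------------------
# Sliding windows

def _window_starts(length: int, step: int = STEP) -> np.ndarray:
    return np.arange(0, max(length, 1), step, dtype=np.int64)


def window_profile(
    site_idx: pd.DataFrame,
    window: int = WINDOW,
    step: int = STEP,
    chrom_lengths: Optional[Dict[str, int]] = None,
) -> pd.DataFrame:
    """Sliding-window means of the per-site indexes.

    Windows are ``[g, g + window)`` for every grid start ``g`` on the
    ``step`` grid of each chromosome; the window value is the unweighted
    mean of the per-site indexes and ``delta`` the difference of those
    means over the identical site set.  Windows without sites are
    emitted with ``n_snps = 0`` and NaN statistics.  Sites must be
    sorted by (chrom, pos).
    """
    if window % step != 0:
        raise ValueError("window must be a multiple of step")
    pos_all = site_idx["pos"].to_numpy()
    chrom_all = site_idx["chrom"].to_numpy()
    order = np.lexsort((pos_all, chrom_all))
    if not np.array_equal(order, np.arange(len(site_idx))):
        # allow chromosome blocks in original (e.g. Chr01..Chr11) order
        block_ok = all(
            np.all(np.diff(pos_all[chrom_all == c]) > 0) for c in pd.unique(chrom_all))
        if not block_ok:
            raise ValueError("site table must be sorted by position within chromosome")
    frames = []
    for chrom in pd.unique(chrom_all):
        mask = chrom_all == chrom
        pos = pos_all[mask]
        it = site_idx.loc[mask, "index_T"].to_numpy()
        is_ = site_idx.loc[mask, "index_S"].to_numpy()
        dt = site_idx.loc[mask, "depth_T"].to_numpy()
        ds = site_idx.loc[mask, "depth_S"].to_numpy()
        length = (chrom_lengths or {}).get(chrom, int(pos.max()) if pos.size else 1)
        starts = _window_starts(length, step)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, starts + window, side="left")
        n = hi - lo
        mean_t = np.full(starts.size, np.nan)
        mean_s = np.full(starts.size, np.nan)
        delta = np.full(starts.size, np.nan)
        med_d = np.full(starts.size, np.nan)
        for k in range(starts.size):
            if n[k] == 0:
                continue
            sl = slice(lo[k], hi[k])
            mean_t[k] = np.mean(it[sl])
            mean_s[k] = np.mean(is_[sl])
            delta[k] = mean_s[k] - mean_t[k]
            med_d[k] = np.median((dt[sl] + ds[sl]) / 2.0)
        frames.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": starts + window,
            "n_snps": n.astype(np.int64), "index_T": mean_t, "index_S": mean_s,
            "delta": delta, "median_depth": med_d,
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# The simulated null

def _null_deltas(
    depth_t: np.ndarray,
    depth_s: np.ndarray,
    bulk_size_t: int,
    bulk_size_s: int,
    n_replicates: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null per-site delta draws at given depths; shape ``(n_sites, R)``.

    Each bulk draws its members' F2 genotypes — the sum of ``2 * n``
    Bernoulli(1/2) allele copies, i.e. per-individual copies are
    1/4 : 1/2 : 1/4 — then binomial read counts at its depth.
    """
    depth_t = np.atleast_1d(np.asarray(depth_t, dtype=np.int64))
    depth_s = np.atleast_1d(np.asarray(depth_s, dtype=np.int64))
    shape = (depth_t.size, n_replicates)
    p_t = rng.binomial(2 * bulk_size_t, 0.5, size=shape) / (2.0 * bulk_size_t)
    p_s = rng.binomial(2 * bulk_size_s, 0.5, size=shape) / (2.0 * bulk_size_s)
    alt_t = rng.binomial(depth_t[:, None], p_t)
    alt_s = rng.binomial(depth_s[:, None], p_s)
    return alt_s / depth_s[:, None] - alt_t / depth_t[:, None]


def simulate_null(
    depth: int,
    bulk_size: int = 9,
    n_replicates: int = 10_000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    bulk_size_s: Optional[int] = None,
    depth_s: Optional[int] = None,
) -> np.ndarray:
    """Monte-Carlo sample of per-site delta(SNP-index) under no QTL.

    Both pools use ``depth`` and ``bulk_size`` unless the ``*_s``
    overrides are given.  Deterministic under ``seed``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed) if rng is None else rng
    return _null_deltas(
        np.array([depth]), np.array([depth_s if depth_s is not None else depth]),
        bulk_size, bulk_size_s if bulk_size_s is not None else bulk_size,
        n_replicates, rng)[0]


@dataclass
class NullModel:
    """Per-depth empirical null of delta(SNP-index) and its CI bands.

    ``thresholds`` has one row per depth on the grid with the empirical
    (lo99, lo95, hi95, hi99) quantiles, smoothed so the bands never
    widen as depth increases.
    """

    bulk_size_t: int
    bulk_size_s: int
    n_replicates: int
    seed: int
    thresholds: pd.DataFrame
    samples: Optional[Dict[int, np.ndarray]] = None

    def thresholds_at(self, depth: float) -> pd.Series:
        grid = self.thresholds["depth"].to_numpy()
        d = int(np.clip(round(depth), grid.min(), grid.max()))
        return self.thresholds.set_index("depth").loc[d]


def build_null_model(
    depths: Iterable[int] = range(1, 41),
    bulk_size: int = 9,
    n_replicates: int = 10_000,
    seed: int = 0,
    bulk_size_s: Optional[int] = None,
    keep_samples: bool = False,
) -> NullModel:
    """Simulate the null at every depth on a grid and extract CI bands.

    The 95% band is the empirical (0.025, 0.975) quantile pair and the
    99% band the (0.005, 0.995) pair; isotonic smoothing (running
    min/max over increasing depth) enforces that bands only narrow as
    depth grows.
    """
    bulk_size_s = bulk_size if bulk_size_s is None else bulk_size_s
    depths = sorted(set(int(d) for d in depths))
    if not depths or depths[0] < 1:
        raise ValueError("depth grid must be non-empty with depths >= 1")
    root = np.random.SeedSequence(seed)
    rows = []
    samples = {} if keep_samples else None
    for d, ss in zip(depths, root.spawn(len(depths))):
        rng = np.random.default_rng(ss)
        draw = simulate_null(d, bulk_size, n_replicates, rng=rng, bulk_size_s=bulk_size_s)
        lo99, lo95, hi95, hi99 = np.quantile(draw, [0.005, 0.025, 0.975, 0.995])
        rows.append((d, lo99, lo95, hi95, hi99))
        if keep_samples:
            samples[d] = draw
    thr = pd.DataFrame(rows, columns=["depth", "lo99", "lo95", "hi95", "hi99"])
    thr["hi95"] = np.minimum.accumulate(thr["hi95"])
    thr["hi99"] = np.minimum.accumulate(thr["hi99"])
    thr["lo95"] = np.maximum.accumulate(thr["lo95"])
    thr["lo99"] = np.maximum.accumulate(thr["lo99"])
    return NullModel(bulk_size, bulk_size_s, n_replicates, seed, thr, samples)


def site_significance(site_idx: pd.DataFrame, null: NullModel) -> pd.DataFrame:
    """Flag sites outside the per-depth 95%/99% bands.

    A site's band is looked up at the rounded harmonic mean of its two
    pool depths, which matches the read-sampling variance term of its
    delta exactly.
    """
    out = site_idx.copy()
    dt = out["depth_T"].to_numpy().astype(float)
    ds = out["depth_S"].to_numpy().astype(float)
    hm = 2.0 * dt * ds / (dt + ds)
    grid = null.thresholds["depth"].to_numpy()
    key = np.clip(np.round(hm), grid.min(), grid.max()).astype(int)
    thr = null.thresholds.set_index("depth")
    lo95 = thr["lo95"].to_numpy()[key - grid.min()]
    hi95 = thr["hi95"].to_numpy()[key - grid.min()]
    lo99 = thr["lo99"].to_numpy()[key - grid.min()]
    hi99 = thr["hi99"].to_numpy()[key - grid.min()]
    d = out["delta"].to_numpy()
    out["band_depth"] = key
    out["significant_95"] = (d < lo95) | (d > hi95)
    out["significant_99"] = (d < lo99) | (d > hi99)
    return out


# ---------------------------------------------------------------------------
# Window-level p-values

def window_p(
    obs_delta: float,
    depths_t: Sequence[int],
    depths_s: Sequence[int],
    bulk_size_t: int = 9,
    bulk_size_s: int = 9,
    n_replicates: int = 10_000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[float, float]:
    """Empirical two-sided tail probability of a window's |delta|.

    The window-level null averages independent per-site delta draws at
    the window's observed per-site depths.  Returns ``(p, p_normal)``:
    the empirical p floored at ``1 / (n_replicates + 1)`` and a
    normal-tail approximation for sub-floor reporting.
    """
    depths_t = np.asarray(depths_t, dtype=np.int64)
    if depths_t.size == 0:
        raise ValueError("window p-value undefined for an empty window")
    rng = np.random.default_rng(seed) if rng is None else rng
    site_draws = _null_deltas(depths_t, np.asarray(depths_s, dtype=np.int64),
                              bulk_size_t, bulk_size_s, n_replicates, rng)
    null_means = site_draws.mean(axis=0)
    n_tail = int(np.count_nonzero(np.abs(null_means) >= abs(obs_delta)))
    p = (1 + n_tail) / (n_replicates + 1)
    sd = float(null_means.std())
    p_norm = float(2.0 * sps.norm.sf(abs(obs_delta), scale=sd)) if sd > 0 else float(obs_delta == 0)
    return p, p_norm


def attach_window_p(
    windows: pd.DataFrame,
    site_idx: pd.DataFrame,
    bulk_size_t: int = 9,
    bulk_size_s: int = 9,
    n_replicates: int = 2_000,
    seed: int = 0,
    window: int = WINDOW,
    chunk: int = 500,
) -> pd.DataFrame:
    """Window p-values for a whole profile, sharing per-site null draws.

    Per chromosome, one matrix of per-site null index draws is
    generated (in replicate chunks, to bound memory) and prefix sums
    give every overlapping window's null mean in O(1); the two-sided
    tail count is accumulated across chunks.  Each window's marginal
    null matches ``window_p``; draws are shared between overlapping
    windows, as are the sites themselves.
    """
    out = windows.copy()
    p_emp = np.full(len(out), np.nan)
    p_norm = np.full(len(out), np.nan)
    root = np.random.SeedSequence(seed)
    chrom_seeds = dict(zip(pd.unique(out["chrom"]), root.spawn(len(pd.unique(out["chrom"])))))
    for chrom, wdf in out.groupby("chrom", sort=False):
        smask = site_idx["chrom"].to_numpy() == chrom
        pos = site_idx.loc[smask, "pos"].to_numpy()
        dt = site_idx.loc[smask, "depth_T"].to_numpy().astype(np.int64)
        ds = site_idx.loc[smask, "depth_S"].to_numpy().astype(np.int64)
        if pos.size == 0:
            continue
        starts = wdf["start"].to_numpy()
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, starts + window, side="left")
        n = hi - lo
        active = np.flatnonzero(n > 0)
        obs = np.abs(wdf["delta"].to_numpy())
        tail = np.zeros(len(wdf), dtype=np.int64)
        ss_null = np.zeros(len(wdf))  # running sum of squared null means
        rng = np.random.default_rng(chrom_seeds[chrom])
        done = 0
        while done < n_replicates:
            r = min(chunk, n_replicates - done)
            draws = _null_deltas(dt, ds, bulk_size_t, bulk_size_s, r, rng)
            csum = np.vstack([np.zeros((1, r)), np.cumsum(draws, axis=0)])
            for k in active:
                null_mean = (csum[hi[k]] - csum[lo[k]]) / n[k]
                tail[k] += int(np.count_nonzero(np.abs(null_mean) >= obs[k]))
                ss_null[k] += float(np.sum(null_mean ** 2))
            done += r
        rows = wdf.index.to_numpy()
        sd = np.sqrt(ss_null[np.arange(len(wdf))] / n_replicates)
        for j, k in enumerate(range(len(wdf))):
            if n[k] == 0:
                continue
            p_emp[rows[k]] = (1 + tail[k]) / (n_replicates + 1)
            p_norm[rows[k]] = (2.0 * sps.norm.sf(obs[k], scale=sd[k])
                               if sd[k] > 0 else float(obs[k] == 0))
    out["p"] = p_emp
    out["p_normal"] = p_norm
    return out


# ---------------------------------------------------------------------------
# QTL region calling

def region_interval(start: int, end_inclusive: int) -> int:
    """Region length in the printed convention: ``end - start`` where
    the end is the 1-based inclusive last position of the last window."""
    return int(end_inclusive) - int(start)


def _chrom_number(chrom: str) -> str:
    m = re.search(r"(\d+)$", str(chrom))
    return str(int(m.group(1))) if m else str(chrom)


def call_qtl(
    windows: pd.DataFrame,
    site_idx: Optional[pd.DataFrame] = None,
    alpha: float = 0.01,
    window: int = WINDOW,
    null: Optional[NullModel] = None,
    criterion: str = "p",
) -> pd.DataFrame:
    """Merge significant windows into named QTL regions.

    Significance is ``p < alpha`` from the window-level Monte-Carlo
    null (``criterion="p"``, the default) or, with ``criterion="band"``
    and a :class:`NullModel`, the window delta falling outside the
    per-depth 99% band at the window's median depth.  The band route is
    far more conservative under linkage, where neighbouring sites share
    bulk genotypes and the site-independent window null understates the
    spread of window means.

    Consecutive significant windows are merged while they overlap or
    abut on the step grid; empty windows never join a region, and a
    non-significant gap wider than one window separates regions.  A
    region spans the first window's start to the last window's end - 1
    (1-based inclusive print convention), with ``interval = end -
    start``.  Names are ``qHT{chrom}.{k}`` in positional order.
    """
    if criterion == "p":
        if "p" not in windows.columns:
            raise ValueError("windows need a p column; run attach_window_p first")
        sig_mask = windows["p"] < alpha
    elif criterion == "band":
        if null is None:
            raise ValueError("band criterion needs a NullModel")
        d = windows["delta"].to_numpy()
        med = windows["median_depth"].to_numpy()
        lo = np.array([null.thresholds_at(v)["lo99"] if np.isfinite(v) else np.nan
                       for v in med])
        hi = np.array([null.thresholds_at(v)["hi99"] if np.isfinite(v) else np.nan
                       for v in med])
        sig_mask = pd.Series((d < lo) | (d > hi), index=windows.index)
    else:
        raise ValueError(f"unknown calling criterion {criterion!r}")
    sig = windows[(windows["n_snps"] > 0) & sig_mask]
    regions: List[dict] = []
    for chrom, wdf in sig.groupby("chrom", sort=False):
        wdf = wdf.sort_values("start")
        k = 0
        cur: List[pd.Series] = []
        for _, row in wdf.iterrows():
            if cur and row["start"] <= cur[-1]["start"] + window:
                cur.append(row)
            else:
                if cur:
                    k += 1
                    regions.append(_make_region(chrom, k, cur, site_idx, window))
                cur = [row]
        if cur:
            k += 1
            regions.append(_make_region(chrom, k, cur, site_idx, window))
    cols = ["name", "chrom", "start", "end", "interval", "n_snps", "n_windows",
            "delta_peak", "index_T_peak", "index_S_peak", "p",
            "delta_region", "index_T_region", "index_S_region",
            "peak_start", "peak_end"]
    return pd.DataFrame(regions, columns=cols)


def _make_region(
    chrom: str, k: int, rows: List[pd.Series],
    site_idx: Optional[pd.DataFrame], window: int,
) -> dict:
    start = int(rows[0]["start"])
    end = int(rows[-1]["start"]) + window - 1
    peak = max(rows, key=lambda r: abs(r["delta"]))
    rec = {
        "name": f"qHT{_chrom_number(chrom)}.{k}",
        "chrom": chrom, "start": start, "end": end,
        "interval": region_interval(start, end),
        "n_snps": 0, "n_windows": len(rows),
        "delta_peak": float(peak["delta"]),
        "index_T_peak": float(peak["index_T"]),
        "index_S_peak": float(peak["index_S"]),
        "p": float(min(r["p"] for r in rows)) if "p" in rows[0] else np.nan,
        "delta_region": np.nan, "index_T_region": np.nan, "index_S_region": np.nan,
        "peak_start": int(peak["start"]), "peak_end": int(peak["start"]) + window - 1,
    }
    if site_idx is not None:
        m = ((site_idx["chrom"] == chrom)
             & (site_idx["pos"] >= start) & (site_idx["pos"] <= end))
        rec["n_snps"] = int(m.sum())
        if m.any():
            it = float(site_idx.loc[m, "index_T"].mean())
            is_ = float(site_idx.loc[m, "index_S"].mean())
            rec["index_T_region"] = it
            rec["index_S_region"] = is_
            rec["delta_region"] = is_ - it
    return rec


def regions_to_bed(regions: pd.DataFrame) -> pd.DataFrame:
    """Regions in BED convention (0-based half-open)."""
    return pd.DataFrame({
        "chrom": regions["chrom"],
        "start": regions["start"].astype(int),
        "end": regions["end"].astype(int) + 1,
        "name": regions["name"],
    })


# ---------------------------------------------------------------------------
# Genome-wide summaries

def mean_delta_summary(site_idx: pd.DataFrame) -> Tuple[float, float]:
    """Genome-wide mean delta and its Monte-Carlo standard error.

    Linkage makes per-site deltas strongly correlated along a
    chromosome, so the s.e. treats chromosome means as the independent
    replicates (cluster s.e.): ``sd(chrom means) / sqrt(n_chrom)``.
    """
    means = site_idx.groupby("chrom", sort=False)["delta"].mean().to_numpy()
    mean = float(site_idx["delta"].mean())
    if means.size < 2:
        return mean, float("nan")
    return mean, float(means.std(ddof=1) / np.sqrt(means.size))
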