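"""Scan statistics: indexes, windows, the simulated null, window
p-values and region calling."""

import numpy as np
import pandas as pd
import pytest

from bsaqtl import qtlseq


def test_snp_index_arithmetic_and_errors():
    assert qtlseq.snp_index(0, 10) == 0.0
    assert qtlseq.snp_index(10, 10) == 1.0
    assert qtlseq.snp_index(7, 20) == pytest.approx(0.35)
    with pytest.raises(ValueError):
        qtlseq.snp_index(1, 0)
    with pytest.raises(ValueError):
        qtlseq.snp_index(11, 10)


def test_delta_is_s_minus_t():
    assert qtlseq.delta_snp_index(0.4, 0.4) == 0.0
    assert qtlseq.delta_snp_index(0.3, 0.7) == pytest.approx(0.4)
    with pytest.raises(ValueError):
        qtlseq.delta_snp_index(-0.1, 0.5)


def _site_table(pos, index_t, index_s, depth=13, chrom="Chr01"):
    n = len(pos)
    return pd.DataFrame({
        "chrom": chrom, "pos": np.asarray(pos, dtype=np.int64),
        "depth_T": depth, "depth_S": depth,
        "index_T": index_t, "index_S": index_s,
        "delta": np.asarray(index_s) - np.asarray(index_t),
    })


def test_single_site_fills_every_overlapping_window():
    si = _site_table([500_000], [0.2], [0.9])
    win = qtlseq.window_profile(si, chrom_lengths={"Chr01": 1_000_000})
    covered = win[win["n_snps"] > 0]
    assert len(covered) == 51  # starts 0..500k inclusive on the 10-kb grid
    assert np.allclose(covered["delta"], 0.7)
    assert (win.loc[win["n_snps"] == 0, "delta"].isna()).all()


def test_constant_delta_everywhere(rng):
    pos = np.sort(rng.choice(np.arange(1, 2_000_000), 300, replace=False))
    si = _site_table(pos, 0.3, 0.55)
    win = qtlseq.window_profile(si, chrom_lengths={"Chr01": 2_000_000})
    assert np.allclose(win.loc[win["n_snps"] > 0, "delta"], 0.25)


def test_window_profile_matches_brute_force(rng):
    """Exact (bitwise) agreement with an O(n*w) recomputation."""
    pos = np.sort(rng.choice(np.arange(1, 3_000_000), 800, replace=False))
    si = _site_table(pos, rng.random(800), rng.random(800),
                     depth=rng.integers(4, 40, 800))
    win = qtlseq.window_profile(si, chrom_lengths={"Chr01": 3_000_000})
    for _, row in win.sample(60, random_state=0).iterrows():
        mask = (si["pos"] >= row["start"]) & (si["pos"] < row["end"])
        assert row["n_snps"] == mask.sum()
        if mask.sum() == 0:
            assert np.isnan(row["delta"])
            continue
        mt = np.mean(si.loc[mask, "index_T"].to_numpy())
        ms = np.mean(si.loc[mask, "index_S"].to_numpy())
        assert row["index_T"] == mt and row["index_S"] == ms
        assert row["delta"] == ms - mt


def test_window_profile_rejects_unsorted():
    si = _site_table([5_000, 1_000], [0.1, 0.2], [0.3, 0.4])
    with pytest.raises(ValueError):
        qtlseq.window_profile(si)
    with pytest.raises(ValueError):
        qtlseq.window_profile(_site_table([1_000], [0.1], [0.2]),
                              window=1_000_000, step=30_000)


def test_null_support_and_mean():
    draws = qtlseq.simulate_null(1, bulk_size=9, n_replicates=5_000, seed=3)
    assert set(np.round(draws, 6)) <= {-1.0, 0.0, 1.0}
    draws = qtlseq.simulate_null(13, bulk_size=9, n_replicates=50_000, seed=4)
    se = draws.std() / np.sqrt(draws.size)
    assert abs(draws.mean()) < 3 * se


@pytest.mark.parametrize("bulk,depth", [(2, 5), (3, 8)])
def test_null_variance_matches_enumeration(bulk, depth):
    """Exact oracle: Var(delta) = 2 [Var(p) + E[p(1-p)]/d] with the pool
    allele count k ~ Binomial(2n, 1/2), enumerated over k."""
    from scipy.stats import binom
    n2 = 2 * bulk
    k = np.arange(n2 + 1)
    w = binom.pmf(k, n2, 0.5)
    p = k / n2
    var_p = np.sum(w * (p - 0.5) ** 2)
    e_pq = np.sum(w * p * (1 - p))
    var_exact = 2 * (var_p + e_pq / depth)
    draws = qtlseq.simulate_null(depth, bulk_size=bulk, n_replicates=400_000, seed=9)
    assert draws.var() == pytest.approx(var_exact, rel=0.02)


def test_null_model_band_structure(null_model):
    thr = null_model.thresholds
    assert (thr["hi99"] >= thr["hi95"]).all()
    assert (thr["lo99"] <= thr["lo95"]).all()
    # non-widening with depth (isotonic), and clearly narrower deep vs shallow
    assert (np.diff(thr["hi99"]) <= 1e-12).all()
    assert (np.diff(thr["lo99"]) >= -1e-12).all()
    t5, t40 = null_model.thresholds_at(5), null_model.thresholds_at(40)
    assert t40["hi99"] < t5["hi99"]
    # equal bulk sizes: bands symmetric about zero within Monte-Carlo error
    assert np.allclose(thr["hi95"], -thr["lo95"], atol=0.02)
    assert np.allclose(thr["hi99"], -thr["lo99"], atol=0.03)


def test_site_significance_uses_depth_band(null_model):
    si = _site_table([1_000, 2_000], [0.0, 0.5], [1.0, 0.5], depth=30)
    flagged = qtlseq.site_significance(si, null_model)
    assert bool(flagged.loc[0, "significant_99"]) is True
    assert bool(flagged.loc[1, "significant_99"]) is False


def test_window_p_null_and_planted():
    p0, _ = qtlseq.window_p(0.0, [13] * 20, [13] * 20, n_replicates=1_000, seed=0)
    assert p0 > 0.9
    p1, pn = qtlseq.window_p(0.9, [13] * 50, [13] * 50, n_replicates=1_000, seed=0)
    assert p1 == pytest.approx(1 / 1_001)
    assert pn < p1  # labelled parametric tail can report below the floor
    with pytest.raises(ValueError):
        qtlseq.window_p(0.5, [], [], n_replicates=100)


def test_single_site_window_p_consistent_with_depth_null():
    obs = 0.7
    p_win, _ = qtlseq.window_p(obs, [13], [13], n_replicates=40_000, seed=5)
    draws = qtlseq.simulate_null(13, 9, n_replicates=40_000, seed=6)
    p_direct = (1 + np.sum(np.abs(draws) >= obs)) / (40_000 + 1)
    assert p_win == pytest.approx(p_direct, rel=0.15)


def _grid_windows(chrom, sig_starts, all_starts, step=10_000, window=1_000_000):
    rows = []
    for s in all_starts:
        rows.append(dict(chrom=chrom, start=s, end=s + window, n_snps=5,
                         index_T=0.3, index_S=0.6, delta=0.3, median_depth=13.0,
                         p=0.001 if s in sig_starts else 0.5))
    return pd.DataFrame(rows)


def test_call_qtl_merges_and_respects_gaps():
    all_starts = list(range(0, 3_000_000, 10_000))
    sig = set(range(100_000, 210_000, 10_000)) | set(range(2_400_000, 2_420_000, 10_000))
    win = _grid_windows("Chr02", sig, all_starts)
    regions = qtlseq.call_qtl(win, alpha=0.01)
    assert list(regions["name"]) == ["qHT2.1", "qHT2.2"]
    r1 = regions.iloc[0]
    assert (r1["start"], r1["end"]) == (100_000, 1_199_999)
    assert r1["interval"] == 1_099_999 == r1["end"] - r1["start"]
    r2 = regions.iloc[1]
    assert (r2["start"], r2["end"]) == (2_400_000, 3_409_999)
    # no significant windows -> empty frame
    empty = qtlseq.call_qtl(_grid_windows("Chr02", set(), all_starts))
    assert empty.empty


def test_call_qtl_band_criterion(null_model):
    all_starts = list(range(0, 200_000, 10_000))
    win = _grid_windows("Chr03", set(), all_starts).drop(columns="p")
    win.loc[win["start"] == 50_000, "delta"] = 0.95  # far outside any band
    regions = qtlseq.call_qtl(win, null=null_model, criterion="band")
    assert list(regions["name"]) == ["qHT3.1"]
    with pytest.raises(ValueError):
        qtlseq.call_qtl(win, criterion="p")


def test_region_counts_sites(site_index_table):
    win = qtlseq.window_profile(site_index_table,
                                chrom_lengths={f"Chr{i:02d}": 2_000_000
                                               for i in range(1, 12)})
    win["p"] = np.where((win["chrom"] == "Chr02") & (win["delta"] > 0.5), 1e-4, 0.9)
    regions = qtlseq.call_qtl(win, site_index_table)
    assert len(regions) >= 1
    r = regions.iloc[0]
    m = ((site_index_table["chrom"] == r["chrom"])
         & (site_index_table["pos"] >= r["start"])
         & (site_index_table["pos"] <= r["end"]))
    assert r["n_snps"] == m.sum() > 0
    assert abs(r["delta_region"] - (site_index_table.loc[m, "index_S"].mean()
                                    - site_index_table.loc[m, "index_T"].mean())) < 1e-12


def test_pool_swap_negates_window_delta(site_index_table):
    lengths = {f"Chr{i:02d}": 2_000_000 for i in range(1, 12)}
    win = qtlseq.window_profile(site_index_table, chrom_lengths=lengths)
    swapped = site_index_table.rename(columns={
        "depth_T": "depth_S", "depth_S": "depth_T",
        "index_T": "index_S", "index_S": "index_T"})
    swapped["delta"] = swapped["index_S"] - swapped["index_T"]
    win_sw = qtlseq.window_profile(swapped, chrom_lengths=lengths)
    a, b = win["delta"].to_numpy(), win_sw["delta"].to_numpy()
    mask = ~np.isnan(a)
    assert np.array_equal(a[mask], -b[mask])  # bitwise negation
    assert np.array_equal(np.isnan(a), np.isnan(b))


def test_mean_delta_cluster_se(site_index_table):
    mean, se = qtlseq.mean_delta_summary(site_index_table)
    assert np.isfinite(mean) and se > 0
    per_chrom = site_index_table.groupby("chrom")["delta"].mean()
    assert se == pytest.approx(per_chrom.std(ddof=1) / np.sqrt(len(per_chrom)))
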