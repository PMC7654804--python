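"""Generator behaviour: marker placement, the cross, phenotypes,
pooling/read sampling, and byte-identical regeneration."""

import numpy as np
import pandas as pd
import pytest

from bsaqtl import phenotype as ph
from bsaqtl.simulate import (
    GenomeSpec,
    QtlSpec,
    SeqParams,
    SimulationConfig,
    _gamete,
    assign_lri,
    file_digest,
    pool_and_sequence,
    simulate_dataset,
    simulate_f2,
    simulate_parents,
    write_dataset,
)

from conftest import scaled_config, scaled_genome


def test_site_count_is_length_over_spacing(rng):
    genome = GenomeSpec((("Chr01", 1_000_000),), snp_spacing=10_000)
    sites = simulate_parents(genome, rng)
    assert len(sites) == 100
    assert sites["pos"].is_monotonic_increasing
    assert (sites["ref"] != sites["alt"]).all()


def test_zero_sites_is_an_error(rng):
    genome = GenomeSpec((("Chr01", 500),), snp_spacing=10_000)
    with pytest.raises(ValueError):
        simulate_parents(genome, rng)


def test_same_seed_same_sites():
    genome = scaled_genome(200_000)
    a = simulate_parents(genome, np.random.default_rng(5))
    b = simulate_parents(genome, np.random.default_rng(5))
    pd.testing.assert_frame_equal(a, b)


def test_gap_mean_approximates_spacing(rng):
    genome = GenomeSpec((("Chr01", 10_000_000),), snp_spacing=10_000)
    sites = simulate_parents(genome, rng)
    gaps = np.diff(sites["pos"].to_numpy())
    assert gaps.mean() == pytest.approx(10_000, rel=0.02)


def test_no_recombination_gives_whole_parental_chromosomes(rng):
    genome = GenomeSpec((("Chr01", 1_000_000), ("Chr02", 1_000_000)), 50_000)
    sites = simulate_parents(genome, rng)
    geno = simulate_f2(sites, genome, 10, recomb_rate=0.0, rng=rng)
    for i in range(10):
        for chrom in ("Chr01", "Chr02"):
            g = geno[i, (sites["chrom"] == chrom).to_numpy()]
            assert np.all(g == g[0])


def test_single_site_allele_frequency_is_half(rng):
    genome = GenomeSpec((("Chr01", 2_000),), 1_000)
    sites = simulate_parents(genome, rng).iloc[:1].reset_index(drop=True)
    geno = simulate_f2(sites, genome, 4_000, rng=rng)
    freq = geno.mean() / 2.0
    assert abs(freq - 0.5) < 0.02
    counts = np.bincount(geno[:, 0], minlength=3) / 4_000
    assert np.allclose(counts, [0.25, 0.5, 0.25], atol=0.03)


def test_recombinant_fraction_matches_haldane(rng):
    """Two sites 1 Mb apart at 3 cM/Mb: gamete recombinant fraction
    should match the Haldane map value (1 - exp(-2d)) / 2."""
    d_morgans = 0.03
    site_m = np.array([0.0, d_morgans])
    gametes = np.array([_gamete(site_m, 0.06, rng) for _ in range(6_000)])
    c_obs = np.mean(gametes[:, 0] != gametes[:, 1])
    c_exp = (1 - np.exp(-2 * d_morgans)) / 2
    se = np.sqrt(c_exp * (1 - c_exp) / 6_000)
    assert abs(c_obs - c_exp) < 4 * se


def test_lri_assignment_modes(rng):
    genome = GenomeSpec((("Chr01", 100_000),), 10_000)
    sites = simulate_parents(genome, rng)
    geno = np.array([[0] * 10, [1] * 10, [2] * 10], dtype=np.int8)
    qtl = (QtlSpec("Chr01", 50_000, 40.0, "recessive"),)
    lri, idx = assign_lri(geno, sites, qtl, base_lri=48, noise_sd=0, rng=rng)
    assert np.allclose(lri, [48.0, 48.0, 8.0])  # one copy -> no effect
    lri_add, _ = assign_lri(geno, sites, (QtlSpec("Chr01", 50_000, 40.0, "additive"),),
                            base_lri=48, noise_sd=0, rng=rng)
    assert np.allclose(lri_add, [48.0, 28.0, 8.0])
    lri_none, _ = assign_lri(geno, sites, (), base_lri=48, noise_sd=0, rng=rng)
    assert np.allclose(lri_none, 48.0)


def test_recessive_qtl_gives_quarter_low_class(rng):
    genome = GenomeSpec((("Chr01", 200_000),), 10_000)
    sites = simulate_parents(genome, rng)
    geno = simulate_f2(sites, genome, 1_000, rng=rng)
    lri, _ = assign_lri(geno, sites, (QtlSpec("Chr01", 100_000, 40.0),),
                        base_lri=48, noise_sd=2, rng=rng)
    frac_low = np.mean(lri < 28)
    se = np.sqrt(0.25 * 0.75 / 1_000)
    assert abs(frac_low - 0.25) < 4 * se


def test_pool_read_sampling_extremes_and_binomial(rng):
    seq0 = SeqParams(mean_depth=10, error_rate=0.0)
    fixed = np.full((4, 50), 2, dtype=np.int8)
    depth, l1 = pool_and_sequence(fixed, seq0, rng)
    assert np.array_equal(l1, depth)
    depth, l1 = pool_and_sequence(np.zeros((4, 50), dtype=np.int8), seq0, rng)
    assert l1.sum() == 0
    half = np.tile([2, 0], (25, 1)).T.astype(np.int8)  # p = 0.5 at every site
    depth, l1 = pool_and_sequence(half, SeqParams(10_000, 0.0), rng)
    frac = l1.sum() / depth.sum()
    assert 0.49 < frac < 0.51
    with pytest.raises(ValueError):
        pool_and_sequence(np.zeros((0, 5), dtype=np.int8), seq0, rng)


def test_truncation_selection_pool_frequencies(qtl_dataset):
    """Brute-force genotype-conditional selection oracle: with a strong
    recessive QTL the tolerant bulk is fixed for the L1 allele at the
    QTL while the sensitive bulk's frequency is near E[copies|not hom
    L1]/2 = 1/3."""
    ds = qtl_dataset
    j = int(ds.qtl_truth["site_index"].iloc[0])
    ids = [f"F2_{i+1:03d}" for i in range(ds.config.n_f2)]
    idx = {p: k for k, p in enumerate(ids)}
    t_geno = ds.genotypes[[idx[p] for p in ds.bulks.tolerant_ids], j]
    s_geno = ds.genotypes[[idx[p] for p in ds.bulks.sensitive_ids], j]
    freq_t = t_geno.sum() / (2 * len(t_geno))
    freq_s = s_geno.sum() / (2 * len(s_geno))
    assert freq_t > 0.9
    sd = np.sqrt((1 / 3) * (2 / 3) / 18)
    assert abs(freq_s - 1 / 3) < 4 * sd


def test_dataset_regeneration_is_byte_identical(tmp_path):
    cfg = SimulationConfig(genome=scaled_genome(200_000),
                           qtls=(QtlSpec("Chr02", 100_000),))
    ds1 = simulate_dataset(cfg, 42)
    ds2 = simulate_dataset(cfg, 42)
    p1 = write_dataset(ds1, tmp_path / "a")
    p2 = write_dataset(ds2, tmp_path / "b")
    for key in p1:
        assert file_digest(p1[key]) == file_digest(p2[key]), key
    ds3 = simulate_dataset(cfg, 43)
    assert not np.array_equal(ds3.genotypes, ds1.genotypes)


def test_dataset_bulks_respect_phenotype_ranking(qtl_dataset):
    derived = ph.phenotype_table(
        qtl_dataset.phenotypes[qtl_dataset.phenotypes["generation"] == "F2"])
    by_id = dict(zip(derived["plant_id"], derived["lri"]))
    t_max = max(by_id[p] for p in qtl_dataset.bulks.tolerant_ids)
    s_min = min(by_id[p] for p in qtl_dataset.bulks.sensitive_ids)
    assert t_max < s_min


def test_config_file_roundtrip(tmp_path):
    cfg = scaled_config()
    path = tmp_path / "config.txt"
    cfg.to_file(path)
    back = SimulationConfig.from_file(path)
    assert back.genome == cfg.genome
    assert back.qtls == cfg.qtls
    assert back.n_f2 == cfg.n_f2
    assert back.pool_depth == cfg.pool_depth


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(qtls=(QtlSpec("ChrXX", 1_000),)).validate()
    with pytest.raises(ValueError):
        SimulationConfig(n_f2=10).validate()
    with pytest.raises(ValueError):
        QtlSpec("Chr01", 1, dominance="overdominant")
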