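"""Shared fixtures: scaled simulation scenarios and the null model.

The scaled scenario keeps the study's population design (147 F2,
bulks of 9, ~13x pools, ~10x parents, one major recessive QTL) on an
11 x 2 Mb genome so whole-pipeline properties run in seconds.
"""

from __future__ import annotations

import numpy as np
import pytest

from bsaqtl import qtlseq, variants
from bsaqtl.simulate import GenomeSpec, QtlSpec, SimulationConfig, simulate_dataset


def scaled_genome(chrom_len: int = 2_000_000, spacing: int = 2_000) -> GenomeSpec:
    return GenomeSpec(tuple((f"Chr{i:02d}", chrom_len) for i in range(1, 12)), spacing)


def scaled_config(**kwargs) -> SimulationConfig:
    defaults = dict(
        genome=scaled_genome(),
        qtls=(QtlSpec("Chr02", 1_000_000, 40.0, "recessive"),),
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def qtl_dataset():
    """One planted-QTL dataset on the scaled genome, seed 1."""
    return simulate_dataset(scaled_config(), 1)


@pytest.fixture(scope="session")
def noqtl_dataset():
    """A no-QTL dataset on the scaled genome, seed 1."""
    return simulate_dataset(scaled_config(qtls=()), 1)


@pytest.fixture(scope="session")
def oriented_sites(qtl_dataset):
    filtered, _ = variants.apply_filters(qtl_dataset.sites)
    return variants.orient_to_l1(filtered)


@pytest.fixture(scope="session")
def site_index_table(oriented_sites):
    return qtlseq.site_indexes(oriented_sites)


@pytest.fixture(scope="session")
def null_model():
    """Per-depth null bands covering the Poisson(13) depth range."""
    return qtlseq.build_null_model(range(1, 41), bulk_size=9,
                                   n_replicates=100_000, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
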