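"""Published summary tables from the bottle gourd heat-tolerance
QTL-seq experiment that this pipeline's defaults emulate, transcribed
as package data.

These are inputs for validation and worked examples: the per-region
pool SNP-indexes and printed scan statistics, the sequencing
read-accounting counts, and the Sanger genotype panel of the five
candidate SNPs in the major QTL interval (10 tolerant and 16 sensitive
F2 plants plus the parents).
"""

from __future__ import annotations

from typing import Dict, List

import pandas as pd

from .effects import MarkerCall, genotype_call

#: Per-QTL scan statistics: pool SNP-indexes, printed delta, region
#: bounds (1-based inclusive), printed interval length and L1AFD.
QTL_REGIONS = pd.DataFrame(
    [
        ("qHT1.1", "Chr01", 26_260_000, 27_279_999, 12, 0.3713, 0.622, 0.25, 1_019_999, 0.13),
        ("qHT2.1", "Chr02", 11_030_000, 19_249_999, 9052, 0.3092, 0.6285, 0.32, 8_219_999, 0.24),
        ("qHT2.2", "Chr02", 19_410_000, 20_989_999, 1355, 0.3579, 0.5463, 0.19, 1_579_999, 0.11),
        ("qHT5.1", "Chr05", 39_390_000, 40_419_999, 2, 0.45, 0.8333, 0.38, 1_029_999, 0.25),
        ("qHT6.1", "Chr06", 7_460_000, 8_459_999, 934, 0.5917, 0.379, -0.21, 999_999, -0.21),
        ("qHT7.1", "Chr07", 23_220_000, 24_229_999, 5, 0.3648, 0.5812, 0.22, 1_009_999, 0.23),
        ("qHT8.1", "Chr08", 24_880_000, 25_889_999, 4, 0.1853, 0.3988, 0.21, 1_009_999, 0.19),
    ],
    columns=["name", "chrom", "start", "end", "n_snps",
             "index_T", "index_S", "delta_printed", "interval_printed", "l1afd_printed"],
)

#: Read accounting per sequenced sample: raw, trimmed/filtered and
#: uniquely mapped read counts with the printed percentages.
SEQUENCING = pd.DataFrame(
    [
        ("L1", 31_863_484, 28_368_754, 22_974_995, 89.03, 80.99),
        ("L6", 32_686_118, 29_026_164, 24_419_983, 88.80, 84.13),
        ("T-pool", 40_647_374, 35_340_578, 29_026_863, 86.94, 82.13),
        ("S-pool", 40_930_720, 35_936_306, 29_457_284, 87.80, 81.97),
    ],
    columns=["sample", "raw_reads", "trimmed_reads", "mapped_reads",
             "trimmed_pct_printed", "mapped_pct_printed"],
)

#: Parental alleles of the five candidate SNPs (L1 = tolerant parent).
MARKER_ALLELES: Dict[str, Dict[str, str]] = {
    "SNP15": {"L1": "T", "L6": "C"},
    "SNP26": {"L1": "G", "L6": "A"},
    "SNP2": {"L1": "C", "L6": "A"},
    "SNP16": {"L1": "G", "L6": "A"},
    "SNP31": {"L1": "T", "L6": "A"},
}

#: Sanger genotypes (base strings) per marker: tolerant then sensitive
#: individuals.  SNP15/SNP26 were only genotyped on the 4 + 4 pool
#: members because they showed no tolerant/sensitive difference.
MARKER_GENOTYPES: Dict[str, Dict[str, List[str]]] = {
    "SNP15": {"tolerant": ["C", "C", "C", "C"],
              "sensitive": ["C", "C", "C", "C"]},
    "SNP26": {"tolerant": ["AG", "AG", "AG", "AG"],
              "sensitive": ["AG", "AG", "AG", "AG"]},
    "SNP2": {"tolerant": ["C"] * 10,
             "sensitive": ["A", "AC", "AC", "A", "A", "A", "AC", "A",
                           "AC", "AC", "AC", "AC", "A", "AC", "AC", "AC"]},
    "SNP16": {"tolerant": ["G"] * 10,
              "sensitive": ["A", "A", "A", "A", "A", "A", "AG", "A",
                            "AG", "AG", "AG", "AG", "A", "AG", "AG", "AG"]},
    "SNP31": {"tolerant": ["T"] * 10,
              "sensitive": ["A", "AT", "AT", "A", "A", "A", "AT", "A",
                            "AT", "AT", "AT", "AT", "A", "AT", "AT", "AT"]},
}


def marker_calls(marker: str) -> List[MarkerCall]:
    """The genotype panel of one candidate SNP as MarkerCall records."""
    alleles = MARKER_ALLELES[marker]
    calls = []
    for reaction in ("tolerant", "sensitive"):
        for i, bases in enumerate(MARKER_GENOTYPES[marker][reaction], start=1):
            calls.append(MarkerCall(
                f"{reaction[0].upper()}{i}", reaction,
                genotype_call(bases, alleles["L1"], alleles["L6"])))
    return calls
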