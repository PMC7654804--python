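"""Variant-table input and the SNP filters that precede the scan.

The pipeline starts from called variants: a four-sample VCF (tolerant
parent L1, sensitive parent L6, tolerant pool, sensitive pool) with
per-sample allele depths.  Three filters produce the analysis-ready
set: a site-quality cut (QUAL >= 20), a per-pool depth window (4x to
200x inclusive), and the parent-consistency filter that keeps only
sites where both inbred parents look homozygous for opposite alleles —
the source of every informative bulk contrast.  Sites are then
oriented so the tolerant parent's allele is the REF allele, which
fixes the sign convention of every downstream statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .simulate import SAMPLES, VCF_SAMPLES

logger = logging.getLogger(__name__)

#: Count columns expected on a site table, in (ref, alt) pairs per sample.
COUNT_COLUMNS = tuple(f"{s}_{a}" for s in SAMPLES for a in ("ref", "alt"))


class VcfParseError(ValueError):
    """The variant file is malformed or lacks a required sample."""


@dataclass
class FilterReport:
    """Site counts through the filter cascade (first-failure attribution)."""

    total: int = 0
    fail_quality: int = 0
    fail_depth: int = 0
    fail_parent: int = 0
    retained: int = 0
    detail: Dict[str, int] = field(default_factory=dict)

    def check(self) -> None:
        if self.fail_quality + self.fail_depth + self.fail_parent + self.retained != self.total:
            raise AssertionError("filter report does not reconcile")

    def to_frame(self) -> pd.DataFrame:
        rows = [("total", self.total), ("fail_quality", self.fail_quality),
                ("fail_depth", self.fail_depth), ("fail_parent", self.fail_parent),
                ("retained", self.retained)]
        rows += sorted(self.detail.items())
        return pd.DataFrame(rows, columns=["category", "n_sites"])


def read_sites(
    path, sample_map: Optional[Dict[str, str]] = None
) -> Tuple[pd.DataFrame, Dict]:
    """Read biallelic SNPs with per-sample allele depths from a VCF.

    ``sample_map`` maps the canonical roles ``L1, L6, T, S`` to the VCF
    sample ids (default: ``L1, L6, T-pool, S-pool``).  Non-SNP and
    multi-allelic records are skipped and counted.  Returns the site
    table and a metadata dict with ``chrom_lengths``, ``n_skipped`` and
    the sample mapping used.
    """
    path = Path(path)
    if not path.exists():
        raise VcfParseError(f"no such file: {path}")
    sample_map = dict(zip(SAMPLES, VCF_SAMPLES)) if sample_map is None else sample_map
    vcf = VCF(str(path))
    missing = [v for v in sample_map.values() if v not in vcf.samples]
    if missing:
        raise VcfParseError(f"samples missing from {path.name}: {missing}")
    order = [vcf.samples.index(sample_map[s]) for s in SAMPLES]
    chrom_lengths = dict(zip(vcf.seqnames, vcf.seqlens)) if vcf.seqnames else {}

    rows = {c: [] for c in ("chrom", "pos", "ref", "alt", "qual")}
    counts = {c: [] for c in COUNT_COLUMNS}
    n_skipped = 0
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        ad = var.format("AD")
        if ad is None or ad.shape[1] < 2:
            raise VcfParseError(f"record {i + 1} at {var.CHROM}:{var.POS} lacks AD")
        rows["chrom"].append(var.CHROM)
        rows["pos"].append(var.POS)
        rows["ref"].append(var.REF)
        rows["alt"].append(var.ALT[0])
        rows["qual"].append(var.QUAL if var.QUAL is not None else np.nan)
        ad = np.clip(ad[:, :2], 0, None)  # cyvcf2 fills missing with negatives
        for k, s in enumerate(SAMPLES):
            counts[f"{s}_ref"].append(int(ad[order[k], 0]))
            counts[f"{s}_alt"].append(int(ad[order[k], 1]))
    df = pd.DataFrame({**rows, **counts})
    df["pos"] = df["pos"].astype(np.int64)
    if n_skipped:
        logger.info("skipped %d non-SNP/multi-allelic records in %s", n_skipped, path.name)
    if df.empty:
        logger.warning("no biallelic SNP records found in %s", path.name)
    meta = {"chrom_lengths": chrom_lengths, "n_skipped": n_skipped, "samples": sample_map}
    return df, meta


# ---------------------------------------------------------------------------
# Filters

def _pool_depths(df: pd.DataFrame, sample: str) -> np.ndarray:
    return (df[f"{sample}_ref"] + df[f"{sample}_alt"]).to_numpy()


def quality_mask(df: pd.DataFrame, min_qual: float = 20.0) -> np.ndarray:
    return (df["qual"].to_numpy() >= min_qual) & ~np.isnan(df["qual"].to_numpy())


def depth_mask(
    df: pd.DataFrame, min_depth: int = 4, max_depth: int = 200
) -> np.ndarray:
    """Per-pool depth window, inclusive at both bounds.

    The exclusion rule is "< min or > max", so sites at exactly 4x or
    200x are kept.  Applied to the two pools; parental depth enters
    only the homozygosity call in the parent-consistency filter.
    """
    ok = np.ones(len(df), dtype=bool)
    for pool in ("T", "S"):
        d = _pool_depths(df, pool)
        ok &= (d >= min_depth) & (d <= max_depth)
    return ok


def parent_mask(
    df: pd.DataFrame, het_tolerance: float = 0.1, min_parent_depth: int = 4
) -> np.ndarray:
    """Parent-consistency: both parents effectively homozygous, for
    opposite alleles.

    A parent is called homozygous when its depth is at least
    ``min_parent_depth`` and its minor-allele read fraction is at most
    ``het_tolerance`` (read sampling makes exact homozygosity too
    strict).  With biallelic records whose two alleles are the parental
    ones, pool alleles are a subset of the parental alleles by
    construction once the parents are opposite.
    """
    ok = np.ones(len(df), dtype=bool)
    majors = {}
    for parent in ("L1", "L6"):
        r = df[f"{parent}_ref"].to_numpy()
        a = df[f"{parent}_alt"].to_numpy()
        d = r + a
        with np.errstate(invalid="ignore", divide="ignore"):
            minor_frac = np.minimum(r, a) / np.where(d > 0, d, 1)
        ok &= (d >= min_parent_depth) & (minor_frac <= het_tolerance)
        majors[parent] = a > r  # True when the major allele is ALT
    ok &= majors["L1"] != majors["L6"]
    return ok


def filter_quality_depth(
    df: pd.DataFrame, min_qual: float = 20.0, min_depth: int = 4, max_depth: int = 200
) -> pd.DataFrame:
    """Keep sites with QUAL >= ``min_qual`` and both pools inside the
    inclusive depth window."""
    return df[quality_mask(df, min_qual) & depth_mask(df, min_depth, max_depth)].reset_index(drop=True)


def filter_parent_consistent(
    df: pd.DataFrame, het_tolerance: float = 0.1, min_parent_depth: int = 4
) -> pd.DataFrame:
    """Keep sites where the parents are homozygous for opposite alleles."""
    return df[parent_mask(df, het_tolerance, min_parent_depth)].reset_index(drop=True)


def apply_filters(
    df: pd.DataFrame,
    min_qual: float = 20.0,
    min_depth: int = 4,
    max_depth: int = 200,
    het_tolerance: float = 0.1,
    min_parent_depth: int = 4,
) -> Tuple[pd.DataFrame, FilterReport]:
    """Run the full cascade and report first-failure counts per stage.

    The retained set is order-independent (each filter is a pure
    per-site predicate); only the attribution of a multiply-failing
    site to a stage depends on the quality -> depth -> parent order.
    """
    q = quality_mask(df, min_qual)
    d = depth_mask(df, min_depth, max_depth)
    p = parent_mask(df, het_tolerance, min_parent_depth)
    keep = q & d & p
    report = FilterReport(
        total=len(df),
        fail_quality=int((~q).sum()),
        fail_depth=int((q & ~d).sum()),
        fail_parent=int((q & d & ~p).sum()),
        retained=int(keep.sum()),
    )
    report.detail["fail_depth_any"] = int((~d).sum())
    report.detail["fail_parent_any"] = int((~p).sum())
    report.check()
    return df[keep].reset_index(drop=True), report


# ---------------------------------------------------------------------------
# Orientation

def orient_to_l1(df: pd.DataFrame) -> pd.DataFrame:
    """Re-orient each site so the L1 (tolerant-parent) allele is REF.

    After orientation every ``*_alt`` count is the number of reads
    carrying the L6 allele, so the scan's SNP-index (alt / depth) is the
    sensitive-parent allele fraction and the allele-frequency profile's
    L1 frequency is the ref fraction.  Idempotent; requires
    parent-consistent input (raises if the parents share their major
    allele at any site).
    """
    l1_alt = df["L1_alt"].to_numpy() > df["L1_ref"].to_numpy()
    l6_alt = df["L6_alt"].to_numpy() > df["L6_ref"].to_numpy()
    if (l1_alt == l6_alt).any():
        n = int((l1_alt == l6_alt).sum())
        raise ValueError(
            f"{n} sites have parents sharing a major allele; "
            "apply filter_parent_consistent first")
    out = df.copy()
    flip = l1_alt  # L1 allele currently ALT -> swap
    ref, alt = out["ref"].to_numpy().copy(), out["alt"].to_numpy().copy()
    out["ref"] = np.where(flip, alt, ref)
    out["alt"] = np.where(flip, ref, alt)
    for s in SAMPLES:
        r = out[f"{s}_ref"].to_numpy().copy()
        a = out[f"{s}_alt"].to_numpy().copy()
        out[f"{s}_ref"] = np.where(flip, a, r)
        out[f"{s}_alt"] = np.where(flip, r, a)
    return out


# ---------------------------------------------------------------------------
# Read-accounting arithmetic (sequencing summary tables)

def percent(numerator: float, denominator: float, decimals: int = 2) -> float:
    """A percentage rounded to ``decimals`` (the table convention)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round(numerator / denominator * 100.0, decimals)


def mapping_summary(read_counts: pd.DataFrame) -> pd.DataFrame:
    """Read-retention and mapping percentages per sample.

    Input columns: ``sample, raw_reads, trimmed_reads, mapped_reads``.
    Adds ``trimmed_pct`` (trimmed / raw) and ``mapped_pct`` (uniquely
    mapped / trimmed), each to two decimals.
    """
    out = read_counts.copy()
    out["trimmed_pct"] = [percent(t, r) for t, r in zip(out.trimmed_reads, out.raw_reads)]
    out["mapped_pct"] = [percent(m, t) for m, t in zip(out.mapped_reads, out.trimmed_reads)]
    return out
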