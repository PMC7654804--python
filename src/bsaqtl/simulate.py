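"""Synthetic QTL-seq data: a biparental F2 cross, heat-injury phenotypes,
extreme-bulk pooling and short-read allele sampling.

The generator emulates the study design the scan statistics are built
for: two inbred parents (tolerant ``L1``, sensitive ``L6``) homozygous
for opposite alleles at every marker, an F2 population produced by two
recombinant gametes per individual (Haldane model, no interference),
LRI phenotypes driven by one or more QTL plus Gaussian noise, bulks of
the phenotypic extremes, and per-site read counts drawn as
Poisson-depth binomial samples of the pooled allele frequency with a
symmetric sequencing-error flip.

Defaults mirror the study conditions: an 11-chromosome ~313.4 Mb
genome with one segregating SNP per ~2 kb, 147 F2 individuals, bulks
of 9, ~13x pool and ~10x parent depth, and a single major recessive
tolerance QTL on chromosome 2 near 15 Mb whose effect (40 LRI points
below a base of 48) places the simulated parent means near the
observed ones.  A configurable fraction of sites is generated with a
heterozygous parent call so the parent-consistency filter has real
work to do; everything planted is recorded in truth tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import phenotype as ph

SAMPLES = ("L1", "L6", "T", "S")
#: VCF sample ids, in column order.
VCF_SAMPLES = ("L1", "L6", "T-pool", "S-pool")

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome names/lengths and average marker spacing."""

    chromosomes: Tuple[Tuple[str, int], ...]
    snp_spacing: int = 2_000

    def __post_init__(self):
        if not self.chromosomes or any(l <= 0 for _, l in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")
        if self.snp_spacing <= 0:
            raise ValueError("snp_spacing must be positive")

    @property
    def lengths(self) -> Dict[str, int]:
        return dict(self.chromosomes)


def default_genome(snp_spacing: int = 2_000) -> GenomeSpec:
    """An 11-chromosome genome totalling 313,397,697 bp."""
    chroms = [(f"Chr{i:02d}", 28_490_700) for i in range(1, 11)]
    chroms.append(("Chr11", 28_490_697))
    return GenomeSpec(tuple(chroms), snp_spacing)


@dataclass(frozen=True)
class QtlSpec:
    """A tolerance QTL: position, LRI-point effect and dominance mode.

    The effect is the LRI reduction conferred by the tolerant-parent
    (L1) allele under the given dominance: ``recessive`` applies it only
    to L1/L1 homozygotes, ``additive`` scales with allele copies,
    ``dominant`` applies it to carriers.
    """

    chrom: str
    pos: int
    effect: float = 40.0
    dominance: str = "recessive"

    def __post_init__(self):
        if self.effect < 0:
            raise ValueError("QTL effect must be >= 0")
        if self.dominance not in ("recessive", "additive", "dominant"):
            raise ValueError(f"unknown dominance mode {self.dominance!r}")

    def effect_of(self, copies: np.ndarray) -> np.ndarray:
        copies = np.asarray(copies)
        if self.dominance == "recessive":
            return np.where(copies == 2, self.effect, 0.0)
        if self.dominance == "dominant":
            return np.where(copies >= 1, self.effect, 0.0)
        return copies / 2.0 * self.effect


@dataclass(frozen=True)
class SeqParams:
    """Read-sampling parameters: Poisson mean depth and per-base error."""

    mean_depth: float = 13.0
    error_rate: float = 0.001

    def __post_init__(self):
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not (0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must lie in [0, 0.5)")


@dataclass
class SimulationConfig:
    """Full scenario description; defaults reproduce the study design."""

    genome: GenomeSpec = field(default_factory=default_genome)
    qtls: Tuple[QtlSpec, ...] = (QtlSpec("Chr02", 15_000_000, 40.0, "recessive"),)
    n_f2: int = 147
    bulk_size: int = 9
    pool_depth: float = 13.0
    parent_depth: float = 10.0
    error_rate: float = 0.001
    het_parent_rate: float = 0.2
    lowqual_rate: float = 0.02
    base_lri: float = 48.0
    noise_sd: float = 8.0
    recomb_rate: float = 3.0  # cM per Mb

    def validate(self) -> None:
        lengths = self.genome.lengths
        for q in self.qtls:
            if q.chrom not in lengths or not (1 <= q.pos <= lengths[q.chrom]):
                raise ValueError(f"QTL at {q.chrom}:{q.pos} outside the genome")
        if self.n_f2 < 2 * self.bulk_size:
            raise ValueError("population too small for two disjoint bulks")
        SeqParams(self.pool_depth, self.error_rate)
        SeqParams(self.parent_depth, self.error_rate)
        if not (0 <= self.het_parent_rate < 1) or not (0 <= self.lowqual_rate < 1):
            raise ValueError("rates must lie in [0, 1)")

    # -- flat key=value config file ------------------------------------
    def to_file(self, path) -> None:
        lines = []
        lines.append("chromosomes=" + ";".join(f"{c}:{l}" for c, l in self.genome.chromosomes))
        lines.append(f"snp_spacing={self.genome.snp_spacing}")
        lines.append("qtls=" + ";".join(
            f"{q.chrom}:{q.pos}:{q.effect:g}:{q.dominance}" for q in self.qtls))
        for key in ("n_f2", "bulk_size", "pool_depth", "parent_depth", "error_rate",
                    "het_parent_rate", "lowqual_rate", "base_lri", "noise_sd", "recomb_rate"):
            lines.append(f"{key}={getattr(self, key)}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        kv = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            kv[key.strip()] = val.strip()
        chroms = tuple(
            (c.split(":")[0], int(c.split(":")[1])) for c in kv["chromosomes"].split(";"))
        genome = GenomeSpec(chroms, int(kv.get("snp_spacing", 2000)))
        qtls = tuple(
            QtlSpec(p[0], int(p[1]), float(p[2]), p[3])
            for p in (q.split(":") for q in kv["qtls"].split(";") if q))
        ints = {"n_f2", "bulk_size"}
        kwargs = {}
        for key in ("n_f2", "bulk_size", "pool_depth", "parent_depth", "error_rate",
                    "het_parent_rate", "lowqual_rate", "base_lri", "noise_sd", "recomb_rate"):
            if key in kv:
                kwargs[key] = int(kv[key]) if key in ints else float(kv[key])
        cfg = cls(genome=genome, qtls=qtls, **kwargs)
        cfg.validate()
        return cfg


# ---------------------------------------------------------------------------
# Parents and markers

def simulate_parents(
    genome: GenomeSpec,
    rng: np.random.Generator,
    het_parent_rate: float = 0.0,
    lowqual_rate: float = 0.0,
) -> pd.DataFrame:
    """Place biallelic markers along the genome with the parents fixed for
    opposite alleles.

    ``floor(length / spacing)`` sites per chromosome, one per spacing
    bin with uniform jitter inside the bin (so inter-site gaps average
    the spacing).  Each site's L1 allele is randomly the REF or ALT base
    of the (third-party) reference, which downstream orientation must
    undo.  Fractions of sites are planted with a heterozygous parent
    call and/or a sub-threshold quality score, flagged in the output.
    """
    rows = []
    for chrom, length in genome.chromosomes:
        n = length // genome.snp_spacing
        if n == 0:
            continue
        offsets = rng.integers(1, genome.snp_spacing + 1, size=n)
        pos = np.arange(n, dtype=np.int64) * genome.snp_spacing + offsets
        ref_idx = rng.integers(0, 4, size=n)
        alt_shift = rng.integers(1, 4, size=n)
        alt_idx = (ref_idx + alt_shift) % 4
        l1_is_ref = rng.random(n) < 0.5
        het = rng.random(n) < het_parent_rate
        het_parent = np.where(het, np.where(rng.random(n) < 0.5, "L1", "L6"), "")
        low = rng.random(n) < lowqual_rate
        qual = np.where(low, rng.uniform(2.0, 19.5, size=n), rng.uniform(30.0, 60.0, size=n))
        rows.append(pd.DataFrame({
            "chrom": chrom,
            "pos": pos,
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
            "l1_is_ref": l1_is_ref,
            "het_parent": het_parent,
            "qual": np.round(qual, 2),
            "qual_low": low,
        }))
    if not rows:
        raise ValueError("genome yields zero marker sites")
    sites = pd.concat(rows, ignore_index=True)
    return sites


# ---------------------------------------------------------------------------
# The cross

def _gamete(
    site_morgans: np.ndarray, chrom_morgans: float, rng: np.random.Generator
) -> np.ndarray:
    """One recombinant gamete: 0/1 indicator of the L1 allele per site."""
    start = int(rng.integers(2))
    k = int(rng.poisson(chrom_morgans))
    if k == 0:
        return np.full(site_morgans.size, start, dtype=np.int8)
    xo = np.sort(rng.uniform(0.0, chrom_morgans, size=k))
    return ((start + np.searchsorted(xo, site_morgans)) % 2).astype(np.int8)


def simulate_f2(
    sites: pd.DataFrame,
    genome: GenomeSpec,
    n: int,
    recomb_rate: float = 3.0,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """F2 genotypes as L1-allele copy counts, shape ``(n, n_sites)``.

    Each individual is the union of two independent gametes; crossover
    counts per chromosome are Poisson in the chromosome's genetic
    length (Haldane, ``recomb_rate`` cM/Mb), positions uniform.
    """
    if n < 1:
        raise ValueError("need at least one F2 individual")
    rng = np.random.default_rng() if rng is None else rng
    morgans_per_bp = recomb_rate / 100.0 / 1e6
    geno = np.empty((n, len(sites)), dtype=np.int8)
    lengths = genome.lengths
    for chrom, chrom_len in genome.chromosomes:
        idx = np.flatnonzero(sites["chrom"].to_numpy() == chrom)
        if idx.size == 0:
            continue
        site_m = sites["pos"].to_numpy()[idx] * morgans_per_bp
        chrom_m = lengths[chrom] * morgans_per_bp
        for i in range(n):
            geno[i, idx] = _gamete(site_m, chrom_m, rng) + _gamete(site_m, chrom_m, rng)
    return geno


# ---------------------------------------------------------------------------
# Phenotypes

def assign_lri(
    genotypes: np.ndarray,
    sites: pd.DataFrame,
    qtls: Sequence[QtlSpec],
    base_lri: float = 48.0,
    noise_sd: float = 8.0,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[np.ndarray, List[int]]:
    """LRI per individual: ``base - sum(QTL effects) + N(0, sd)``, in [0, 100].

    Each QTL acts through the genotype at the marker site nearest to its
    position on its chromosome; returns the phenotypes and those site
    indices (in ``sites`` order, one per QTL).
    """
    rng = np.random.default_rng() if rng is None else rng
    n = genotypes.shape[0]
    lri = np.full(n, float(base_lri))
    qtl_sites: List[int] = []
    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    for q in qtls:
        idx = np.flatnonzero(chrom_arr == q.chrom)
        if idx.size == 0:
            raise ValueError(f"no marker sites on {q.chrom} for QTL at {q.pos}")
        j = idx[np.argmin(np.abs(pos_arr[idx] - q.pos))]
        qtl_sites.append(int(j))
        lri -= q.effect_of(genotypes[:, j])
    if noise_sd > 0:
        lri += rng.normal(0.0, noise_sd, size=n)
    return np.clip(lri, 0.0, 100.0), qtl_sites


def _readings_from_lri(
    ids: Sequence[str], lri: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """Invent conductivity readings consistent with given LRI values.

    Pre-heat REC is drawn in a realistic 8-15% band; the post-heat REC
    is back-solved from the LRI definition, and S1/S2 pairs constructed
    so the phenotype module recovers the assigned LRI.
    """
    lri = np.asarray(lri, dtype=float)
    rec_ck = rng.uniform(8.0, 15.0, size=lri.size)
    rec_t = lri / 100.0 * (100.0 - rec_ck) + rec_ck
    s2_before = np.round(rng.uniform(1.5, 2.5, size=lri.size), 4)
    s2_after = np.round(rng.uniform(1.5, 2.5, size=lri.size), 4)
    return pd.DataFrame({
        "plant_id": list(ids),
        "s1_before": rec_ck / 100.0 * s2_before,
        "s2_before": s2_before,
        "s1_after": rec_t / 100.0 * s2_after,
        "s2_after": s2_after,
    })


def simulate_reference_lines(
    config: SimulationConfig, rng: np.random.Generator, n_each: int = 10
) -> pd.DataFrame:
    """Phenotypes for the fixed genotypes L1 (tolerant parent), L6
    (sensitive parent) and their F1, ``n_each`` plants per line.

    L1 is homozygous tolerant at every QTL (all effects apply), L6
    homozygous sensitive (none), and the F1 heterozygous (effects apply
    per dominance; none under the default recessive mode — the F1
    phenocopies the sensitive parent).
    """
    out = []
    for label, copies in (("L1", 2), ("L6", 0), ("F1", 1)):
        shift = sum(float(q.effect_of(np.array([copies]))[0]) for q in config.qtls)
        lri = np.clip(
            config.base_lri - shift + rng.normal(0, config.noise_sd, size=n_each), 0, 100)
        df = _readings_from_lri([f"{label}_{i+1:02d}" for i in range(n_each)], lri, rng)
        df.insert(1, "generation", label)
        out.append(df)
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# Pooling and read sampling

def pool_and_sequence(
    bulk_genotypes: np.ndarray,
    seq: SeqParams,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """Sample reads from an equal-contribution DNA pool of a bulk.

    The pool's true L1-allele frequency at each site is the bulk's mean
    allele dosage ``sum(copies) / (2n)``; per-site depth is Poisson and
    the L1 read count binomial at the error-adjusted frequency
    ``p (1 - e) + (1 - p) e``.  Returns ``(depth, l1_count)`` arrays.
    """
    if bulk_genotypes.ndim != 2 or bulk_genotypes.shape[0] == 0:
        raise ValueError("bulk must contain at least one individual")
    p = bulk_genotypes.sum(axis=0) / (2.0 * bulk_genotypes.shape[0])
    depth = rng.poisson(seq.mean_depth, size=p.size)
    p_read = p * (1.0 - seq.error_rate) + (1.0 - p) * seq.error_rate
    l1 = rng.binomial(depth, p_read)
    return depth, l1


def _sequence_parent(
    sites: pd.DataFrame, parent: str, seq: SeqParams, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Read counts for one inbred parent, honouring planted het calls."""
    n = len(sites)
    hom_l1 = 1.0 if parent == "L1" else 0.0
    p = np.where(sites["het_parent"].to_numpy() == parent, 0.5, hom_l1)
    depth = rng.poisson(seq.mean_depth, size=n)
    p_read = p * (1.0 - seq.error_rate) + (1.0 - p) * seq.error_rate
    return depth, rng.binomial(depth, p_read)


# ---------------------------------------------------------------------------
# End-to-end dataset

@dataclass
class Dataset:
    """An in-memory synthetic QTL-seq experiment."""

    config: SimulationConfig
    sites: pd.DataFrame          # marker truth + per-sample read counts
    genotypes: np.ndarray        # (n_f2, n_sites) L1-allele copies
    phenotypes: pd.DataFrame     # conductivity readings + derived LRI
    bulks: ph.BulkSelection
    qtl_truth: pd.DataFrame      # one row per QTL with its marker site


def simulate_dataset(config: SimulationConfig, seed: int) -> Dataset:
    """Run the full generator: markers, cross, phenotypes, bulks, reads."""
    config.validate()
    root = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in root.spawn(6)]
    r_sites, r_cross, r_pheno, r_reads, r_ec, r_ref = rngs

    sites = simulate_parents(
        config.genome, r_sites, config.het_parent_rate, config.lowqual_rate)
    geno = simulate_f2(sites, config.genome, config.n_f2, config.recomb_rate, r_cross)
    lri, qtl_site_idx = assign_lri(
        geno, sites, config.qtls, config.base_lri, config.noise_sd, r_pheno)

    ids = [f"F2_{i+1:03d}" for i in range(config.n_f2)]
    readings = _readings_from_lri(ids, lri, r_ec)
    readings.insert(1, "generation", "F2")
    ref_lines = simulate_reference_lines(config, r_ref)
    pheno = pd.concat([ref_lines, readings], ignore_index=True)
    derived = ph.phenotype_table(readings)
    plants = ph.phenotypes_from_table(derived)
    bulks = ph.select_bulks(plants, config.bulk_size)

    id_index = {pid: i for i, pid in enumerate(ids)}
    t_rows = [id_index[p] for p in bulks.tolerant_ids]
    s_rows = [id_index[p] for p in bulks.sensitive_ids]

    pool_seq = SeqParams(config.pool_depth, config.error_rate)
    parent_seq = SeqParams(config.parent_depth, config.error_rate)
    counts = {}
    counts["L1"] = _sequence_parent(sites, "L1", parent_seq, r_reads)
    counts["L6"] = _sequence_parent(sites, "L6", parent_seq, r_reads)
    counts["T"] = pool_and_sequence(geno[t_rows], pool_seq, r_reads)
    counts["S"] = pool_and_sequence(geno[s_rows], pool_seq, r_reads)

    out = sites.copy()
    l1_is_ref = out["l1_is_ref"].to_numpy()
    for name in SAMPLES:
        depth, l1_reads = counts[name]
        l6_reads = depth - l1_reads
        out[f"{name}_ref"] = np.where(l1_is_ref, l1_reads, l6_reads)
        out[f"{name}_alt"] = np.where(l1_is_ref, l6_reads, l1_reads)

    qtl_truth = pd.DataFrame({
        "chrom": [q.chrom for q in config.qtls],
        "pos": [q.pos for q in config.qtls],
        "effect": [q.effect for q in config.qtls],
        "dominance": [q.dominance for q in config.qtls],
        "site_index": qtl_site_idx,
        "site_pos": [int(sites["pos"].iloc[j]) for j in qtl_site_idx],
    })
    return Dataset(config, out, geno, pheno, bulks, qtl_truth)


# ---------------------------------------------------------------------------
# File output

def write_vcf(sites: pd.DataFrame, chrom_lengths: Dict[str, int], path) -> None:
    """Write the four-sample site table as an uncompressed VCF 4.2 file
    with per-sample AD and DP."""
    lines = ["##fileformat=VCFv4.2", "##source=bsaqtl-simulate"]
    for chrom, length in chrom_lengths.items():
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Read depth per allele (ref,alt)">')
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(VCF_SAMPLES))
    cols = {s: (sites[f"{s}_ref"].to_numpy(), sites[f"{s}_alt"].to_numpy())
            for s in SAMPLES}
    chroms = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    ref = sites["ref"].to_numpy()
    alt = sites["alt"].to_numpy()
    qual = sites["qual"].to_numpy()
    for i in range(len(sites)):
        fields = [chroms[i], str(pos[i]), ".", ref[i], alt[i],
                  f"{qual[i]:.2f}", "PASS", ".", "AD:DP"]
        for s in SAMPLES:
            r, a = cols[s][0][i], cols[s][1][i]
            fields.append(f"{r},{a}:{r + a}")
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def write_dataset(ds: Dataset, outdir, include_genotypes: bool = False) -> Dict[str, Path]:
    """Write the dataset as VCF + phenotype TSV + truth TSVs.

    Regeneration under the same seed is byte-identical.  The full
    genotype matrix is large and only written on request; the QTL truth
    table always records every individual's genotype at each QTL site.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "calls.vcf",
        "phenotypes": outdir / "phenotypes.tsv",
        "bulks": outdir / "bulks.tsv",
        "truth_sites": outdir / "truth_sites.tsv",
        "truth_qtl": outdir / "truth_qtl.tsv",
        "config": outdir / "config.txt",
    }
    write_vcf(ds.sites, ds.config.genome.lengths, paths["vcf"])
    ds.phenotypes.to_csv(paths["phenotypes"], sep="\t", index=False, float_format="%.6f")
    ph.write_bulks(ds.bulks, paths["bulks"])
    truth_cols = ["chrom", "pos", "ref", "alt", "l1_is_ref", "het_parent", "qual", "qual_low"]
    ds.sites[truth_cols].to_csv(paths["truth_sites"], sep="\t", index=False)
    qtl = ds.qtl_truth.copy()
    qtl["genotypes"] = [
        "".join(str(g) for g in ds.genotypes[:, j]) for j in qtl["site_index"]]
    qtl.to_csv(paths["truth_qtl"], sep="\t", index=False)
    ds.config.to_file(paths["config"])
    if include_genotypes:
        paths["genotypes"] = outdir / "truth_genotypes.tsv"
        gdf = pd.DataFrame(ds.genotypes.T,
                           columns=[f"F2_{i+1:03d}" for i in range(ds.genotypes.shape[0])])
        gdf.insert(0, "pos", ds.sites["pos"].to_numpy())
        gdf.insert(0, "chrom", ds.sites["chrom"].to_numpy())
        gdf.to_csv(paths["genotypes"], sep="\t", index=False)
    return paths


def file_digest(path) -> str:
    """SHA-256 of a file, for byte-identity checks."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
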