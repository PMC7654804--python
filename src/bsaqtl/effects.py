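"""Candidate-SNP triage inside a QTL interval.

Once a region is called, the SNPs inside it are placed against gene
models (intergenic / intronic / coding), coding variants are
classified at the codon level (synonymous, nonsynonymous, stop-gain,
stop-loss) by translating the reference and alternate codons
strand-aware, and candidates are ranked by their site-level
delta(SNP-index).  Marker validation follows the recessive-tolerance
model: a tolerant plant must be homozygous for the tolerant-parent
allele, while sensitive plants may be heterozygous or homozygous for
the other allele.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd
from Bio.Seq import Seq
from pyfaidx import Fasta

INTERGENIC = "intergenic"
INTRONIC = "intronic"
SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"
STOP_GAIN = "stop-gain"
STOP_LOSS = "stop-loss"

#: Categories that change the protein and qualify as candidates.
PROTEIN_CHANGING = (NONSYNONYMOUS, STOP_GAIN, STOP_LOSS)

HOM_L1 = "hom_l1"
HET = "het"
HOM_L6 = "hom_l6"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class DataIntegrityError(ValueError):
    """Reference sequence and variant record disagree."""


@dataclass(frozen=True)
class GeneModel:
    """A gene's CDS layout: 1-based inclusive segments on one strand.

    Segments are stored in ascending genomic order; transcription order
    is derived from the strand.  A total CDS length not divisible by
    three marks a partial model (flagged, still usable up to the last
    complete codon).
    """

    gene_id: str
    chrom: str
    strand: str
    cds: Tuple[Tuple[int, int], ...]
    span: Tuple[int, int] = None  # gene bounds; defaults to the CDS hull

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or - (got {self.strand!r})")
        segs = tuple(sorted((int(a), int(b)) for a, b in self.cds))
        if not segs or any(a > b for a, b in segs):
            raise ValueError("CDS segments must be non-empty 1-based inclusive intervals")
        for (a1, b1), (a2, b2) in zip(segs, segs[1:]):
            if a2 <= b1:
                raise ValueError("CDS segments must not overlap")
        object.__setattr__(self, "cds", segs)
        if self.span is None:
            object.__setattr__(self, "span", (segs[0][0], segs[-1][1]))

    @property
    def cds_length(self) -> int:
        return sum(b - a + 1 for a, b in self.cds)

    @property
    def partial(self) -> bool:
        return self.cds_length % 3 != 0

    def contains(self, pos: int) -> bool:
        return self.span[0] <= pos <= self.span[1]

    def cds_offset(self, pos: int) -> Optional[int]:
        """0-based offset of ``pos`` in the spliced CDS (transcription
        order), or None when the position is non-coding."""
        segs = self.cds if self.strand == "+" else tuple(reversed(self.cds))
        off = 0
        for a, b in segs:
            if a <= pos <= b:
                return off + (pos - a if self.strand == "+" else b - pos)
            off += b - a + 1
        return None


@dataclass(frozen=True)
class SnpEffect:
    """One SNP's location/effect classification."""

    snp_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: Optional[str]
    category: str
    aa_change: Optional[str] = None  # e.g. "V -> I" for protein-changing SNPs


@dataclass(frozen=True)
class MarkerCall:
    """One plant's genotype at a candidate SNP plus its phenotype class."""

    individual_id: str
    reaction: str            # "tolerant" | "sensitive"
    genotype: str            # HOM_L1 | HET | HOM_L6


@dataclass(frozen=True)
class ConcordanceResult:
    n_concordant: Optional[int]
    n_total: int
    polymorphic: bool


# ---------------------------------------------------------------------------
# Reference and gene-model input

def read_reference(path) -> Mapping[str, str]:
    """Load a FASTA reference as an upper-case per-chromosome mapping."""
    return {name: str(rec[:]).upper() for name, rec in Fasta(str(path)).items()}


def read_gene_models(path) -> List[GeneModel]:
    """Read gene models from a GFF3-dialect file (gene + CDS features).

    CDS features are grouped to their gene through the ``Parent``
    attribute chain (CDS -> mRNA -> gene, or CDS -> gene directly).
    """
    genes: Dict[str, dict] = {}
    parents: Dict[str, str] = {}
    cds_rows: List[Tuple[str, int, int]] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) != 9:
            raise ValueError(f"malformed GFF3 line: {line!r}")
        chrom, _, ftype, start, end, _, strand, _, attrs = f
        attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
        if ftype == "gene":
            gid = attr.get("ID")
            genes[gid] = {"chrom": chrom, "strand": strand,
                          "span": (int(start), int(end)), "cds": []}
        elif ftype == "mRNA":
            parents[attr.get("ID")] = attr.get("Parent")
        elif ftype == "CDS":
            cds_rows.append((attr.get("Parent"), int(start), int(end)))
    for parent, start, end in cds_rows:
        gid = parents.get(parent, parent)
        if gid not in genes:
            genes[gid] = {"chrom": None, "strand": "+", "span": None, "cds": []}
        genes[gid]["cds"].append((start, end))
    out = []
    for gid, g in genes.items():
        if not g["cds"]:
            continue
        out.append(GeneModel(gid, g["chrom"], g["strand"], tuple(g["cds"]), g["span"]))
    return out


# ---------------------------------------------------------------------------
# Effect classification

def _spliced_cds(gene: GeneModel, chrom_seq: str) -> str:
    parts = [chrom_seq[a - 1:b] for a, b in gene.cds]
    seq = "".join(parts)
    return seq if gene.strand == "+" else seq[::-1].translate(_COMPLEMENT)


def classify_site(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    genes: Sequence[GeneModel],
    reference: Mapping[str, str],
    snp_id: Optional[str] = None,
) -> SnpEffect:
    """Classify one SNP against gene models and the reference sequence.

    Raises :class:`DataIntegrityError` when the reference base at the
    position differs from the record's ref allele; IUPAC ambiguity
    codes are rejected.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref not in "ACGT" or alt not in "ACGT" or ref == alt:
        raise ValueError(f"need distinct unambiguous alleles (got {ref}/{alt})")
    if chrom not in reference or pos > len(reference[chrom]) or pos < 1:
        raise DataIntegrityError(f"reference does not cover {chrom}:{pos}")
    chrom_seq = reference[chrom]
    if chrom_seq[pos - 1] != ref:
        raise DataIntegrityError(
            f"{chrom}:{pos} reference base {chrom_seq[pos - 1]} != ref allele {ref}")
    sid = snp_id or f"{chrom}:{pos}"
    hits = [g for g in genes if g.chrom == chrom and g.contains(pos)]
    if not hits:
        return SnpEffect(sid, chrom, pos, ref, alt, None, INTERGENIC)
    for gene in hits:
        off = gene.cds_offset(pos)
        if off is None:
            continue
        cds = _spliced_cds(gene, chrom_seq)
        codon_i, codon_pos = divmod(off, 3)
        codon = cds[codon_i * 3: codon_i * 3 + 3]
        if len(codon) < 3:  # partial trailing codon on a flagged-partial model
            return SnpEffect(sid, chrom, pos, ref, alt, gene.gene_id, INTRONIC)
        alt_cs = alt if gene.strand == "+" else alt.translate(_COMPLEMENT)
        mutated = codon[:codon_pos] + alt_cs + codon[codon_pos + 1:]
        aa_ref = str(Seq(codon).translate())
        aa_alt = str(Seq(mutated).translate())
        if aa_ref == aa_alt:
            return SnpEffect(sid, chrom, pos, ref, alt, gene.gene_id, SYNONYMOUS)
        if aa_alt == "*":
            cat = STOP_GAIN
        elif aa_ref == "*":
            cat = STOP_LOSS
        else:
            cat = NONSYNONYMOUS
        return SnpEffect(sid, chrom, pos, ref, alt, gene.gene_id, cat,
                         f"{aa_ref} -> {aa_alt}")
    # inside a gene span but in no CDS segment: genic non-coding
    return SnpEffect(sid, chrom, pos, ref, alt, hits[0].gene_id, INTRONIC)


def effects_table(effects: Iterable[SnpEffect]) -> pd.DataFrame:
    return pd.DataFrame([dataclass_dict(e) for e in effects])


def dataclass_dict(e) -> dict:
    from dataclasses import asdict
    return asdict(e)


# ---------------------------------------------------------------------------
# Candidate ranking

def rank_candidates(
    effects: pd.DataFrame, delta_by_site: pd.DataFrame, min_delta: float = 0.5
) -> pd.DataFrame:
    """Protein-changing SNPs with site-level delta >= ``min_delta``,
    sorted by delta descending.

    ``effects`` needs chrom/pos/category columns; ``delta_by_site``
    chrom/pos/delta (a :func:`bsaqtl.qtlseq.site_indexes` table works).
    """
    merged = effects.merge(delta_by_site[["chrom", "pos", "delta"]],
                           on=["chrom", "pos"], how="left")
    keep = merged["category"].isin(PROTEIN_CHANGING) & (merged["delta"] >= min_delta)
    out = merged[keep].sort_values(["delta", "chrom", "pos"],
                                   ascending=[False, True, True])
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Marker-trait concordance

def genotype_call(bases: str, l1_allele: str, l6_allele: str) -> str:
    """Classify a Sanger genotype string (e.g. ``"C"``, ``"AC"``) against
    the parental alleles."""
    obs = set(bases.upper())
    if obs == {l1_allele.upper()}:
        return HOM_L1
    if obs == {l6_allele.upper()}:
        return HOM_L6
    if obs == {l1_allele.upper(), l6_allele.upper()}:
        return HET
    raise ValueError(f"genotype {bases!r} not composed of parental alleles "
                     f"{l1_allele}/{l6_allele}")


def marker_concordance(
    calls: Sequence[MarkerCall], model: str = "recessive"
) -> ConcordanceResult:
    """Score genotype-phenotype concordance at a candidate marker.

    Under the recessive-tolerance model a call is concordant iff a
    tolerant plant is homozygous for the L1 allele and a sensitive
    plant is heterozygous or homozygous L6.  The optional dominant
    model instead requires sensitive plants to be homozygous L6.  A
    marker where every individual falls in one genotype class is
    non-polymorphic: its concordance is undefined and reported None.
    """
    if not calls:
        raise ValueError("need at least one marker call")
    if model not in ("recessive", "dominant"):
        raise ValueError(f"unknown concordance model {model!r}")
    genotypes = {c.genotype for c in calls}
    if len(genotypes) == 1:
        return ConcordanceResult(None, len(calls), polymorphic=False)
    n_conc = 0
    for c in calls:
        if model == "recessive":
            ok = (c.genotype == HOM_L1) if c.reaction == "tolerant" \
                else c.genotype in (HET, HOM_L6)
        else:
            ok = c.genotype in (HOM_L1, HET) if c.reaction == "tolerant" \
                else c.genotype == HOM_L6
        n_conc += int(ok)
    return ConcordanceResult(n_conc, len(calls), polymorphic=True)


def concordance_table(
    markers: Mapping[str, Sequence[MarkerCall]], model: str = "recessive"
) -> pd.DataFrame:
    """Concordance summary for several markers (rows: marker id)."""
    rows = []
    for mid, calls in markers.items():
        res = marker_concordance(calls, model)
        rows.append((mid, res.n_concordant, res.n_total, res.polymorphic))
    return pd.DataFrame(rows, columns=["marker", "n_concordant", "n_total", "polymorphic"])
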