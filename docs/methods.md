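# Methods

## Phenotype model

REC = S1/S2 × 100% is the conductivity of a leaf-disc soak relative to
the fully-lysed (boiled) sample, in percent; LRI rescales the
heat-induced REC change by the remaining headroom,
LRI = (Lt − Lck)/(100 − Lck) × 100, with Lck the pre-heat and Lt the
post-heat REC.  We fix Lck = control (pre-heat) so that larger LRI
means more injury; the opposite labelling would make every tolerant
plant score high.  LRI may be negative (a plant leaking less after
heat than before); such transgressive values are reported as computed,
not clipped, because truncating them would bias bulk selection.
Classification uses a strict `LRI < threshold` for tolerance (default
threshold 10%), so a plant exactly at the threshold is sensitive —
the tolerant/sensitive definitions are open at the boundary and the
conservative assignment keeps marginal plants out of the tolerant
bulk.  Bulk selection takes the `n` lowest- and `n` highest-LRI plants
(default 9 + 9 from 147 F2); ties at a cutoff are broken by plant id
so selection is deterministic and order-invariant.

## Synthetic data generator

The generator emulates the sequencing experiment the scan is designed
for, at the level of *called variants* (it does not simulate reads,
alignment artifacts, indels or multi-allelic sites):

- **Markers.** `floor(length/spacing)` biallelic sites per chromosome,
  one per spacing bin with uniform jitter.  Default spacing 2 kb
  reproduces the ~1 SNP / 2 kb density of a typical
  parent-divergent F2 panel on a 313.4 Mb, 11-chromosome genome.
  Each site's tolerant-parent allele is randomly the REF or ALT base
  of the third-party reference, so downstream orientation is
  non-trivial, as in real data mapped to an unrelated cultivar.
- **Cross.** Gametes recombine under Haldane's model (no
  interference): crossover counts are Poisson in the chromosome's
  genetic length at 3 cM/Mb (default), positions uniform.  F2
  genotypes are the sum of two independent gametes, giving the
  1/4 : 1/2 : 1/4 segregation the null model assumes.
- **Phenotypes.** LRI = base − Σ QTL effects + N(0, sd), truncated to
  [0, 100].  Defaults: base 48, noise sd 8, one recessive QTL of 40
  LRI points on chromosome 2 — placing the simulated parent means
  near the observed ones (sensitive ≈ 47%, tolerant ≈ 10%) and making
  the F1 phenocopy the sensitive parent.  Conductivity readings are
  back-solved from the assigned LRI so the phenotype module's
  arithmetic round-trips.
- **Reads.** A pool's true L1-allele frequency is the bulk's mean
  allele dosage; depth is Poisson (13× pools, 10× parents by
  default) and allele counts binomial at the error-adjusted frequency
  p(1−e) + (1−p)e with e = 0.001.  Sequencing error is a symmetric
  allele flip; no base qualities are simulated because the pipeline
  consumes calls, not reads.
- **Planted filter work.** A configurable fraction of sites (default
  0.2, matching the ~20% heterozygous parent calls such experiments
  show) is generated with one parent heterozygous, and 2% with
  sub-threshold site quality.  F2 genotypes at het-parent sites still
  follow the standard biparental model; those sites exist to exercise
  the parent-consistency filter and are removed before any scan.
  Everything planted is recorded in truth tables, and regeneration
  under one seed is byte-identical.

What passing tests on this generator do *not* show: robustness to
alignment and calling artifacts, segmental duplication, segregation
distortion, or non-Gaussian phenotype noise — none of which the
generator produces.

## Filters

Sites are kept when QUAL ≥ 20 and each *pool's* depth lies in the
inclusive window [4, 200] (the exclusion rule is "< 4 or > 200", so
the bounds themselves are keepable).  Parental depth enters only the
homozygosity call: a parent is effectively homozygous when its depth
is ≥ 4 and its minor-allele read fraction is ≤ 0.1 — read sampling
makes exact homozygosity unusable — and the two parents must be
homozygous for opposite alleles.  All filters are pure per-site
predicates, hence idempotent and order-commutative on the retained
set; the filter report attributes multiply-failing sites to the first
stage (quality → depth → parent) and reconciles exactly.

## Orientation and sign conventions

`orient_to_l1` makes the tolerant parent's allele the REF allele at
every site.  The scan's SNP-index counts the *alternate* allele — the
sensitive parent's — so Δ = index_S − index_T is positive where the
tolerant bulk is enriched for the `L1` allele, and the window Δ agrees
in sign (and, at equal depths, in value) with
L1AFD = freq_T(L1) − freq_S(L1).  This is the only convention under
which a scan's Δ column and its L1AFD column can carry the same sign
at a tolerant-parent QTL, which is how published scans of this design
print them.  Note: among the transcribed reference regions in
`bsaqtl.datasets`, one (qHT7.1) is described in prose as
L6-derived while its tabulated L1AFD is positive; the package follows
the tabulated number (sign of the region mean decides the donor,
exactly zero is left undetermined).

## Windows and regions

Windows are `[g, g + 1 Mb)` for every start `g` on the 10-kb grid of
each chromosome; the window statistic is the unweighted mean of
per-site indexes over the identical site set, with empty windows
emitted as gaps (never interpolated, never joined to a region).  The
grid runs to the chromosome end, so terminal windows may overrun the
sequence; region ends are grid ends.  A called region spans its first
significant window's start to its last significant window's end − 1
(1-based inclusive print convention) with interval = end − start;
consecutive significant windows merge while they overlap or abut on
the grid, so a single non-overlapping gap separates regions.  Region
tables report both the peak-window pool indexes and the region-wide
site means, since either summary is defensible.

## Null model and significance

One null replicate at depth d draws each bulk's pooled allele count as
Binomial(2n, 1/2) — equivalent to n individual genotypes at
1/4 : 1/2 : 1/4 — and read counts as Binomial(d, p̂).  Per-depth
bands are the empirical (0.025, 0.975) and (0.005, 0.995) quantiles
over 10⁴–10⁵ replicates, isotonically smoothed (running min/max over
increasing depth) so bands never widen with depth.  A *site's* band is
looked up at the rounded harmonic mean of its two pool depths: the
read-sampling variance of Δ is E[p(1−p)](1/d_T + 1/d_S) =
2·E[p(1−p)]/d_harm, so a single-depth simulation at d_harm matches
the site's null variance exactly.

Window p-values average independent per-site null draws at the
window's observed depths and take the two-sided empirical tail of
|Δ|, floored at 1/(R+1); a clearly-labelled normal-tail approximation
(`p_normal`) is also reported for sub-floor magnitudes.  **Caveat:**
sites in a window share bulk genotypes through linkage, which this
site-independent window null ignores, so window p-values are
anticonservative — on a whole-genome run most windows can reach
nominal significance while per-site band exceedance stays at ~1%.
`call_qtl` therefore supports two routes: the window-p criterion
(default) and a `criterion="band"` route that flags a window only when
its Δ leaves the per-depth 99% band at the window's median depth —
much more conservative and closer to how such scans are read off
figures.  Calibration is asserted where it is well-defined: per-site
99%-band exceedance ≈ 1% on a no-QTL genome, and the genome-wide mean
Δ within 3 Monte-Carlo standard errors of zero, where the s.e. is
computed by clustering at the chromosome level (sd of chromosome
means / √11) because linkage makes the naive iid s.e. wrong by about
an order of magnitude under these designs.

## Scaled validation scenario

Whole-pipeline properties run on an 11 × 2 Mb genome at 2 kb marker
spacing with the full study population design (147 F2, bulks of 9,
13× pools, 10× parents, recessive effect 40, noise sd 8), the QTL at
Chr02:1 Mb; this keeps the full test suite and the acceptance script
in seconds-to-minutes.  The scaling matters for localization claims:
with bulks of 9 at 3 cM/Mb, the Δ plateau around a major QTL is
several Mb wide and the sensitive pool's frequency profile wanders by
±0.1 on Mb scales, so on full-length chromosomes the top window is
reliably on the right chromosome but its centre is only localized to
roughly ±4 Mb — consistent with the multi-Mb intervals such scans
publish.  On the scaled genome the 2 Mb recovery tolerance is met in
20/20 seeded replicates.

## Degenerate inputs and numerical choices

Zero-depth sites raise (they must be depth-filtered); empty windows
carry NaN statistics; a monomorphic marker's concordance is undefined
and reported as such rather than as 0 or 100%.  IUPAC ambiguity codes
in effect classification are rejected, not resolved; a partial
trailing codon on a CDS whose length is not a multiple of three is
treated as non-coding.  Window means are computed by direct slicing
(not prefix sums) so they equal a brute-force recomputation bitwise,
and pool-swap antisymmetry holds bit-for-bit because Δ is always the
literal subtraction of the two pool means.

## Known limitations

The window-level null's anticonservativeness under linkage (above) is
the main one.  Others: the donor call uses the sign of a mean, with no
uncertainty attached; the simulator's uniform marker spacing and
constant recombination rate are simplifications; the effect
annotator handles SNPs only and collapses UTR/splice categories into
genic-noncoding; and the concordance model assumes fully recessive
tolerance (a dominant option exists but is off by default).
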