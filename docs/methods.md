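# Methods

## Scope and coordinates

The package covers the dry-lab half of a targeted capture experiment:
everything downstream of an aligner/SNV-caller's read-count table and
upstream of wet-lab validation.  Read alignment, primary SNV calling and
probe synthesis are out of scope; their outputs (interval files, per-base
depths, per-variant read counts, annotation tables) are the package's
inputs.  Intervals are 0-based half-open (BED convention) everywhere except
variant tables, which are 1-based as in VCF.

## Capture design

Exons (coding and UTR) are expanded by `flank` (default 40 bp) on each
side, clipped at zero, and merged into disjoint targets.  Baits of length
`L` (default 120) are laid at step `s = L/k` (`k` = tiling factor, default
3) on a grid anchored so one bait is centered on the target midpoint
`m = floor((start+end)/2)`; every grid placement overlapping the target by
at least one base is a candidate.  This places exactly `k` candidates over
every target base, including single-base targets (which receive `k`
staggered overhanging baits).  A candidate is rejected iff its total
overlap with repeat intervals exceeds `max_repeat_overlap` (default 20 bp),
a per-bait budget that keeps short exons flanked by interspersed repeats
capturable.  No other bait filter is applied; segmental duplications are
deliberately not excluded.  A bait whose grid position would start before
coordinate 0 is dropped rather than clipped, preserving the fixed bait
length.  The design report counts failed target bases (no accepted bait)
and failed regions (targets with no accepted bait) separately, since "x% of
regions failed" can be read either way.

If `L` is not divisible by `k` the step is `floor(L/k)` and a warning is
issued; the defaults never hit this.

## Coverage statistics

"Covered by more than 10/30 reads" uses strict inequality: depth exactly 10
does not count.  A read is on-target when it overlaps the capture target
region by ≥1 bp.  Empty target sets give an on-target rate of 0; empty
depth input is an error.

## Zygosity and cryptic indels

Zygosity is a step function of VAF with `het_min = 0.30` and
`hom_min = 0.80`.  These bracket the observed clusters — heterozygotes near
48–51%, homozygotes near 100% — while leaving a *weak support* class below
0.30 for the ~25% VAF signals that arise when an aligner reads an
unrepresented indel as nearby substitutions.  `min_depth` defaults to 10
(the looser of the two published depth cutoffs); 30 is available through
the same parameter.  Runs of ≥2 weak-support SNVs on one chromosome with
successive gaps ≤ `max_gap` (3 bp) and pairwise variant-read ratios ≤
`ratio_tol` (1.5) are grouped into one indel candidate — values chosen to
cover the canonical 2-bp-apart case with margin.  Candidates are resolved
when a truth/realignment source (synthetic runs supply the planted indel
table) overlaps the span; otherwise they are emitted unresolved for
Sanger-style confirmation.  Sites at or above `het_min` are never consumed
by candidate grouping.

Multi-allelic sites are represented as one observation per alt allele
sharing the reference read count, keeping VAF well defined.

## Filter cascade

Order: dbSNP → conservation → cohort recurrence → 1000 Genomes.  The first
three are independent predicates (any order gives the same survivors — the
suite asserts this); recurrence precedes the 1000 Genomes check because
that check is defined only for variants seen in few probands.  Details:

* dbSNP: known variants pass only if flagged clinically associated.
* Conservation: SNVs with PhyloP < 0.9 are discarded; indels are exempt
  (the score is defined for an SNV's consensus nucleotide); a missing score
  passes with a log message (configurable).
* Recurrence: a variant carried (any zygosity) by more than `max_probands`
  (default 3) of the cohort's probands is treated as an ethnic-group
  polymorphism regardless of database status.
* 1000 Genomes: membership in the project, or in a supplied list of other
  published genomes from hearing individuals, fails the variant.

Every applied filter is recorded in an ordered verdict trail; a variant is
rare iff all recorded verdicts pass.  Survivors are classified by effect:
codon translation (Biopython) for coding SNVs on either strand, indel
length mod 3 within the CDS for frameshift vs in-frame, a `splice_window`
(default 2 bp, the canonical dinucleotides; configurable up to the captured
flank) on the intronic side of exon boundaries, UTR/intronic otherwise.
"Potentially functional" counts nonsense, missense, splice junction and
frameshift only.

## Segregation model

Full penetrance, no phenocopies, no de novo events, autosomal loci only.
Affected members must carry two pathogenic alleles under the recessive
model (homozygous, or het for both alleles of a compound pair) and at least
one under the dominant model; unaffected members must not.  Members with
unknown genotype or phenotype abstain.  Compound-het phase uses the trio
rule: trans when each parent carries exactly one of the two alleles, cis
when one parent carries both and the other neither, unknown otherwise.  The
rule is sound but deliberately incomplete — configurations where dose
arithmetic alone forces a phase return unknown — and an affected
double-het with unknown phase is counted consistent-with-warning, since a
lone het pair is insufficient evidence either way.  The test suite checks
the rule and the full checkers against haplotype-enumeration oracles on
pedigrees of up to 8 members.

## Cohort statistics

Allele frequency is `(2·n_hom + n_compound_het + n_het) / 2N`: a compound
heterozygote contributes one focal chromosome (the partner allele counts
toward its own tally).  Chromosomes are treated as independent draws
(Hardy–Weinberg; cohort members unrelated by report).  The case/control
comparison is a two-sided Fisher exact test on the 2×2 chromosome-count
table; Pearson chi-square (uncorrected) is available via `method="chi2"`.
On the headline founder-allele table the two differ materially (Fisher
2.4e-19, chi-square 1.5e-27) because the exact null is conditional; both
are reported by the acceptance script.  The odds ratio is the sample ratio
with a Haldane–Anscombe 0.5 correction applied to all cells when any cell
is zero.  The attributable fraction `n_solved/n_total` carries an exact
one-sided Clopper–Pearson lower bound (`Beta⁻¹(1−conf; k, n−k+1)`).

## Synthetic data generator

Defaults are the study conditions: a 246-gene panel (6–26 exons of
80–360 bp per gene, ~1.2 Mb of targets after flanking), 8% of target bases
repeat-masked, median depth 937× with 5% contiguous dropout, 11 probands,
~2 shared common polymorphisms per target kb (each carried by ≥4 probands,
90% known to dbSNP), ~25 private SNVs and ~35 private indels per proband
(2% observed homozygous), and cohorts of 52 cases / 282 controls with the
founder allele at 0.337 vs 0.028 and a second pathogenic allele at 0.058.

* **Reference and genes.**  Random sequence per contig; each gene gets a
  defined reading frame (premature in-frame stops rewritten), 0–25 bp UTRs,
  and a 20% chance of lying on the minus strand, so effect classification
  is exercised on both strands.
* **Depth.**  Log-normal around the median with AR(1) autocorrelation
  (ρ = 0.99, σ = 0.25), plus contiguous dropout blocks (200–800 bp) forced
  below 10 reads, with ~40 bp log-linear shoulders where the block edge
  falls inside a target.  Because targets are exon-sized, blocks usually
  span a whole target and the shoulders are truncated: the generator
  reproduces the "fraction > 10 reads" figure (1 − dropout within ±0.02)
  but not a distinct 10–30× band, so the >30-reads fraction tracks the
  >10-reads fraction.  Passing tests therefore validate threshold counting
  and dropout calibration, not the real shape of GC-driven decay.
* **Variants.**  Read support is Binomial(depth, p) with p = 0.5 for het,
  0.995 for hom (not 1.0, so the homozygous threshold is exercised;
  all-variant-reads fixtures also occur), and 0.25 per member site of a
  planted cryptic indel, emitted as two substitutions 2 bp apart whose
  underlying 2-bp deletion is recorded as truth.  The planted causal allele
  is a coding missense/nonsense SNV with PhyloP ≥ 1.2 and damaging
  PolyPhen-2/SIFT annotations, absent from all database stubs.
* **Cohorts and families.**  Cohort genotypes are exact Hardy–Weinberg
  multinomial draws over {focal, partner, wild-type} chromosomes.  Families
  are two-generation, two parents and six children, redrawn until at least
  three members are affected — the enrolled kindreds such studies ascertain
  are large and multiplex (four to nine affected members); affection follows
  the causal genotype with full penetrance, and benign candidate genotypes
  are transmitted Mendelian-style conditioned on the proband's observed
  call.

What the generator does not emulate: read-level errors and base qualities,
alignment artifacts other than the cryptic-indel signature, linkage between
nearby variants, population structure or relatedness within cohorts, and
X-linked inheritance.  End-to-end results on it validate the decision
logic, not aligner behaviour on real reads.

## Problem sizes and determinism

All randomness flows from `SimulationConfig.seed` through independent
per-stage streams; a fixed seed reproduces byte-identical exports.  The
test suite and acceptance script use a 12-gene panel (≈70 kb) for the
100-replicate planted-variant recovery study and the full 246-gene panel
for single-run coverage figures; recovery uses 100 seeded replicates, the
size at which the ≥95% recovery property is asserted.  The residual
failure mode is real and instructive: a private homozygous indel that
survives the cascade and, with ~¼ probability per affected sib, happens to
co-segregate; large multiplex families suppress it to a ~1–2% rate.

## Known limitations

* Bait placement ignores probe thermodynamics and GC balance; the design
  module will not reproduce a vendor's exact bait set.
* The conservation filter trusts the supplied PhyloP stub; no liftover or
  score recomputation.
* Effect classification handles one transcript per gene and simple c./p.
  arithmetic; no HGVS normalisation, no multi-transcript reconciliation.
* The segregation checker reports qualitative consistency, not linkage LOD
  scores, and assumes full penetrance.
* Fisher/chi-square treat chromosomes as independent; kinship correction is
  out of scope.
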