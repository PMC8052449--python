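# Methods

## Energy model

A duplex between two sense-strand regions of one pre-mRNA is scored as

ΔG = Σ nearest-neighbor stacking terms within helices + Σ loop penalties,

at 37 °C in kcal/mol.  Admissible base pairs are Watson–Crick and the G·U
wobble.  The ten Watson–Crick stacking terms are bundled at the published
two-decimal Turner-2004 values (`src/pccr/data/turner_stacks.tsv`); the
eleven wobble-containing terms are bundled at the 0.1 kcal/mol precision
at which the ViennaRNA distribution ships that parameter set.  Two
tandem-wobble steps (5'GU3'/3'UG5' = +1.3, 5'UG3'/3'GU5' = +0.3) are
destabilizing — a property of the published table that the test suite
deliberately does not "fix".

Loop penalties are sequence-independent generic initiation terms
(`data/loop_penalties.tsv`): 3.80 for a 1-nt bulge, 2.80 for a 2-nt
bulge, and internal loops scored as initiation-by-size plus
0.6 kcal/mol per unit of asymmetry (1×1 = 1.00, 1×2 = 1.60, 2×2 = 1.10).
The sequence-dependent 1×1/2×1/2×2 tables are intentionally not used: the
grammar treats a loop as a fixed-cost interruption between helices.

**Convention.**  ΔG contains no duplex-initiation and no terminal-AU
terms.  This matches a pure-extension search, where only differences
between candidate structures matter; comparisons against tools that
include an initiation term must add it back (the cross-check test adds
ViennaRNA's +4.10 initiation before comparing perfect helices, and
agrees within rounding of the wobble precision).

## Search grammar and dynamic program

A valid structure is an antiparallel chain of base pairs (i strictly
increasing on strand 1, j strictly decreasing on strand 2) composed of
helices of at least k consecutive pairs separated by internal loops or
bulges of at most m nucleotides per strand ((0,0) excluded).  Wobble
content is capped per window: every k consecutive pairs of a helix must
be an entry of the precomputed k-mer pair table (k = 5, ≤ 2 wobbles by
default; 6,144 entries).  The table is the only admissibility oracle the
search consults, so the wobble cap is enforced per k-window rather than
per helix.  Ns never pair.

The DP state is the cell (i, j) at which the last k-window of a
structure ends; transitions are (a) shifting the window by one — adding
one stacking term — or (b) a loop jump of (a, b) ≤ (m, m) followed by a
fresh k-mer seed.  Cost: O(|s1|·|s2|·(m+1)²) in the dense worst case, but
cells are enumerated sparsely through a k-mer index of strand 1 against
the ≤ 16 admissible partners of each strand-2 window, which makes
genome-scale scans cheap on conserved-region input.  Ties between
co-optimal transitions resolve in a fixed order (seed < stack < loops in
lexicographic (a, b)), so tracebacks are deterministic.

Hits are cells passing the energy threshold (−15 kcal/mol) whose
one-step stacking successor is not at least as good (such cells are
interior to a better structure ending one pair later); arms must span at
least `min_len` = 10 nt.  Nested and suboptimal hits are retained at this
stage; the non-intersection rule (two hits conflict only if they share
nucleotides on both strands) is applied afterwards, greedily by
ascending ΔG, then longer total span, then leftmost arm.  Retaining
suboptimal non-conflicting hits is a deliberate choice: region pairs can
host several genuine duplexes.

An exhaustive enumerator over the same grammar (depth-first over all
seed/extend/jump decisions, scored independently by direct summation)
serves as the oracle; the DP is required to match it exactly, per end
cell, on random small inputs.

## Search space construction

Intronic regions are the maximal segments of each protein-coding gene
that overlap no annotated exon of any gene, extended by up to 10 nt into
the flanking exon blocks (clipped at short exons and gene bounds) so
that duplexes overlapping splice sites remain findable.  Exclusion
tracks (repeats, small RNAs, conserved TFBS, …) are subtracted after
extension and before intersecting with the conserved-element track; each
resulting conserved intronic region (CIR) keeps its gene attribution,
and overlapping genes each receive their own CIRs.  All coordinates are
0-based half-open; GTF input is converted on read.

Pairs of same-gene CIRs (including a CIR with itself) with genomic gap
≤ L = 10,000 nt are scanned on sense-strand sequence.  Self-pair hits
whose two arms overlap genomically are discarded, as are mirror
duplicates.  Spread d is the inner genomic gap between the arms
(half-open end of the left arm to start of the right arm).  The relative
gene position is p = (x−a)/((b−a)−(y−x)+1) for an interval [x, y) in
gene [a, b) on the plus strand and 1−p on the minus strand, clamped to
[0, 1]; the denominator is written so that p runs from 0 at the 5' end
to ~1 at the 3' end of the gene.

## Null models

* **Random shift** moves each structure to a uniform offset within its
  gene, preserving arm lengths and spread.
* **Random gene** re-creates each structure at the same relative
  position in a random gene of matching length (±10%; nearest-length
  fallback is logged).
* **Re-wiring FDR** replaces the second member of every real CIR pair
  with a CIR from a different gene matched on length (±10%) and GC
  (±5 percentage points; bins relax with a warning when the pool is
  empty) and re-runs the identical search; FDR = control predictions /
  real predictions, averaged over n randomizations and stratified by
  energy group.  The matching tolerances are this package's choices —
  "controlled for composition and length" admits a family of schemes.

Enrichment of inside/outside/crossing placements relative to a feature
set counts a structure once per feature; "outside" uses loop-out
semantics (the feature must lie strictly between the two arms, not
merely within the footprint).  Significance is a two-tailed Wilcoxon
signed-rank test of the n = 40 control counts against the observed
count, with a percentile interval on the ratio.

Odds ratios use OR = ad/bc with Woolf log-CIs and Fisher exact p values;
a Haldane correction of 0.5 per cell is applied and flagged when a
product of off-diagonal cells is zero.  The forked-peak odds ratio uses
a 50-nt window from the arm ends — chosen to mirror the RNA-bridge
proximity rule, since "near" has no published number — and is
configurable.

## Variation statistics

SNP density compares merged arm regions against merged non-arm conserved
background with a one-tailed Poisson test for depletion.  ΔΔG of an
observed SNP is evaluated on a fixed pair topology (no refolding): a
pair whose nucleotides can no longer pair loses its two adjacent
stacking terms; the null re-applies the same ref→alt substitution at
every other reference-allele position of the same arm.  Compensatory
polymorphisms are base pairs where variants at ≥ 1% carrier frequency on
both sides produce alternative alleles that can still pair (WC or
wobble); same-haplotype co-occurrence is *not* required, as phasing is
out of scope.  The null permutes pairing partners within groups of the
same pair type, chromosome, and donor count, where the donor count is
the carrier count reconstructed from allele frequencies for a cohort of
2,504 individuals; group sizes and the pair-type multiset are preserved
exactly, and the observed count is tested against the permutation mean
with a one-tailed Poisson test.

Per-base-pair covariation E values (from external covariation software)
aggregate multiplicatively over flagged pairs (empty product = 1);
Benjamini–Hochberg adjustment runs across structures with E < 1.  The
Stockholm exporter joins the two arm alignments with a ten-adenine
spacer, drops organisms with indels in either arm, requires ≥ 15
surviving rows, and writes the duplex as `<`/`>` brackets in `SS_cons`.

## Splicing statistics

Ψ = inc/(inc + 2·exc), undefined below denominator 10.  Splice sites
with ≥ 3 pooled split reads are ranked by support; the top and bottom 2%
are active/inactive (position-sorted tie-break for determinism).
Cryptic sites are externally scored candidates above side-specific
strength thresholds (donor > 800, acceptor > 950 on the scaled score)
minus expressed and annotated sites.  Introns with and without
structures are matched by log10-length bins of width 0.1, sampled
without replacement to equal counts, and compared by transcript-end
containment via odds ratios.  Support by experimental RNA-RNA contact
data uses 1-nt arm overlap on both sides for a true positive; π is the
fraction with a correct partner among structures with ≥ 1 matching arm.
RNA-bridge candidates need a peak within 50 nt of one arm, an exon
within 50 nt of the mate arm (nearest boundaries, inclusive), and a
knockdown response at q < 0.01; loop-out candidates need the exon
strictly between the arms and a peak on an arm.  The ΔΨ/q values are
consumed as input — the differential-inclusion machinery itself is an
upstream concern.

## Synthetic fixtures: what they do and do not show

`make_toy_genome` builds one chromosome of i.i.d. background sequence
(GC 0.45) holding 50 genes of 6–14 kb with 2–4 exons on random strands,
and plants 120 panhandles: stems grown pair by pair (10% wobble) until a
target energy drawn from [−40, −15] kcal/mol is crossed, with a small
internal loop in 30% of the plants, written into two intronic conserved
islands 100–9,000 nt apart with non-pairing guard margins (≤ 3 nt, below
the seed length, so the planted structure can neither extend nor seed
into them).  Stems whose own optimal fold differs from the planted
topology are rejection-sampled away — the optimality check uses the
search itself, which is independently validated against exhaustive
enumeration, so ground truth remains well-defined.  Decoy islands carry
shuffled stem sequence to exercise the false-discovery machinery.
Track generation plants SNVs (2%/nt, 10% depleted in arms, plus
compensatory pairs), peaks (independent / forked / on-arm geometry),
editing sites (30% of arm adenosines vs 3% background), reactivity
depression proportional to |ΔG|, junction counts with ΔΨ = −0.2 for
looped-out exons, and transcript-end clusters in duplex loops.
Everything derives from one mandatory seed; outputs are byte-identical
across runs.

Passing on these fixtures shows that the implementation is internally
correct and calibrated under its own model; it does not show robustness
to real-genome phenomena the generator omits — repeat-driven spurious
complementarity, alignment/annotation errors, composition heterogeneity
along chromosomes, linked variants, or realistic phylogenetic
covariation (the Stockholm path is tested on hand-built alignments
only).

## Problem sizes and numerical choices

The bundled study fixture uses 50 genes / 120 plants (≈ 1 Mb genome);
oracle-equivalence runs 200–250 random pairs of length ≤ 15; null
calibration uses 100 replicates of 25 structures × 20 features with 40
shifts each; re-wiring degenerate checks use 2-gene universes.  These
sizes make the full suite and the acceptance script run in seconds to a
few minutes while keeping every statistical check adequately powered.
Energies compare at 1e-6 absolute tolerance (table entries are exact
sums of two-decimal parameters); DP/oracle energies must agree to 1e-9.
Degenerate inputs: sequences shorter than k yield empty results, not
errors; a structure longer than its gene stays in place under random
shift (logged); zero off-diagonal 2×2 cells trigger the flagged Haldane
correction; empty experimental sets and empty region sets are errors.
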