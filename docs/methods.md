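# Methods

This note records the exact definitions, conventions and design choices
behind each stage, plus what the synthetic generator does and does not
emulate.

## Coordinates and formats

All coordinates are 0-based half-open (UCSC table convention).  CGIs
are read from BED3+ (optional name column); gene models from
knownGene-style TSV, headered or headerless in the standard UCSC column
order, with trailing-comma exon lists; bisulfite calls from a per-site
TSV (`chrom, pos, strand, meth_calls, unmeth_calls`), one row per
covered CpG cytosine per strand; alignments from MAF with three rows
per block (human, chimp, ancestor — source labels configurable).  MAF
was chosen over ancestral-alignment EMF dumps because it carries the
same information with far better tooling; parsing and writing go
through Biopython's `AlignIO`.

## Positional classification

A transcript's 5′ window runs from 3 kb upstream of its first exon
through that exon; the 3′ window from the final exon through 3 kb
downstream; the intragenic window from the end of the first exon to the
start of the final exon.  "First" and "final" are in transcription
orientation, so on minus-strand transcripts the first exon is the
highest-coordinate exon.  Windows are clamped at position 0 (and at the
chromosome length when known).  Overlap means ≥ 1 shared base.
Categories are assigned with strict priority 5′ > 3′ > intragenic,
falling through to intergenic.

Choices where the convention was genuinely open:

* The 3′ window **includes the final exon body**, mirroring the 5′
  definition, which explicitly includes the first exon.
* When several transcripts trigger the winning category, the CGI is
  coding if **any** of them is protein-coding (`cdsStart != cdsEnd`),
  and all triggering transcripts are reported as associated.
* Intergenic CGIs are always non-coding.

## Methylation levels

All estimators compute percentages, `100 * S / (S + C)`:

* `pooled_strand_averaged` — pool calls per strand, average the two
  strand percentages with equal weight.  A strand with zero calls is
  ignored rather than counted as 0%.  Intended for deep whole-genome
  bisulfite data.
* `pooled` — one ratio over all calls.  Algebraically the
  coverage-weighted mean of per-site ratios.
* `site_mean` — unweighted mean of per-site ratios over sites with
  coverage ≥ `min_reads_per_site` (use 4 for RRBS-style
  informative-site filtering; 0 averages all covered sites).

A CGI with fewer than 5 total calls (methylated + unmethylated, all
sites, both strands) is excluded.  The source description of this
filter ("fewer than five methylated or hypomethylated cytosines") is
ambiguous between S+C < 5, S < 5, and C < 5; we read it as the total,
which is also the only reading that excludes nothing on deep data.  The
filter is applied once per CGI per sample at the table level; the bare
estimator functions exclude only on zero calls so they remain usable as
plain ratios.  Labels are inclusive at both boundaries: LM ⇔ level
≤ 20%, HM ⇔ level ≥ 80%; everything else is `intermediate`.  5hmC
levels use the identical pooled ratio on a separate
hydroxymethylated/non-hydroxymethylated call stream, and
`cgis_with_hydroxymethylation` supports removing CGIs with ≥ 1
hydroxymethylated call (bisulfite chemistry cannot tell 5hmC from 5mC,
yet 5hmC deaminates far less).

## Substitution rates

Each rate is `events / (2 × opportunities)`: opportunities are counted
on the ancestor, events are summed over the human and chimp lineages,
and each lineage can contribute at most one event per opportunity, so
defined rates lie in [0, 1].  A rate is undefined (NaN) when the CGI
has no ancestral source state; undefined rates are dropped from any
group mean rather than imputed.

Counting semantics (the source formulas are silent on alignment
details; these are this package's conventions):

* An ancestral dinucleotide is two **consecutive alignment columns**
  with a non-gap, non-N ancestor base in each.  A lineage is eligible
  for a dinucleotide event only if it has unambiguous (non-gap, non-N)
  bases in both columns — an insertion or deletion voids that lineage's
  event but leaves the opportunity in the denominator.
* Derived dinucleotides outside every listed target class (e.g.
  CpG→TpA, double substitutions) count toward no numerator and stay in
  the denominator.
* The non-CpG-context condition is evaluated on the **derived** sequence
  for A/T→G/C (a derived G/C that forms a CpG is not an event) and on
  the **ancestral** sequence for G/C→A/T (ancestral CpG members are
  excluded from the denominator), following the formulas' wording.
  Context uses adjacent alignment columns; at block edges the unknown
  neighbour counts as non-CpG context.
* A dinucleotide belongs to a CGI when its **first base's** human
  coordinate lies in `[start, end)`; single-base classes use the
  column's own human coordinate.  Gap columns inherit the coordinate of
  the next human base.  Dinucleotides spanning two MAF blocks are not
  counted.
* Everything is computed on the forward strand only; the TpG/CpA target
  pair already folds in deamination on the complementary strand.

Coverage is the fraction of CGI bases present as non-gap human bases in
any block; CGIs strictly below 50% are excluded (exactly 50% is
retained, since the exclusion rule removes those covered on *less than*
half).

## The rate-threshold stump

The stump is an exhaustive single Gini split, the depth-1 tree a CART
package produces: candidate thresholds are midpoints of consecutive
distinct sorted rates, the chosen one minimises the size-weighted child
impurity, ties go to the smallest threshold, and children are reported
as (≥ t) "left" and (< t) "right" so the high-rate leaf comes first.  A
`min_leaf_size` option (default 1, a `minbucket` analogue) supports
parity experiments with CART defaults.  Single-class or constant-rate
inputs give a flagged degenerate fit.  Published thresholds
(0.03825 for the whole-genome analysis, 0.03984 for the RRBS replay)
arise from the full-scale data; when replaying such a grouping they are
supplied as the pipeline's `fixed_threshold` configuration rather than
refitted.

## Summaries

Group summaries report, per group and per rate, the count of CGIs with
that rate defined, the mean, and the SEM (sample standard deviation
with n−1 over √n; undefined for n < 2).  Positional count tables omit
intermediate and excluded CGIs; cross-sample cross-tabs let
intermediate/excluded second-sample labels fall outside both columns,
so rows need not sum to the stratum size.  Fractions are emitted at
full precision (TSV output rounds to 4 decimals); presentation rounding
is the caller's business.

## Synthetic data: what it emulates, and what it does not

The generator plants CGIs on slot-structured chromosomes (one slot per
CGI, 20 kb by default) so that each island falls in exactly one
positional class of its slot's transcript; gene strands alternate.
Island sequence is built from CpG units at a target density of CpG
starts per base (0.10 inside islands, 0.01 in background — island
density and contrast in the range of real CGIs against mammalian
background), with accidental CpG joins broken so the planted density is
exact in expectation.

Two lineages evolve independently from the ancestor.  Dinucleotide
events (CpG→TpG/CpA, CpG→other, TpG/CpA→CpG, other→CpG) are drawn per
ancestral dinucleotide at the group's branch probability; overlapping
candidate events are resolved leftmost-first, and an applied
dinucleotide event blocks single-base events at its two positions.
Single-base events (A/T→G/C, and G/C→A/T at ancestral non-CpG-context
positions) are then drawn at unconsumed positions.  Default group
parameters are per-branch CpG→TpG/CpA probabilities of 0.04 (sperm-HM)
and 0.005 (sperm-LM) — the methylation-dependent deamination contrast
the analysis is designed to detect, with the fitted threshold expected
between them — TpG/CpA→CpG of 0.008 vs 0.004 (CpG fixation mildly
elevated with methylation), and the four remaining classes equal across
groups (at_to_gc 0.008, gc_to_at 0.012, cpg_to_other and other_to_cpg
0.005), so only the two CpG-gain/loss rates should separate the groups.
True methylation levels default to 0.90 (HM) and 0.05 (LM); bisulfite
coverage is Poisson with mean 30 per site per strand and methylated
calls are binomial at the true level.

Truth counts are recorded by re-scanning the emitted
ancestor/human/chimp sequences with the same single-substitution
classification the estimator uses (implemented independently in the
generator), so estimator output equals truth exactly on gapless
cohorts — this is asserted in tests.  One deliberate consequence: a
planted A/T→G/C event that lands next to a C or G can create a derived
CpG; the estimator (and hence the truth recount) then counts it as a
TpG/CpA→CpG fixation rather than a GC gain, exactly as it would on real
data.  Realised fixation rates therefore sit slightly above their
nominal branch probabilities; the planted HM/LM fixation contrast is
2× so the group ordering stays detectable through this background.

Not emulated: realistic chromosome-scale sequence composition,
recombination, CpG-density gradients, empirical CGI length
distributions, multiple hits per site, or lineage-specific rate
asymmetry.  Default simulations are gapless so counting semantics are
unambiguous; an opt-in `indel_rate` applies independent per-base
lineage deletions as a stressor for the gap rules (insertions are not
simulated, and truth counts are not recorded in that mode).  Passing
parameter-recovery tests therefore demonstrates correctness of the
estimators under the stated generative model, not robustness to every
artefact of real methylomes and alignments.

## Problem sizes and numerical choices

Test and acceptance runs use cohorts of 200 CGIs per methylation group
(800 bp islands, ≈ 60 ancestral CpGs each) for rate recovery, 100
seeded replicates for the threshold-location check, 105 CGIs at
coverage 30 for methylation recovery, and 1,000 random ≤ 100 bp triples
for exact oracle equivalence of the event counter — sizes at which the
expected sampling error of each recovered quantity is several times
smaller than the planted contrasts.  Random draws all flow from
explicit `numpy` generator seeds; outputs are byte-identical under a
fixed seed.  No floating-point tolerances enter the counting code
(integer counts throughout); level and rate comparisons in tests use
binomial or sample standard errors as stated alongside each test.

## Known limitations

* Coverage and rate estimation treat multiple overlapping MAF blocks
  as a union of human positions but count dinucleotides within blocks
  only; EPO-style block fragmentation at CGI scale is not modelled.
* The minus-strand "cytosine" of a CpG whose C is the last island base
  falls one base outside the island and is attributed accordingly.
* `pooled_strand_averaged` weights strands equally regardless of
  coverage imbalance; whether the original whole-genome analyses
  weighted by coverage is not determinable from their description.
* The stump fits a single split only; a deeper CART tree pruned to one
  split could in principle choose a different threshold on pathological
  data.
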