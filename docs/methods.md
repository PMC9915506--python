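# Methods

## The screen in one paragraph

A CONDEL is inferred where two independent lines of cross-species evidence
intersect: a reference-genome interval must be *deleted* in a quorum of
species from every screened trait-reduced clade, and simultaneously
*conserved* in nearly all trait-complete outgroup species.  Both kinds of
evidence are read off pairwise alignment chains (reference vs one query
genome each), which makes the screen independent of any multiple
alignment and robust to assembly fragmentation as long as chains carry
the orthologous locus.  The unit of scanning is the gene: a window around
each gene's TSS bounds the search, and a candidate inherits links to all
genes whose windows call it.

## Coordinates and interval algebra

All coordinates are 0-based half-open on the reference; BED output is
emitted natively in that convention.  `IntervalSet` keeps sorted,
disjoint, non-abutting intervals per chromosome; union, intersection,
subtraction and k-of-n coverage thresholds are computed by boundary
sweeps, which makes every per-base mask exact rather than approximate.
"Within *d* bp" is read inclusively everywhere: intervals separated by
exactly *d* bases merge, and an N-run exactly 100 bp from a chain gap
still masks it.  Soft-masked (lowercase) bases are treated as their
uppercase nucleotide except in N-run detection, which is case-insensitive
for N.

## Orthologous chain selection

The original orthology-mapping procedure lives in prior tooling; this
package adopts an explicit, configurable interpretation computable from
chain files alone.  Aligned-base counts (not chain scores) rank chains:
the winner maximizes in-gene aligned bases, with header score and then
smaller chain id breaking ties.  Acceptance requires, inclusively,

* `in_gene_aligned / second_in_gene_aligned >= 10` (vacuous without a
  runner-up), and
* `total_aligned / in_gene_aligned >= 10` — the chain must carry
  substantial syntenic context beyond the gene, which penalizes short
  paralogous or processed-pseudogene chains.

Whether the historical gene-in-synteny criterion counted flanking mapped
genes rather than a base ratio is not recoverable from published text;
the base-ratio contract is isolated behind `map_gene_to_chain` so an
alternative definition can be swapped in.

## Gap calling

Every inter-block separator with `dt > 0` is a deletion call spanning
those `dt` reference bases; `dq = 0` makes it single-sided, `dq > 0`
double-sided.  Both enter the screen identically — the side is retained
for reporting only.  Masking against assembly gaps happens in *query*
coordinates (the suspect sequence lives in the query assembly): the query
context, its edges extended 100 bp each way, is tested against maximal
N-runs of length ≥6 ("longer than 5").  For double-sided gaps the
distance is measured from the context's edges, the more conservative of
the conceivable conventions.  Retained gaps merge within 20 bp per chain
*before* the cross-chain union, so gaps on different chains never merge.
Note that merging can bridge aligned blocks shorter than the merge
radius, so a species' merged gap footprint may slightly exceed the sum of
its raw `dt` values.

## Conservation scoring

Window identity is exact base matching (case-insensitive, N never
matches) with the window size as denominator; windows never span block
boundaries, so no gap-column policy is needed.  Defaults: window sizes
10/25/50/100 bp, step 1 (the step is not dictated by the procedure;
step 1 is maximally sensitive and affordable at the scales this package
targets — it is configurable for large genomes).  All sizes are pooled
into one ranked list per species.  Selection accumulates windows in
descending identity, tracking merged-flattened coverage, until coverage
reaches 5% of the non-N reference length, then adds every window tied
with the stopping window.  Because whole tie cohorts enter, the selected
set equals "all windows with identity ≥ θ" for a unique level θ, which
the implementation finds by bisection over the distinct identity levels —
the result is provably order-independent.  The 5% quota is taken against
non-N reference length (N-runs cannot align, so counting them would
silently tighten the quota); this too is configurable.  At low divergence
the tie cohort at identity 1.0 is typically much larger than the quota;
the quota then acts as a floor, not a ceiling, exactly as the tie rule
dictates.

## The gene-centric scan

Eligibility: orthology calls from ≥17 outgroups and ≥5 targets.  The
window is `[TSS − 200000, TSS + 200001)` — 400,001 bp unclipped,
including the TSS base symmetrically — clipped at chromosome ends.  The
deletion quorum is evaluated per base: a species counts at a base iff its
merged gap set covers it, and a base passes iff the count reaches
`ceil(2/3 × mapped clade members)` in every screened clade.  Screened
clades are those with ≥2 members (overridable); singleton trait-reduced
lineages are reported as supporting species but never gate candidacy.
A clade member without an orthology call for the gene drops out of both
numerator and denominator for that gene.  The conserved mask requires ≥17
outgroups per base, never counting the reference itself.  Intersections
≥20 bp are raw candidates; merged within 20 bp, kept at ≥50 bp, and
discarded if more than one scorable outgroup shows a gap over the
interval.  Scorability requires the outgroup's accepted chain to span the
candidate entirely — an outgroup whose chain stops short neither supports
nor violates.  Candidates from different genes unify when they overlap by
≥1 base (in practice they are identical, since all windows cut the same
genome-wide masks); reported conserved support is the minimum per-base
outgroup count over the candidate's mask-passing bases, so merge-bridged
bases cannot inflate it.

## Statistics

*Enrichment.*  One-sided binomial over-representation: with K of N
background genes annotated to a term and k of s study genes observed,
p = P(X ≥ k), X ~ Binomial(s, K/N); under-representation is not tested
(only enrichment folds >1 are of interest downstream).  FDR is
Benjamini–Hochberg (via statsmodels).

*Boschloo's exact test.*  The statistic is Fisher's one-sided conditional
p-value; the p-value maximizes, over the common success proportion π, the
exact probability of a statistic at least as extreme.  The implementation
mirrors the convention of the widely used SciPy routine applied to a
rows-as-groups table `[[a, m−a], [b, n−b]]`: the unconditional binomial
pair is taken over the table's outcome margin, and the two-tailed p is
twice the smaller one-sided value, capped at 1.  This choice makes
results directly comparable with studies that used that routine, and a
test pins the equivalence against `scipy.stats.boschloo_exact`.  The
nuisance maximization scans 999 evenly spaced interior grid points and
refines 201 points around the arg-max; doubling the grid moves the
reported p by far less than printed precision.

*Mann–Whitney U.*  Exact permutation enumeration when the pooled sample
is ≤20 with no ties; otherwise the normal approximation with tie and
continuity corrections (via scipy).

## Synthetic data generator

The generator emulates the structure the screen assumes — one reference,
many query genomes at known divergence, clade-structured deletions — not
realistic molecular evolution.  Defaults: 1 Mb reference, 40 genes, 20
outgroups at 2% substitution divergence, two screened clades of 4 and 3
target species plus 2 singleton target lineages at 5% divergence, 8 true
deletions of 60–300 bp, 4 decoys per class, 12 neutral background indels
per species, and up to 30 bp of outward breakpoint jitter per species on
true deletions.  Chains are derived analytically from the per-species
edit script, eliminating aligner nondeterminism and external binaries: a
deletion of L bases yields `dt = L` with `dq = 0`, or `dq > 0` when a
query insertion is co-placed (double-sided).  Roughly every fifth species
is emitted as a minus-strand assembly (reverse-complemented FASTA,
`q_strand='-'` chains) to exercise strand bookkeeping.  All randomness
flows through one seeded generator with a fixed draw order, so a seed
determines the bundle byte for byte.

Design choices worth knowing:

* **Outward-only jitter.**  Each deleting species extends a true deletion
  by 0–30 bp per side, never shrinking it, so every deleter covers the
  full truth footprint and the per-base quorum region contains it.
  Symmetric jitter could shrink the quorum intersection of a 60 bp truth
  below the 50 bp candidate minimum — a construction artifact, not a
  property of the method — so the truth set would no longer certify
  recall.  Decoys get no jitter for the same reason: their rejection must
  come from the one criterion they violate.
* **Substitution placement.**  Substitutions avoid 5 bp buffers around
  every breakpoint so window identities near engineered edits stay
  interpretable; low-conservation decoys instead receive a substitution
  every 5 bp across the interval in every outgroup, which leaves no
  perfect 10 bp window inside and an unbridgeable (>20 bp) hole in
  conserved coverage.
* **Background indels** (1–40 bp deletions, 1–15 bp insertions) are kept
  ≥600 bp from every truth/decoy site in every species so they can
  neither fake a quorum nor create an outgroup violation.
* **N-runs.**  Assembly-gap decoys place an 8 bp N-run 40 bp downstream
  of each deleter's breakpoint in query coordinates (within the 100 bp
  masking radius); additional benign N-runs are injected per target
  species ≥1 kb from any separator to confirm masking has no false
  trigger.

What the generator does **not** emulate: rearrangements and inversions,
repeat families and segmental duplication, indel/substitution rate
heterogeneity along the genome, fragmented multi-scaffold assemblies, or
alignment error.  Passing the recovery tests therefore demonstrates the
pipeline's logic is correct under its stated assumptions, not that those
assumptions hold for any particular real assembly set.

## Problem sizes and runtime

The default synthetic study (1 Mb × 29 query species, step-1 windows in
four sizes) runs the full pipeline in well under a minute on one core;
the test suite's shared default-scale bundle keeps the end-to-end
recovery, monotonicity, and conservation-sanity checks on the same data.
Conservation scoring dominates cost and scales linearly in reference
length × outgroups; the window step and window sizes are the levers for
larger genomes.

## Degenerate inputs and tie-breaks

Empty interval sets propagate as empty results, never errors.  Chains
must satisfy the format's arithmetic invariants at parse time (block sums
vs header spans, no zero-length blocks, no empty separators); violations
raise with the offending line number.  Orthology ties break
deterministically (aligned bases, then score, then smaller chain id), the
conservation ranking is insensitive to input order by construction, and
a quota that cannot be reached selects every window.  A 2×2 test with an
empty group is an error; a table with no successes anywhere returns
p = 1.

## Known limitations

* The screen cannot distinguish true deletion from unalignable divergence
  — that ambiguity is inherent to chain gaps and is inherited from the
  evidence, not the implementation.
* The orthology contract is an interpretation (see above); with real
  chains from a different orthology pipeline, acceptance decisions may
  differ at the margins.
* Per-base quorum denominators use mapped clade members; with very
  incomplete assemblies this makes small clades easier to satisfy than a
  fixed-denominator reading would.
* The binomial enrichment test treats annotations as flat sets: no
  ontology-hierarchy propagation and no term-term dependence correction
  beyond BH-FDR.
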