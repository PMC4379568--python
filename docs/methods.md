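# Methods

This note describes the models, algorithms and numerical choices behind
`hervetools`, and what the synthetic-data tests do and do not establish
about real genomic sequences.

## The biological model

A provirus integrates with two identical long terminal repeats (LTRs).
After integration each LTR copy accrues neutral substitutions
independently, so the divergence between the 5' and 3' LTR of one
element grows linearly with time and dates the insertion.  HERV-E
elements fall into three subgroups — LTR2, LTR2B, LTR2C — defined by
5'LTR sequence divergence, with consensus lengths 463/483/501 bp and
pairwise consensus identities of roughly 75–83%.  Most genomic copies
are degraded: LTR–LTR recombination leaves solitary LTRs, and internal
deletions truncate gag/pol/env.

## Pairwise alignment and the identity statistic

Global alignment is a three-state affine-gap dynamic program (Gotoh),
with a gap run of length k costing `gap_open + (k-1)·gap_extend`
(defaults: match +1, mismatch −1, open −5, extend −1).  Gap-state
switches are allowed, so the score is the true optimum over all global
alignments; tests verify this against exhaustive enumeration for short
sequences.  The traceback is deterministic (diagonal preferred over
vertical over horizontal on ties), making every downstream result
bit-stable.

**Percent identity** is computed over *compared* columns only: columns
containing a gap or `N` in either row are excluded from numerator and
denominator.  No published definition of the identity statistic
accompanies the printed divergences, so this is the package's own
choice; it makes substitution-only simulations exact, and is the main
caveat when comparing against identities produced by other tools on
real sequences.  Inter-LTR divergence is `100 − identity`.

One known edge case: when a query is truncated exactly at a position
whose base happens to match the reference's final base, co-optimal
end-gap placements can attach a stray terminal residue; segmentation
results for heavily truncated queries should be read together with
their `partial`/`missing` flags.

## Molecular-clock dating

`age = divergence / rate` with rate 0.3 percentage points of inter-LTR
divergence per million years.  The rate is deliberately *not* halved:
the printed table arithmetic (9.5%→32 My, 2.9%→10 My, 14.4%→48 My, …)
matches `d/0.3`, meaning 0.3%/My is the rate at which the two copies
diverge from *each other*; each copy individually mutates at 0.15%/My,
and the simulator does exactly that.  Ages round to the nearest integer
My (ties away from zero); estimates above 50 My are reported censored
(">50 My"), both configurable.  One locus in the bundled table prints
20 My where the formula gives 21.33→21; the package reports the
computed value and the tests document the discrepancy.  Similarly, the
published subgroup percentage for 21/46 prints 45.6% although nearest
rounding gives 45.7%; `summarize_subgroups` rounds.

Ortholog-based lower bounds map presence of the orthologous insertion
in five primate groups to censored ages (chimpanzee >6, gorilla >8,
orangutan >15, Old World monkeys >25, marmoset >45 My).  The package
maps user-supplied presence flags only; it does not compute
whole-genome alignments.

## Subgroup classification and U3/R/U5 segmentation

Classification is nearest-consensus: global-align the query against the
three consensi and take the argmax identity, with a 1.0
percentage-point ambiguity margin and label-order tie-break.  Whether
the original assignment used nearest-consensus identity or tree
placement is not recorded; tree placement is available through the
phylogeny module as a cross-check.

The published per-subgroup U3/R and R/U5 boundary positions are given
only as ranges (298–337 and 399–435); the defaults are the midpoints
317 and 417, configurable per consensus.  Boundaries are projected
through the query–consensus alignment; a boundary landing in a query
gap maps to the next aligned query base, keeping the tripartition an
exact contiguous partition of the aligned query span.  Regions with no
aligned query residue are flagged `missing`; regions whose consensus
extent is not fully covered are flagged `partial`.

## Structure calling

Exact-word dot plots against an annotated reference provirus (8,806 bp,
ltr5–gag–pol–env–ltr3).  Per-gene coverage is the fraction of the
gene's reference word-start positions (word size 11) matched anywhere
in the element; thresholds 0.80/0.05 split present/truncated/absent.
The thresholds are the package's own operationalization — no published
criterion distinguishes "truncated" from absent — and were chosen so
that deletion fractions ≤0.15 are always called present, 0.30–0.90
truncated and ≥0.97 absent, with the in-between bands documented as
undefined by design.

LTR detection uses a shorter word (8) and a lower coverage floor
(0.35): an element whose LTRs have diverged ~6% from their subgroup
consensus (a 40 My-old element) retains an expected fraction
0.94⁸ ≈ 0.61 of intact 8-mers, so 0.35 leaves a ≥6σ margin, while a
random 2 kb flank covers <1% of consensus words.  (A 50% floor was
considered but fails sporadically at the oldest cohort ages.)  Element
hits are clustered with a 200 bp gap threshold; two qualifying clusters
≥1 kb apart count as a 5'+3' pair.  The caller prefers the element's
own subgroup consensus as LTR reference (the pipeline wires this up
automatically); the reference provirus's LTRs are the fallback.  Both
strands are scanned.  Elements with no homology at all are returned
`unclassified`, never silently called solo.  An element whose internal
genes are entirely deleted but which did not recombine into a solo LTR
would place its two LTRs adjacent and be merged into one cluster; the
default deletion band (≤0.85 per gene) keeps simulated elements away
from this degenerate case.

## Phylogeny

*Alignment.*  Progressive multiple alignment: pairwise p-distances from
global alignments feed a neighbor-joining guide tree (scikit-bio's NJ);
profiles are aligned pairwise up the guide tree with the same
affine-gap scheme, scoring columns by frequency-weighted sum of pairs.
Deterministic for fixed input order.  Pre-aligned FASTA can be loaded
instead for parity runs with external aligners.

*Parsimony.*  Fitch small parsimony with gaps and `N` as missing data
(a missing leaf is compatible with any state).  Site patterns are
compressed with multiplicities, and the search runs on
parsimony-informative patterns only; uninformative patterns contribute
a topology-independent constant (distinct observed states − 1) that is
added back to reported scores.

*Search.*  Random stepwise addition (each taxon inserted at its
best-scoring edge) followed by SPR hill-climbing that accepts the first
improving move per pass and stops at a local optimum — a deliberate,
simple reading of a "level 1" rearrangement search; no attempt is made
to reproduce any particular program's search schedule bit-for-bit.
Candidate insertions are scored exactly in O(1) vector operations per
edge from directional (edge-rooted) Fitch state sets; tests verify the
formula against full rescoring and the whole search against exhaustive
topology enumeration for 7 taxa.  All tied-best topologies are
retained; alignments with no informative sites return a star tree
rather than an arbitrary resolution.

*Bootstrap.*  Site resampling with replacement; replicate r draws its
randomness from `SeedSequence(seed, spawn_key=(r,))`, so runs are
reproducible and replicates independent.  Each replicate reweights the
precomputed site patterns (no re-encoding), runs one random-addition
start plus SPR, and the replicate trees are combined by strict
majority-rule consensus (splits in >50% of replicates) with integer
percentage supports — so clades below 50% support never appear, which
is also the display convention.  The consensus construction is
cross-checked against dendropy's implementation in the tests.

## The simulator

`simulate_provirus` inverts the clock: both LTRs start as identical
copies of the subgroup ancestor; each copy draws
`Binomial(L, age × rate/2/100)` substitution positions uniformly and
substitutes Jukes–Cantor style (uniform choice among the other three
bases).  Internal gag/pol/env are copied from the synthetic reference
provirus, optionally with one contiguous deletion per gene (default:
probability 0.5, fraction uniform in [0.35, 0.85] — inside the
caller's truncated band).  Solo LTRs form with configurable probability
as a hybrid of the two mutated copies at a uniform crossover point.
Uniform random flanks (500 bp default) are added.  Default indel rate
is zero so count-based oracles are exact; indels are available to
stress the aligner.

Defaults mirror the published cohort: 46 elements, subgroup mix
16/21/9 (hit exactly by largest-remainder allocation), solo-LTR
probability 29/46, ages drawn from {10, 15, 20, 25, 30, 40} My.

The three synthetic consensi derive from one random ancestor with
region-graded branch substitution rates (U3 12%, R 8%, U5 2.5% per
branch) and tail-truncation to 463/483/501 bp, giving pairwise
identities in the published 75–85% band and the real subgroups'
U3 < R < U5 conservation gradient.  The synthetic reference provirus
uses the LTR2C consensus as both LTRs (the full-length prototype is an
LTR2C element) around random internals proportioned 30.5/44.5/25%
across gag/pol/env.

**What the simulations do not capture.**  Internal genes accrue no
substitutions (only deletions), real LTRs contain indels and tandem
substructure, flanks are uniform random rather than repeat-rich genomic
sequence, and the synthetic consensi share no homology with the real
DFAM consensi.  Passing tests therefore establish correctness of the
*algorithms* under the stated generative model, not end-to-end accuracy
on real genomes; the real consensus region-similarity ranges and the
published tree topology are reproducible only with the external
reference sequences and are deliberately outside the test surface.

Two quantified biases, asserted as bounds in the tests: coincident
substitutions make measured divergence trail the applied mutation load
by <0.5 percentage points at cohort-scale divergences (≤12%), which at
40 My means the mean clock estimate sits ~1.6 My low (the 40 My
recovery band allows 3 My for this reason, versus 1.5 My at 10 and
20 My); and rounding three percentages to 1 dp can make a summary sum
to 100 ± 0.15.

## Problem sizes

The test suite and the acceptance script use: 100 random instances
(≤6 leaves, ≤30 sites) for the Fitch oracle; 50 seeded 7-taxon
datasets against exhaustive search over all 945 topologies; 200
simulated proviruses per age stratum; the full 46-element cohort with
200 bootstrap replicates for the three-clade segregation check.
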