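# Methods

## Scope and model

`ampbench` evaluates amplicon sequencing workflows against a mock
community: a set of named full-length 16S rRNA gene sequences with input
relative abundances. All comparisons between a read or variant (a
fragment, typically 200–450 nt) and a reference (~1–2 kb) use **infix
(semi-global) edit distance**: the fragment aligns inside the reference
with free terminal gaps on the reference, so a perfect substring scores 0.
Global distance would be dominated by length and is never used.

The expected unique variant count of a community under a primer pair — the
coverage denominator — comes from in-silico PCR: the forward primer is
matched on the plus strand, the reverse primer (stored as synthesized) as
its reverse complement, IUPAC-aware, ungapped and exact; the inter-primer
insert is extracted and deduplicated. When several hit pairs produce a
product, the innermost (shortest positive insert) pair is kept, mimicking
the dominant PCR product. Inserts can be extracted with or without the
primer-binding sequence (`include_primers`); the default excludes them,
matching a primer-trimmed read world. An `N` in a reference never
satisfies a primer position.

## The triage cascade

Variants are assigned the **first** matching category in a fixed order:
exact → primer-dimer → chimera → off-target → mismatch/contaminant. A
sequence that satisfies several tests (e.g. a chimera that also contains a
primer substring) deliberately receives the earlier label; the order is
part of the contract and is tested.

**Chimera (bimera) test.** For a variant `v` of length `L`, one forward
and one reverse semi-global DP sweep per reference give the profiles
`pre_A(k)` (distance of `v[:k]` to the best infix of A) and `suf_B(k)` for
every breakpoint `k` at once; the in-row dependence of the DP is resolved
with a prefix-minimum scan, and the sweep runs over all references
simultaneously (numba-jitted, with a pure-numpy fallback). The best
two-parent decomposition `d2 = min_{A≠B, 0<k<L} pre_A(k) + suf_B(k)` is
exact over all ordered pairs and breakpoints at `O(refs·L·M)` total cost.
The call is chimeric iff

* `d1 − d2 ≥ margin` (default 4 edits), where `d1` is the best
  single-reference distance — this guards against labelling ordinary
  mismatched variants as chimeric; and
* `d2 ≤ ⌈0.01·L⌉` — the two-parent model must actually fit, which rejects
  contaminants that merely prefer two references slightly.

Both thresholds are exposed (`TriageParams`). Equality of the DP with an
exhaustive per-split enumeration (computed independently with edlib) is
asserted over 500 random panels in the test suite.

**Off-target test.** Best infix identity (matches / alignment columns)
below 0.6 against every reference, or a single homopolymer run covering
≥ 50 % of the variant. This is a deliberate, documented heuristic for
sequences a taxonomy classifier would leave unclassified: uniform-random
DNA scores ~0.55 identity against unrelated 16S sequences, while genuine
16S fragments—even heavily mutated ones—stay well above 0.7.

**Mismatch vs contaminant.** Leftover variants are pooled with the
community's region sequences; pairwise distances are `1 − identity` of the
infix alignment (terminal gaps free, internal gaps count); average-linkage
(UPGMA, scipy) clustering is cut at the distance cutoff (default 0.15,
inclusive). Variants in a cluster containing at least one reference are
mismatches, others contaminants. Clustering runs on raw variants;
consensus collapsing is not applied before the call. Tie-breaking inside
the linkage is scipy's; ties have measure zero for these real-valued
distances.

## Merging, trimming, clustering

R1 and reverse-complemented R2 are merged at the ungapped offset
maximizing overlap matches (ties → larger overlap); success requires
overlap ≥ 50 nt and an overlap mismatch fraction ≤ 0.1. At mismatching
overlap columns the higher-Q base wins with quality `|q1 − q2|`; at
agreements the larger Q is kept. A negative best offset means the mates
read through each other (template shorter than the reads); only the
overlap region is then emitted, which removes adapter read-through
without a separate adapter trimmer. The substitution-only error model
makes a gapped merge unnecessary; indel-tolerant merging is out of scope.

Quality trimming is modified Mott: positions score
`cutoff − 10^(−Q/10)` (cutoff default 0.01) and the maximal-sum contiguous
segment is retained (first segment on exact ties), rejected below a
minimum length (default 200 nt, applied uniformly to every primer set).
Trim-length *selection* for denoisers uses a trailing moving average
(window 10; shorter prefixes use the plain prefix mean) over per-position
mean Q: the candidate length is the longest prefix with moving average
≥ Q30, then lengths are extended 1 nt at a time — R2 first, then R1 —
until `len_R1 + len_R2 − amplicon ≥ 30`, erroring if impossible at full
length. Clustering at 100 % similarity is exact string deduplication;
variant ids are ordered by descending total count, then sequence.

## Metrics

* accuracy = reads in exact variants / all denoised reads; 0/0 is missing
  (NaN), never 0.
* coverage = distinct *expected* variants hit by ≥ 1 exact variant /
  expected count; several workflow variants hitting one mock variant count
  once.
* chimera fraction = reads in chimera variants / all denoised reads.
* compositional bias = Spearman's ρ (mean ranks on ties) between input
  member abundances and output exact-match abundances; members sharing an
  identical region variant receive that variant's full read count each, so
  communities with shared variants have an intrinsic ρ ceiling below 1 —
  a region-resolution limit, not an estimator defect. Workflows without
  exact matches yield NaN and are omitted from downstream summaries.
* cross-talk rate = reads whose exact (i7, i5) pair is not assigned to any
  sample / all reads; index-quality contrasts use Welch's t and Hedges g
  (pooled, weighted SD, no small-sample correction).
* ANOVA uses sequential (type-I) sums of squares with main effects and all
  two-way interactions; η² = SS_term/SS_total, so terms plus residual sum
  to 1. Sequential SS matches the near-balanced full-factorial designs
  this tool targets; the term order is the factor column order and is
  recorded in the output table.
* Analytic rarefaction without replacement:
  `E[S(d)] = Σ_i 1 − C(N−n_i, d)/C(N, d)` via log-gamma, clamped to
  observed richness for `d ≥ N`.

## Synthetic-data generator

The generator is the package's ground-truth instrument, not a fixture. It
emulates:

* templates drawn from community amplicon inserts proportional to input
  abundance (abundances default to normalized lognormal(0, 0.8) draws —
  uneven, qPCR-like);
* chimeric templates `A[:k] + B[k:]` with distinct-sequence parents drawn
  by abundance. The rate is set directly or through an elongation-time
  knob `rate(t) = 0.04·exp(−ln2·(t−15)/165)`, calibrated to halve between
  15 s and 180 s; the exponential form is this simulator's convention for
  the observed monotone trend, not an estimated mechanism. Breakpoints are
  uniform at least `breakpoint_margin` (default 20 nt) from either end: a
  nascent strand shorter than that cannot stably re-anneal to re-prime,
  and a breakpoint a few nt from an end is in principle indistinguishable
  from a point mutation for any reference-based test;
* contaminants: community inserts mutated at 25 % divergence (16S-like but
  outside every 15 % clade), or a user-supplied pool;
* primer-dimers: a concrete forward-primer expansion joined to the
  reverse complement of a reverse expansion;
* off-target artifacts: 120–200 nt low-complexity sequences dominated by a
  homopolymeric tract (≥ 60 % of the length);
* reads: R1 = template prefix, R2 = reverse-complement prefix, padded with
  random adapter-like bases when the template is shorter than the read
  (2 × 300-style read-through); Q per position ~ Normal(profile, 2),
  clipped to [2, 60], with linearly decaying profiles (R1 38→31, R2
  37→24 — R2 stochastically worse); each base miscalls with probability
  10^(−Q/10) uniformly to another base. A clean read whose template region
  is hit becomes `mismatch_error` in the truth table. `errors_enabled=False`
  turns miscalls off for closed-loop checks;
* index reads: 8-nt i7/i5 per sample; with probability `crosstalk_rate`
  the emitted pair is swapped to a combination absent from the plan, and
  such reads' index Q is lowered by `crosstalk_q_penalty` (default 5).

One `numpy` generator seeded from `SimConfig.seed` drives all stages;
reruns are byte-identical (FASTQ Q capped at 41 on write, Phred+33).

The default synthetic community has 37 members collapsing to 23 region
variants. Two insert regimes exist: independent random inserts
(`divergence=None`, pairwise ~75 % — "well separated") and
ancestor-mutation inserts (e.g. `divergence=0.15`, closer to real 16S
variable regions). Detector-recovery suites use the separated regime
because reference-based chimera detection is only identifiable when
parents differ enough around the breakpoint; with realistic 16S
similarity some chimeras are inherently undetectable, which is a property
of the problem, not of the implementation.

**What passing tests do not show.** The generator has no indels, no PCR
cycle-by-cycle amplification or polymerase-specific fidelity, no
position-dependent error motifs, no chimera breakpoint clustering at
conserved regions (a weighting hook exists but is off by default), and
its communities are either more diverged or more cleanly structured than
real soil communities. Perfect triage recovery on separated synthetic
communities therefore bounds the best case; real-data categories (and the
published real-run numbers such as per-run cross-talk percentages or
denoiser coverage ceilings) are outside what a desk-scale synthetic
benchmark can reproduce.

## Problem sizes in the shipped suites

Closed-loop evaluation runs 2 samples × 2500 reads (depth at which the
coupon-collector failure probability for 23 uneven variants is < 1e-5);
ground-truth triage recovery uses 2 × 1000 reads over an 8-member /
6-variant separated community; parameter recovery uses 50 replicates of
10⁴ templates (chimera rate 0.03, cross-talk 0.0025); oracle equivalence
uses 500 random panels of ≤ 5 references × ≤ 300 nt. These sizes are the
package's own choices balancing statistical resolution against a quick
default test run.

## Known limitations

* The off-target heuristic replaces taxonomy-based classification; it is
  tuned for "unclassifiable or low-complexity", not for detecting real
  off-target amplification of non-16S genomic loci with 16S-like
  composition.
* `exact_match` containment treats any full-reference-substring variant as
  exact, including fragments shorter than the amplified region that
  survive trimming.
* Hedges g is reported without the small-sample correction factor.
* Spearman ρ p-values are intentionally not reported; workflow-level
  inference is done through the ANOVA layer.
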