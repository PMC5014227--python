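# Methods

This note documents the models and procedures implemented in `bacatlas`,
the parameters that matter, what the synthetic data does and does not
emulate, and the design choices made where the design was genuinely open.

## Discriminative k-mer classification

The arm classifier follows the discriminative-k-mer idea: during index
construction every k-mer (k = 19 by default, strand-canonicalized because
clone insert orientation is arbitrary) is attributed to the targets it
occurs in. K-mers occurring in exactly one target are kept under that
target's label. K-mers occurring in exactly the short- and long-arm targets
of the *same* chromosome — and nowhere else — are kept under that
chromosome's centromeric pseudo-target (`4HC` etc.), exploiting the fact
that flow-sorted arm fractions overlap across the centromere. All other
multi-target k-mers are discarded.

Rare k-mers (within-target total count below `min_kmer_count`, default 2)
are dropped before attribution. This filter exists to scrub sequencing
errors out of *read-based* targets; on assembled single-copy target
sequences — where almost every k-mer occurs exactly once — it must be
disabled (`min_kmer_count=1`), and the default synthetic pipeline does so.
The rarity filter is applied per target, not globally: a k-mer rare in one
target but frequent in another is treated as absent from the first.

Classification counts a BAC's k-mer occurrences (with multiplicity; a
distinct-k-mer mode is available) found in the index, per label. With best
and second-best counts h₁ and h₂, the confidence is

    c = h₁ / (h₁ + h₂)        (c = 1 when h₂ = 0)

and the best label is accepted iff c is *strictly* greater than the
threshold (default 0.75) — a 30-vs-10 split scores exactly 0.75 and is
rejected. Ties for the top label are rejected as well. The two-best-targets
ratio is the minimal [0, 1] confidence consistent with the classifier
family this mirrors; it is configurable. A clone lying mostly inside the
centromeric overlap legitimately receives the centromeric label even if its
insert pokes out slightly; the simulator's ground-truth labels therefore
follow the majority of the insert's bases.

The index is serialized with an explicit magic string and version, followed
by a JSON header and the raw sorted k-mer/label arrays.

## Annotation rules

Alignment hits of gene models against BAC nodes (12-column tabular records;
a built-in exact-seed matcher stands in for an external aligner on
synthetic runs) pass three filters, in this order:

1. node length ≥ 200 bp — applied to the *node*, not the alignment length;
2. e-value ≤ 1e-20;
3. gene models hitting ≥ 10 distinct BACs are excluded outright (these are
   overwhelmingly repeat/transposon-derived and would swamp the counts).
   The distinct-BAC count is taken after filters 1–2.

Gene counts are distinct-model counts: a model hitting three nodes of one
BAC counts once for that BAC. Per-arm unique counts are computed within the
arm; the genome-wide unique count is computed across all BACs, so the
per-arm column sum can exceed it when models span arm boundaries — both
numbers are reported.

The built-in matcher anchors exact 31-bp seeds (sampled at half-seed
stride, both strands), verifies each candidate diagonal by direct
comparison over the overlap span, and emits one record per (node, gene)
with pseudo-e-value 1e-30 when identity ≥ 0.95 over ≥ 200 bp. It is
deterministic and strand-aware; it does not model gaps or alignment
statistics and is not a general-purpose aligner.

## Synteny voting and map joins

Hits with e-value ≤ 1e-20 vote for reference chromosomes; a strict
plurality places the BAC, and its position is the arithmetic mean of its
hit coordinates on the winning chromosome only. Ties leave the BAC
unplaced (conservative; the alternative of arbitrary choice would
fabricate placements). Contig votes count one vote per placed member BAC.
Positions keep the subject map's units; no implicit conversion.

The two-map join chains marker → (map A group, cM), marker → BAC, BAC →
(map B group, cM), keeps only chains whose group pair is in the configured
orthology table, and collapses duplicate (marker, BAC) chains. Inversions
are flagged by Kendall's tau over sliding windows of consecutive anchor
pairs (default 10 pairs), merging runs of ≥ 2 consecutive negative-tau
windows. The window and run parameters are this package's own choice — the
phenomenon is usually reported visually from dot plots without a stated
detection rule — and should be treated as a screening heuristic, not a
breakpoint caller.

## Landscape windows and deviant regions

Windows of `window` bp advance by `step` bp from position 0 of each
chromosome (production defaults 40 Mb / 2.5 Mb; the last partial window is
emitted and flagged). A BAC belongs to every window containing its anchor
coordinate — a point, not its insert interval, matching how clones are
anchored to golden-path coordinates. Per window:

- p0 / p1 / p3plus: proportions of member BACs with 0, exactly 1, ≥ 3
  high-confidence gene models (post frequent-model exclusion);
- GD = |union of HC models over member BACs| / n_bacs;
- RF = (max cM − min cM) / (max bp − min bp, in Mb) over member BACs —
  the literal cM/Mb ratio rather than a regression slope (a slope mode
  exists). RF is undefined on a zero-bp span.

Windows with fewer than `min_bacs_per_window` (default 5) BACs report
missing GD/RF and are excluded from threshold computation. Deviant regions
are windows simultaneously in the top GD quantile (default 0.75) and the
bottom RF quantile (default 0.25), both genome-wide over non-missing
windows, merged when overlapping or adjacent. Quantile thresholds make the
visual "red on green" reading of a landscape heat map explicit and
scale-free; with exchangeable profiles they admit a small rate of isolated
false windows (~6% of windows under independence), which surface as
single-window regions easily distinguished from multi-window islands.

## Rarefaction and the saturation asymptote

The screening matrix (pools × clones, 0/1) is resampled by permuting the
pool order (default 10,000 permutations, seeded) and recording cumulative
unique positive clones per number of pools applied. Exhaustive enumeration
over all orderings is provided up to 8 pools and serves as the test oracle.
The mean curve is fitted by least squares to a saturating model — negative
exponential A(1−e^(−bx)) by default, hyperbolic Ax/(B+x) as an alternative;
neither form is canonical for this problem, so estimates always carry the
model name. The asymptote A is constrained to at least the observed unique
count. Because clones carrying more genes are detectable by more pools, the
asymptote systematically understates the true gene-bearing clone count;
this bias is reproduced, not corrected.

## Assembly statistics

N50/L50 follow the resource-table footnotes read literally, which use
different inequalities: N50 is the length at which the descending prefix
sum first reaches *at least* half the total; L50 is the smallest prefix
count whose sum *exceeds* half. For node lengths [50, 50]: N50 = 50 but
L50 = 2. A strict mode applies the common ≥-for-both convention. Group
tables use unweighted means over member BACs; the "All" row is recomputed
from the pooled clone set, never from group means, so avg length × n_bacs
reproduces total length exactly (before rendering-time rounding).

Cross-assembly concordance counts bases inside maximal exact matches of
≥ 100 bp (either strand, overlaps merged) — a deliberate lower bound on
gapped-aligner coverage that needs no external binary and is exact on
synthetic data. A clone pair is discarded as discordant when coverage is
below 33% *in both directions*; a single-direction mode exists.

## The synthetic data: what it emulates and what it does not

Defaults (chosen once as the package's study conditions):

- 7 chromosomes named 1H–7H; arms 1.6 Mb (S) + 2.0 Mb (L) sharing a 120 kb
  centromeric overlap (~3.5 Mb per chromosome, ~24.4 Mb genome). The first
  chromosome is a single whole-chromosome target with no arm split,
  mirroring resources where one chromosome cannot be arm-sorted.
- GC content 0.445; uppercase ACGT only (no Ns), keeping k-mer logic exact.
- 300 genes of 2 kb per chromosome, placed by thinning a uniform proposal
  against a piecewise-linear density ramp rising 4× from centromere to
  telomeres; optional interior islands add a uniform block of extra genes
  (the default pipeline plants one 24%-of-chromosome island with 120 extra
  genes at the centre of chromosome 2). Gene models are classified HC with
  probability 0.45, LC otherwise.
- 5 shared repeat families of 3 kb, 30 copies each, pasted genome-wide
  before gene placement — so a minority of gene models legitimately overlap
  repeats and exercise the frequent-model exclusion.
- A genetic map per chromosome: the cumulative integral of a bathtub-shaped
  recombination intensity (low plateau of 1 Mb at the centromere, rising
  linearly to the chromosome ends; floor 2% of the distal intensity),
  scaled to 150 cM. Weakly monotone by construction.
- A 500-clone library of 100 ± 10 kb inserts drawn from chromosomes
  proportionally to length (~2× redundancy, the regime of a
  minimal-tiling-path resource), each cut into 1 + Poisson(18.7) nodes
  with a 60 bp deletion at every internal junction; nodes < 200 bp dropped.
- Probe screening: genes partitioned uniformly among 30 pools; a pool
  holding ≥ 1 of a clone's genes detects it with probability 0.6; every
  (pool, clone) cell is additionally a false positive with probability
  0.001.
- Cross-species hit tables: a strictly collinear ortholog layout (gene i of
  chromosome c maps to position i on foreign chromosome Os(c)), one record
  per true clone–gene overlap at e-value 1e-30, plus Poisson off-target
  records per clone at e-value 1e-21 (they pass the cutoff; voting must
  out-shout them).
- Landscape windows for this toy scale: 400 kb / 25 kb — the same 16:1
  window:step ratio as the production 40 Mb / 2.5 Mb defaults.

Coordinates are 0-based half-open internally everywhere; exported
alignment-style tables use 1-based fully-closed coordinates and say so.
One seed drives each operation through a single NumPy generator stream, so
identical (spec, seed) gives byte-identical outputs.

Not emulated: read-level sequencing (no reads, qualities or error models),
pooled-clone deconvolution, restriction-fragment fingerprinting, assembly
collapse over tandem repeats, gapped alignment statistics, and real
cM-per-Mb magnitudes (the toy chromosomes compress 150 cM into ~3.5 Mb, so
absolute RF values are ~40× a real cereal's; all RF-based logic is
quantile- or ratio-based and unaffected). Passing tests therefore
demonstrate the correctness of the *procedures* under controlled structure,
not performance on real repeat-laden sequence.

## Numerical and edge-case policy

- Non-ACGT letters break k-mer enumeration (no k-mer spans them) and are
  excluded from GC content entirely; an all-N assembly has undefined GC,
  reported as missing.
- Empty inputs: an empty library classifies to an empty list with a 0-of-0
  rate; an empty detection matrix, empty node list or empty assembly is an
  error.
- Tie-breaks: classification ties → unassigned; vote ties → unplaced;
  equal S/L base counts in truth labelling → S.
- The asymptote fit uses bounded least squares (A ≥ observed unique count,
  rates > 0) with analytic-free initial values; non-convergence raises an
  error carrying the optimizer message rather than returning a value.
- Problem sizes in the test suite and acceptance script (24 Mb genome,
  500 clones, 10,000 permutations) were chosen so the full analysis
  completes in a couple of minutes on one CPU while every recovery
  statistic is estimated from hundreds of clones.
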