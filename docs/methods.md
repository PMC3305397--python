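# Methods

## Coordinate conventions

All internal coordinates are 0-based half-open (BED convention); every
user-facing report renders 1-based fully-closed strings
(`3L:18384438..18385008`), and the two forms round-trip losslessly.  The
printed form of that example spans 571 bp.  Chromosome names are matched
by exact string identity after whitespace removal, so the typographic
"3 L" found in print legends normalises to "3L".

## Binding-site scoring

A PFM of counts `n[j, b]` (L positions × A,C,G,T) becomes a log2-odds PWM

    W[j, b] = log2( (n[j, b] + p·q_b) / (N_j + p) / q_b )

with column totals `N_j`, background frequencies `q` (default uniform
0.25) and total per-column pseudocount `p` (default 1, distributed across
bases by `q`; keeps zero counts finite without overwhelming small count
matrices).  A window's relative score `(S − S_min)/(S_max − S_min)` is
matrix-independent; a site is called at relative score ≥ 0.90, the
conventional percentage cut-off, with ties inclusive ("cut-off" read as a
minimum acceptable score).  Both strands are scanned by default
(enhancer activity is strand-agnostic); a minus-strand hit is reported on
forward-axis coordinates with the motif-oriented word stored.  Windows
containing N are skipped rather than scored.  Overlapping hits of the same
motif are all reported — downstream cluster counting needs raw
occurrences, and de-duplication would silently change the k-in-w rule.

Degenerate matrices whose best and worst scores coincide (fully uniform
PFMs) are constructible, but relative scoring of them raises an error
rather than returning an arbitrary value.

## Cluster calling

A hit is cluster-eligible iff some half-open window `[x, x+w)` contains
the start positions of ≥ k hits including it; windows slide at 1 bp.
Equivalently, some run of k consecutive start-sorted hits including it
spans < w.  Defaults k = 3, w = 400 bp.  Counting uses hit *starts*, not
full containment, making the rule insensitive to motif length.  Eligible
hits whose consecutive starts are ≤ w apart chain into one maximal,
disjoint cluster — single merged calls rather than every qualifying
window.  Plus- and minus-strand hits are pooled by default (configurable),
and pooled multi-factor hit lists can impose per-factor minimum member
counts.  The implementation is verified against exhaustive window
enumeration.

## Conservation

Tracks are PhastCons-style per-base probabilities in [0, 1] read from text
bedGraph or fixedStep wiggle (equivalent encodings yield identical
tracks; overlapping bedGraph intervals are an error).  Values outside
[0, 1] are rejected by default; an explicit option clamps (with a logged
warning) or accepts them for non-probability tracks.

Missing (uncovered) bases default to score 0 (`as_zero`): conservation
tracks conventionally omit unalignable sequence, which is non-conserved
for this purpose.  The `exclude` policy averages covered bases only and
treats a fully uncovered interval as an explicit error.

Region-level conservation is the arithmetic mean over all bases (not the
fraction of bases above a cut-off).  A "conserved motif" is a hit whose
footprint mean reaches the site cut-off.  No canonical published value
exists for either cut-off; both default to 0.5 — the midpoint of the
probability scale — are independent parameters, and are recorded in every
report so sensitivity can be assessed.

## Landscape analysis

Non-coding regions are the per-chromosome complement of annotated exons
(introns + intergenic) by default; the complement of whole gene spans
(intergenic only) is one flag away.  Regions shorter than 100 bp are
dropped because per-kb densities on very short regions are numerically
unstable; the threshold is configurable.  A hit is assigned to the region
containing its start, consistent with cluster calling, so boundary-
straddling hits count exactly once.

Each region's statistics are mean conservation and conserved-motif count
normalised per 1000 bp.  The percentile of a query is
`100 × #{regions with metric strictly < query} / #regions`, with the query
excluded from the denominator when it is itself a member of the
distribution; strict inequality matches the natural phrasing "X % of
regions are less conserved / have fewer sites".  Which motif collection
the density counts is an explicit input (a single matrix or several).

## Synthetic genomes

The simulator emulates exactly the structure the landscape analysis
assumes — enhancers conserved and motif-dense relative to background —
with one integer seed determining everything (byte-identical reruns).

* Background sequence is i.i.d. with GC 0.42 (fly-like euchromatin);
  empirical GC converges within 2 points of the target by 100 kb.
* Genes are regular ladders (default 3 exons × 300 bp, 400 bp introns).
  Exons receive elevated conservation like enhancers, so the exon mask is
  exercised against realistically conserved coding sequence.
* Per-base conservation is Beta-distributed i.i.d. within a region class:
  background Beta(2, 8) (mean 0.2), elevated Beta(8, 2) (mean 0.8) — the
  simplest model producing the region-mean separation the landscape
  analysis relies on; parameters exposed.
* Planted sites are drawn per column from the planting PFM's frequency
  model and accepted only at relative score ≥ 0.95 (rejection sampling,
  consensus fallback) — near-consensus variation rather than the trivial
  maximum, exercising behaviour near the 0.90 cut-off.  Default 3 sites
  per enhancer inside a central 400 bp core, non-overlapping, random
  strands.  Decoy sites (same sampling, background conservation) are
  planted in intergenic gaps at a low Poisson rate (default 0.05/kb).
* Placement distributes genes/enhancers along each chromosome with
  minimum 200 bp gaps and multinomially allocated slack; infeasible
  requests fail before any file is written.  The `worked_example` preset
  fixes one chromosome of 60 kb, 8 genes and one 571 bp enhancer welded
  exactly 6 kb downstream of a gene end — a human-readable fixture tying
  tests to the worked example.
* The default planting matrix is an 8-bp AT-rich homeodomain-style model
  (synthetic, not any curated database entry): a sharp TTTAT core with
  softer 3' columns so near-consensus words exist above high cut-offs.

What the simulator does **not** model: indels and alignment structure
(conservation is i.i.d. per base, not phylogenetically simulated),
dinucleotide composition, overlapping genes, alternative isoforms beyond
overlapping exon masks, and realistic motif false-positive structure.
Passing recovery tests therefore demonstrates the pipeline's correctness
and its behaviour under the stated effect sizes, not performance on real
genomes.

## Problem sizes and numerical choices

The validation suite uses 60–160 kb genomes (hundreds of non-coding
regions for percentile checks; 100 seeded replicates for end-to-end
recovery) — small enough for exhaustive brute-force oracles to verify
every stage, large enough for stable empirical distributions.  The
acceptance script aggregates 25 replicates.  Scores are float64
throughout; relative scores are clipped to [0, 1] against rounding;
threshold comparisons allow 1e-12 slack so exact-boundary scores are
inclusive; BED scores are relative score × 1000 rounded to integers.
Ties at per-column argmax (consensus) break in A,C,G,T order.

## Known limitations

* Genome-wide percentile values are only comparable under identical
  assembly, annotation release, conservation track version and cut-offs;
  published whole-genome percentages cannot be verified without that
  exact bundle, which is why every report logs its thresholds.
* bigWig/bigBed binary tracks are out of scope (text bedGraph/wiggle
  only), as are motif discovery, higher-order background models and
  p-value calibration of PWM scores.
* The cluster rule is the deterministic k-in-w scan; no statistical
  significance is attached to cluster counts.
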