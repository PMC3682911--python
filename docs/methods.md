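# Methods

This note documents the models implemented, the numerical choices behind
them, what the synthetic-data generator does and does not emulate, and the
known limitations.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Supermatrix assembly

Per-gene sequence pools are reduced to one sequence per species (the one
with the most non-missing residues; ties go to input order), concatenated
with 1-based inclusive partition ranges, and filtered:

- **Minimum data rule.**  Species whose *total* non-missing length across
  all genes is below 250 bp are removed (strict "less than"; a taxon with
  exactly 250 bp stays).  A per-gene-fragment variant of the rule is
  available behind the `per_gene` flag; the species-total reading is the
  default because it is the one consistent with a minimum surviving taxon
  of a few hundred bp when single short fragments are common.
- **Deduplication.**  Taxa whose rows are identical — same present cells
  *and* the same missingness footprint, with `?`, `N` and `-` equated for
  footprint purposes — collapse to the case-insensitively first label.
  Requiring the footprint to match is the strict reading of "identical
  across all genes": two taxa distinguishable by which genes they have are
  not identical.
- **Reconciliation.**  Species labels are matched across genes by exact
  string equality after whitespace normalization; no synonym resolution.
  Merging genes sequenced from different individuals under one binomial is
  what creates composite terminals, exactly as in real supermatrices.

Matrix statistics report raw and integer-rounded percentages; the rounded
convention is what published summaries print (e.g. 2 497 of 12 896 bp →
19% present / 81% missing).

## Alignment layer

Pairwise alignment is Gotoh's three-state affine dynamic program,
maximizing score with a gap of length L costing `open + L·extend` (the
first gap residue pays both).  Defaults: Blosum62 with open = 12,
extend = 3 for amino acids; match +5 / mismatch −4 with the same gap costs
for nucleotides (the rRNA scoring is not fixed by any published source;
these mirror common aligner defaults).  Traceback ties break
diagonal > up > left, so output is deterministic.  The same DP runs on
column-frequency profiles (sum-of-pairs expected score, occupancy-weighted),
which gives profile–profile merging the property that member alignments are
only ever split by new gap columns, never reordered.

Protein-coding genes align via translation: the reading frame is the first
of the three offsets with no internal stop codon (a record with stops in
every frame is rejected with a reason); the amino-acid profile alignment is
expanded 3:1 back onto the nucleotides, so degapping the output reproduces
each input exactly.  Progressive alignment follows a UPGMA guide tree on
k-mer distances (k = 6 for nucleotides, 3 for amino acids) — any
deterministic guide tree would do, and downstream checks are
property-based.  End trimming removes leading/trailing columns with
non-gap occupancy below 0.5; columns under 25% occupancy can be listed for
manual review (the by-eye adjustment step of real pipelines cannot be
codified).

## Likelihood engine

- **Model.**  Per-partition GTR with off-diagonals `Q_ij = r_ij π_j`,
  GT ≡ 1, normalized to one expected substitution per unit branch length;
  detailed balance holds by construction.  Among-site rates use Yang's
  discrete gamma with k = 4 equal-probability categories represented by
  their means (k is configurable; k = 1 reduces to plain GTR).  Base
  frequencies are empirical per partition.  Branch lengths are shared
  across partitions; each partition has a positive rate multiplier, kept at
  mean 1 by renormalizing multipliers and absorbing the factor into branch
  lengths (likelihood-invariant).
- **Pruning.**  Felsenstein's algorithm over compressed site patterns,
  vectorized over categories × patterns × states, with per-pattern scaling
  and log accumulation at every internal node (needed well before
  thousands of taxa).  `?`, `N` and `-` are fully missing (all-ones
  partials): an all-missing column contributes exactly zero
  log-likelihood, and pattern compression makes site order irrelevant
  bit-for-bit.  Transition matrices come from the symmetrized
  eigendecomposition (real spectrum by reversibility); tiny negative
  entries from round-off are clamped at zero.
- **Branch-length optimization.**  For each branch, the likelihood as a
  function of its length needs only the inside ("down") partial below it
  and the outside partial of the rest of the tree; the engine maintains
  both through a Gauss–Seidel sweep (outside partials updated on the way
  down, inside partials refreshed on the way back up), so each 1-D
  optimization is exact at the current state and the sweep never decreases
  lnL.  The 1-D maximizer brackets the sign change of the analytic
  derivative geometrically and then runs safeguarded secant iteration; a
  final guard never accepts a point worse than the input.  Lengths are
  bounded to [1e−8, 10]; sweeps stop when a sweep gains < 0.01 lnL
  (default) or after 50 sweeps with a warning.
- **Model optimization.**  Coordinate ascent over partitions: L-BFGS-B on
  log-exchangeabilities, log-α (bounds [0.02, 100]) and log-multiplier,
  with empirical π.  A partition with no variable pattern keeps defaults
  with α pinned at the upper bound and a warning.  Steps that would lower
  the partition lnL are rejected, so the ascent is monotone.
- **Search.**  Starting trees are random-addition-order Fitch parsimony
  (bitmask sets, exact up/down decomposition so each insertion point is
  scored in O(1) per pattern); ties go to the first edge in preorder.  NNI
  hill-climbing evaluates both rearrangements of every internal edge with
  local 5-branch re-optimization (candidates reuse the parent engine's
  partials for unchanged subtrees), accepts the best strict improvement,
  rescans until no edge improves, and finishes with a full branch-length
  re-optimization.  The protocol-level default is 11 seeded starts, best
  final lnL, ties to the first seed.

## SH-like aLRT support

For an internal branch, per-site log-likelihood vectors are computed for
the current NNI-optimal configuration and its two NNI alternatives (each
with local branch re-optimization).  RELL resampling draws B = 1000
multinomial site weightings; each replicate's three totals are centered by
the corresponding original totals, and support is the percentage of
replicates in which the observed margin `l1 − l2` strictly exceeds the
replicate's centered best-minus-second margin.  Identical vectors give
support 0; a margin that is huge relative to per-site variance gives 100;
support depends only on the vectors, not on which configuration was called
"current".  Per-edge RELL seeds derive from (master seed, edge index), so
annotated trees are byte-reproducible.

**Calibration caveat.**  At a genuinely zero-length branch the observed
margin is the maximum of three topologies fitted to the same noise and has
the same scale as the resampled centered margins, so this statistic family
yields mean support around 40–55 at null branches rather than near zero —
our implementation averages ≈ 37 on 8-taxon star simulations, and FastTree's
SH-like supports average ≈ 58 on identical data.  What *is* guaranteed, and
what the tests assert alongside the stricter stated bar, is that null
branches essentially never reach the strong-support region (0/50 null edges
above 95 in the calibration), while a branch of 0.5 expected substitutions
with 5 000 sites exceeds 95 in 100% of replicates.  Practical reading:
treat SHL < 85 as "not established", not as evidence of absence.

## Diagnostics and audit

The completeness regression is ordinary least squares of terminal branch
length on proportional completeness (present bp / total matrix length) with
Pearson r and its two-sided t-test; a constant predictor is an error, not a
silent r = 0.  Support summaries use the strictly-greater convention
("share of internal edges with SHL > 85") while the strong-support label
for individual conflicts uses ≥ 85; both thresholds are exposed.

The monophyly audit is a rooted computation (clade status depends on root
placement; analyses of unrooted search output should first root on the
designated outgroup or on a reference bipartition, as
`analysis/06_taxonomy_audit.py` does).  A taxon with k maximal pure clades
is monophyletic iff k = 1; otherwise it is paraphyletic when the intruders
inside its MRCA form exactly one clade, else polyphyletic — an
operationalization of terms the literature uses informally.  A conflicting
branch is an internal edge whose child clade contains a proper non-empty
subset of the taxon plus at least one non-member; the unrooted four-point
incompatibility criterion was rejected because it cannot see rooted
non-monophyly of a set whose complement is small.  Singletons are
"trivial" and never flagged.  The rogue screen (weakly supported
attachment + majority-foreign neighborhood of ≥ 5 labeled tips) is
report-only: the published removals were judgment calls, and the screen is
a reproducible proxy, not a replacement.

## Synthetic data: what it emulates, what it does not

The generator draws Yule trees (rescaled to a chosen height), evolves
per-partition GTR+Γ sequences, and masks them gene-wise: each taxon keeps
each gene with that gene's published coverage fraction (12S 0.56, 16S 0.57,
BDNF 0.18, c-mos 0.40, cyt-b 0.48, NT3 0.10, ND2 0.45, ND4 0.37, PDC 0.09,
R35 0.10, RAG-1 0.33, RAG-2 0.11); scaffold taxa (default 10%) always keep
the seven nuclear genes; taxa falling under 250 bp are redrawn, then
dropped with a log entry.  Whole-gene presence alone yields only ≈ 63%
missing cells with those fractions; the real matrix reaches 81% because
present sequences are partial fragments (mean 2 497 bp over 3.75 genes).
Retained genes are therefore truncated to a contiguous window covering
`fragment_fraction` of the gene, default 0.53, derived from those two
printed means; the expected missing fraction `1 − f·Σ p_i L_i / Σ L_i` is
then ≈ 0.806.  Realized missingness runs one or two points lower because
the scaffold and the minimum-data redraws both add data.

Planted taxonomies cut the tree into a requested number of disjoint clades
(splitting the largest clade repeatedly), pair realized clades with the
requested sizes by rank — arbitrary size vectors cannot generally be
realized exactly as clades on a given topology — and apply violation moves
(tip → foreign genus) to create known non-monophyly.

Not emulated: indels and alignment error, heterotachy, base-composition
drift across the tree, rogue placement caused by contamination or
misidentification, and phylogenetically clustered gene absence (an
"mtDNA-only clade" knob would concentrate nuclear absence but is not part
of the default stated world).  A green simulation test therefore
establishes the correctness and calibration of the algorithms under the
declared generative model — not robustness to alignment artifacts or
systematically non-random missingness.

## Scalings used by the tests

Everything runs on one CPU within the suite's budget: topology recovery
uses 8-taxon Yule trees (stated range 8–32) with six 1 000-bp gene
partitions and the coverage fractions of the six best-sampled genes, 11
starts × 20 seeds; α and branch-length recovery use 8/6-taxon fixed trees
with 10⁵/5·10⁴ sites (pattern compression keeps these cheap); SHL
calibration uses 10 star-truth trees × 5 edges for the null and 20
strong-branch replicates; the regression null uses 100 seeds at n = 100
and the type-I check 500 seeds at n = 60.  The full-scale published
analysis (4 162 taxa, 12 896 bp, supercomputer-days) is far outside desk
scale, and its absolute lnL is not a target.

## Known limitations

- NNI-only search: no SPR/TBR, so deep rearrangements can require many
  accepted moves; adequate at test scale, slow for thousands of taxa.
- No GTRCAT-style approximation; everything is GTR+Γ throughout.
- Empirical (not ML) base frequencies.
- The NEXUS reader handles the dialect this package writes (plus standard
  matrices readable by dendropy), not the format zoo.
- Codon-position partitioning is implemented in the partition scheme but
  the simulator generates gene-level models only.
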