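# Methods

## Scope and data model

The package starts where RepeatMasker stops: a `.out` hit table and a
`.align` alignment file against a TE consensus library, plus a genome
FASTA, a chromosome-size table, a gene GFF3, CpG-island intervals and a
recombination map.  All intervals are held 0-based half-open in memory;
readers and writers convert at the boundary (GFF3 and `.out` genomic
coordinates are 1-based inclusive on disk, BED and the map TSV half-open).
Consensus coordinates are the one deliberate exception: they live in
consensus space and remain 1-based inclusive, as in the dialect, with
minus-strand `.out` rows normalised on parse so `cons_start ≤ cons_end`
always holds.

The `.align` dialect varies between RepeatMasker versions, so the package
defines one canonical dialect (the hit's `.out` row followed by interleaved
wrapped query/consensus lines) that its own writer and the simulator both
emit; the parser accepts exactly that dialect and joins blocks to `.out`
rows by coordinates, keeping orphan blocks with a warning.

## Divergence and age

Per alignment, columns are classified as match, transition, transversion,
gap or ambiguous; gaps and non-ACGT symbols are excluded from the site
count because substitutions are undefined there.  The CpG adjustment
follows the convention of the standard divergence-summary tooling: a
transition at a column whose consensus base is the C or G of a CpG
dinucleotide counts 1/10, and if both bases of one CpG pair carry
transitions the pair counts as exactly one transition; transversions are
never reweighted.  CpG pairs are read off the consensus row of the
alignment with adjacency taken across gap columns (CG occurrences cannot
overlap, so the pairing is unambiguous).  The adjustment is a flag:
unadjusted K is available and, with an all-false CpG mask, equals the
textbook K2P distance.

K is reported in percent.  The estimator raises on saturation
(`1 − 2P − Q ≤ 0` or `1 − 2Q ≤ 0`) rather than clamping, and copies
aggregate fragment K by length-weighted mean.  Age conversion uses
`T = (K/100)/(2μ)`; the factor 2 reflects that the consensus approximates
the ancestral state, so copy-to-consensus divergence accumulates along the
copy's branch at the pairwise rate.  With the collared-flycatcher rate
μ = 2.3 × 10⁻⁹ /site/yr this puts the recent/ancient boundary K = 7
(inclusive) at ≈ 15.2 My.  μ and the threshold are `AgeModel` fields; the
rate used for TE dating is deliberately distinct from any rate used to
infer the recombination map, which enters this package only as data.

## Defragmentation and filtering

Merging is a deterministic greedy left-to-right pass over hits sorted by
(chrom, start).  A hit joins an open copy iff (a) it shares the copy's
last fragment's run ID — RepeatMasker's own statement that the fragments
are one interrupted element, allowed to bridge any gap — or (b) family,
chromosome and strand match, the genomic gap is ≤ `max_gap` (default
2 500 bp), and consensus coordinates are collinear for the strand with up
to `cons_overlap_tol` (15 bp) of backtrack.  When several open copies
qualify, the one whose last fragment ends nearest wins; run-ID matches
beat proximity.  Every hit lands in exactly one copy (a partition;
asserted as a property test), and exact duplicates are dropped with a
warning.  The published analysis delegated this step to an external merge
script; the algorithm here is an explicit reimplementation with the
parameters exposed, not a bug-for-bug copy.

LTR retrotransposons are assembled after merging: an internal-part copy
(`X_I`) fuses with its nearest preceding and following LTR-part copies
(`X_LTR`, same stem and strand, gaps ≤ `max_gap`) into one copy named by
the stem, resolved leftmost-first; unpaired LTRs stay solo.

The 80–80–80 filter keeps copies with `merged_len ≥ 80` bp, `K < 20` %
(the divergence value the rule's 80 % identity corresponds to here) and
consensus-span fraction ≥ 0.80, and removes Unclassified copies.  The
span criterion is computed from the union of fragment consensus intervals
over the consensus length implied by the hits themselves
(`cons_end + cons_left`); for assembled LTR elements the denominator is
`2·|LTR| + |internal|`.  `strict=False` drops the span criterion.  Copy
*coverage* always uses fragment unions, not envelopes, so a nested foreign
element is never counted inside its host; envelopes (with gaps) are kept
for reporting.  `merged_len` counts the fragment-union bp, with the
envelope available behind a field rather than a separate accounting mode.

## Landscapes

Items (fragments in raw mode, copies in final mode) accrue their length to
bin `floor(K)`; bins 0–50 are emitted per group including empty ones so
that binned bp conserve annotated bp exactly — an identity asserted on
every fixture.  Items beyond the last bin accrue to it rather than vanish
(conservation over tail resolution).  Family-level groups (e.g. ERVK
within LTR) are supported by feeding family labels.  The secondary axis
maps bin edges through the age model.

## Windows and feature tables

Chromosomes are tiled with non-overlapping windows (default 200 kb); the
trailing partial window is kept but flagged and excluded from rank
statistics by default, since its smaller support would otherwise enter the
correlations with equal weight.  Coverage is
`100 · |union ∩ window| / width` with intervals clipped at window edges —
invariant to interval order and splitting (property-tested).  GC uses
non-N bases only; the recombination rate is the overlap-bp-weighted mean
of map intervals, missing when no interval overlaps.  Age classes are
assigned per merged copy, not per fragment, and recent/ancient coverages
are computed from the disjoint copy sets, so with no cross-class fragment
overlap `te_cov_recent + te_cov_ancient = te_cov_all` per window.

## Statistics

Pairwise Kendall τ-b uses the standard tie-corrected form.  The partial
correlation inverts the pairwise τ-b matrix over {x, y, controls} and
reads `τ_xy·z = −M_xy/√(M_xx M_yy)` from the inverse — equivalent to the
textbook recursion for one control (asserted to 1e-12 on random tables) —
matching the behaviour of the partial-correlation packages used for this
kind of analysis.  Two-sided p-values come from the normal approximation
with the effective sample size reduced by the number of controls; the
correlation report runs each TE category (all/ancient/recent) against each
feature controlling for the other three features, with a Bonferroni family
of the three categories per feature.  Complete-case rows across all used
columns give one consistent n per correlation; windows without
recombination data drop out listwise.  Sex chromosomes stay in the feature
table but are excluded from correlations.

Kruskal–Wallis (tie-corrected, χ² with k−1 df) compares per-chromosome
relative coverages between macro and micro chromosomes; micro is strictly
"< 20 Mb", so an exactly-20-Mb chromosome is macro.  The
coverage-vs-length regression fits log₁₀(relative coverage) on length by
OLS, dropping zero-coverage chromosomes with a warning; a perfectly flat
response short-circuits to slope 0, p = 1 rather than the 0/0 the t-test
would produce.

## Synthetic data

The simulator inverts the divergence estimator.  Copies are evolved from
their consensus by per-site categorical sampling with
transition:transversion odds κ:1 (default 2) split evenly over the two
transversions, and the transition rate at CpG-context sites multiplied by
`cpg_multiplier` (default 10).  The base substitution probability is
calibrated by bisection so that the *expected* CpG-adjusted K2P of the
resulting alignment — computed in closed form from the site composition,
including the pair rule — equals the requested `K_true`; truth alignments
are gapless (indel stress for the parser is out of scope by default).
Measured calibration bias of the median estimate is ≲ 0.25 divergence
units at K ∈ {1, 5, 10, 20} and alignment lengths ≥ 1 kb; the per-copy
sampling scatter at those lengths is of order 0.5–1 unit, which is why
calibration is asserted on the median estimate, not on per-copy errors.

The default configuration sketches a scaled-down songbird genome: seven
chromosomes totalling 4 Mb (macro/micro mix under a 500-kb scaled
threshold plus a Z), 45 % GC, an ERVK-like LTR burst (K ~ Exp(1), full
LTR–internal–LTR structures with per-part hits and distinct run IDs),
solo LTRs, two CR1-like LINE families at broad K 5–28 with 5′ truncation
(probability 0.8, kept fraction uniform on [0.2, 1]), a SINE and a DNA
family.  TE density is a few-fold higher than the 5–10 % typical of real
bird genomes so that a small genome still yields statistically useful
copy counts.  Nested insertions (probability 0.1 by default) split a
single-fragment host at a uniform internal breakpoint; the two host
fragments share the host's run ID and carry the exact consensus
coordinates, mirrored on the minus strand.

Each chromosome carries a latent field (moving-average-smoothed Gaussian,
standardised, 50-kb resolution).  Monotone links from that field set TE
insertion intensity (softmax over windows, separately tunable for recent
and ancient copies), gene density, CpG-island density, recombination rate
(log-linear) and background GC.  The planted rank-association sign between
TE coverage and a feature is the sign of the product of the two
coefficients; `plant_correlations` reports the expected sign table.  With
several features coupled to the same field, partialling one feature out of
another attenuates the associations — by design, that is what the partial
statistic does — so sign-recovery checks couple one feature at a time.

For rank-statistic validation at realistic window counts the module also
samples feature tables directly at the window level
(`simulate_window_table`), skipping sequence realisation: the same
latent-field links, with TE bp multinomially placed over windows.
Sequence-level genomes at 500 windows × 200 kb × hundreds of replicates
would be pointless work for a test of the statistics; the window-level
sampler is the declared model of that layer, not a shortcut around it.

What the simulator does **not** emulate: insertions that displace sequence
(copies overwrite background, so coordinates never shift), indels in
alignments (off by default), solo-LTR formation by recombination,
selection against insertions, satellite/low-complexity repeats, and
assembly artefacts.  Passing tests therefore demonstrate correctness of
the bookkeeping, the estimator and the statistics under the stated model —
not robustness to alignment error or assembly collapse in real data.

## Validation problem sizes

The shipped checks use: estimator calibration at 200 replicates per
divergence level on a 1.2-kb consensus; defragmentation truth recovery on
100 seeded compact genomes (two chromosomes, 0.8 Mb, 62 planted copies
each, nesting probability 0.3); the matrix/recursion identity on 1 000
random 3-variable tables; type-I rate and sign recovery on 200/100
window-level replicates at n = 500 windows; and conservation identities on
every simulated fixture.  Observed results: recovery 100 %, type-I rate
≈ 0.065–0.075 at α = 0.05, sign recovery 100 %, conservation exact.

## Known limitations

* The merge is an approximation of the published toolchain's behaviour;
  parameters are exposed but no attempt is made to replicate its edge
  cases, solo-LTR/full-element statistics, or its output formats.
* The 80 % identity leg is applied as K < 20, the divergence the published
  analysis itself equates to the identity threshold; sequence-level
  identity is not recomputed.
* `.align` support is limited to the canonical dialect defined here.
* The normal approximation for the partial τ p-value is asymptotic;
  windowed genomic data are spatially autocorrelated and no correction for
  that is attempted (matching the analysis the package models).
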