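# Methods

This note documents the models behind `scsurvey`, the parameter
choices that matter, what the synthetic data does and does not
emulate, and the numerical conventions. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Alignment engine and search statistics

Pairwise similarity is scored by exact affine-gap local alignment
(Gotoh's three-state recursion), not by a heuristic seeded search: the
sequences involved are at most a few thousand residues, so full
dynamic programming is affordable (a numba-compiled kernel processes
roughly 10^8 cells/s on one core) and removes seeding artifacts from
every downstream statistic.

Conventions, chosen once and shared with the brute-force oracle used
in tests:

* a gap of length *k* costs `gap_open + k·gap_extend` (open **and**
  extend charged on the first gap residue), matching the convention of
  standard protein-search tools with the default 11/1 costs;
* the substitution matrix is BLOSUM62 (loaded from Biopython's matrix
  collection) over the 20 amino acids plus X; B, Z, U, J, O and `*`
  are rejected at parse time so scoring semantics stay unambiguous;
* among equal-scoring alignment end cells the smallest (query index,
  subject index) wins; traceback prefers diagonal over up
  (query-consuming gap) over left. This makes every result, including
  tie cases, deterministic;
* coordinates are 0-based half-open on the ungapped sequences; only
  the single best local alignment per pair is reported.

Raw scores are converted with the published gapped Karlin–Altschul
parameters for BLOSUM62/11/1, λ = 0.267 nats and K = 0.041:
`S′ = (λS − ln K)/ln 2`, `E = m·n·2^(−S′)`. Composition-based score
adjustment (a default of web BLAST) is deliberately not implemented;
printed scores of real protein pairs are therefore expected to deviate
by a few percent, and the acceptance checks on published pairwise
scores use a ±10% band.

Percent identity is counted over all alignment columns, gap columns
included in the denominator. This is the stricter of the common
definitions; it feeds directly into the mismatch fraction used for
trees (below).

## Shuffle null model

For each query, a *random analog* — a uniform Fisher–Yates permutation
of its residues, preserving length and composition exactly — is
searched against the same proteome. The ten best bit scores of native
and analog searches (E ≤ 100, the survey's reporting threshold) are
compared with a classic pooled-variance two-sample Student's t-test
(df = n₁+n₂−2; Welch's variant is available by flag). Zero pooled
variance is handled by contract: equal means give (t = 0, p = 1),
unequal means a signed infinite t with p = 0.

A cell is flagged **exclusive** when three conditions hold:

1. the analog's maximum reaches `exclusivity_ratio` (default 0.7) of
   the native maximum;
2. the t-test fails to separate the two top-10 lists at α = 0.05 (or
   either list has fewer than two qualifying scores);
3. the native maximum is itself at least 50 bits.

The third condition is this package's own addition: scores below the
reporting floor are noise for both native and analog queries, and
without the floor every empty cell would satisfy conditions 1–2. The
50-bit value is the same "very low similarity" threshold used for
table rendering; it brackets from below the 56–99-bit range in which
the exclusivity phenomenon is actually observed. All three knobs are
in `SurveyConfig`.

One analog per query is the default (matching the original manual
procedure); pooling n > 1 analogs is supported and recommended
(n ≈ 20) when flag stability matters more than fidelity.

**Calibration caveat.** The two-sample t-test on *truncated* top-k
lists is anti-conservative: selecting the 10 best of many scores
right-skews both samples, and the measured type-I error grows with the
ratio of proteome size to k (about 8% at 12 subjects, 13% at 20, for
k = 10). The type-I calibration reported by the acceptance script
therefore uses proteomes of exactly k = 10 subjects (lists complete,
no selection), where the test holds its nominal 5% level. Users
comparing top-10 lists drawn from large proteomes should treat small
p-values near α with caution — in this package the t-test only ever
*retains* the null (an exclusivity flag requires the test to fail), so
anti-conservatism makes the flag harder, not easier, to trip.

## Score tiers

Reported maxima are classified low (< 50), moderate (50–99), or high
(≥ 100 bits), mirroring the conventions of the published survey tables
(scores under 50 omitted as "very low", 100 and over set in bold).
Thresholds are configurable; the classification is monotone by
construction.

## Coiled-coil scanner

The scanner is the classic sliding-window heptad method: every
28-residue window is scored, in each of the 7 heptad frames, as the
geometric mean of per-residue propensities at the heptad position each
residue occupies; a residue's score is the maximum over covering
windows and frames, and its probability comes from a two-Gaussian
model, `P = G_cc/(G_cc + 30·G_glob)` (globular prior 30).

The propensity table shipped in `data/cc_propensities.tsv` is
**package-constructed** (labelled synthetic): hydrophobics enriched at
the a/d core, charged residues at e/g and the solvent-exposed
positions, helix breakers strongly disfavoured, X neutral. The
Gaussian score statistics are **calibrated, not copied**: the frozen
constants in `coiledcoil.py` were produced by
`scripts/calibrate_coils.py`, which fits the (mean, sd) of
max-over-frame window scores on (a) sequences drawn from the package's
heptad model and (b) sequences drawn from the background composition.
The calibration is reproducible (fixed seed, 4000 windows per class)
and must be re-run if the table, the window, or the heptad sampling
model changes.

Consequence to keep in mind: detector and generator share the same
propensity table, so segment-recovery results on synthetic fixtures
demonstrate internal consistency of the scanner, not performance on
real proteins. A further known artifact, shared with the classic
method: charged low-complexity sequences (e.g. poly-E) score above the
coiled-coil mean even without any heptad periodicity.

Segments are maximal runs with probability ≥ 0.5 and length ≥ 21
residues (three heptads), reported as 0-based half-open intervals.

## Distance trees

Family trees are built from *pairwise* optimal local alignments:
p = 1 − identity over aligned columns, coverage = aligned query span /
shorter sequence length. The reference web pipeline aligns families
with a constraint-based multiple aligner before computing distances;
replacing that stage with pairwise local alignments is a documented
divergence — real-data topologies are targets of qualitative, not
exact, reproduction.

The mismatch fraction is corrected for among-site rate variation with
the Grishin relation `1 − p = ln(1 + 2d)/(2d)`, solved by Brent's
method to |Δq| ≤ 1e−10 (d = 0 at p = 0; p = 1 maps to an infinity
marker). The corrected matrix goes through standard neighbor joining
(scikit-bio's implementation; 3-leaf case closed-form; negative branch
lengths clamped to zero), then a nearest-neighbor-interchange hill
climb under the *balanced* minimum-evolution criterion, evaluating
candidate topologies by Pauplin's length `Σ_{i<j} D_ij·2^(1−p_ij)`
(p_ij = topological path length) with best-improvement sweeps until no
NNI helps. The balanced length is asserted non-increasing at every
step. Branch lengths of the refined topology are re-fit by ordinary
least squares and clamped at zero.

Before distances are computed, unalignable sequences are removed
automatically: a record is excluded when its best bit score against
every other family member is below 50 or its best aligned coverage is
below 0.3. These two thresholds operationalize the reference
pipeline's silent outlier dropping (its actual rule is undocumented);
both are exposed as parameters. Fewer than three survivors is an
error.

## Synthetic data

The generator provides every fixture the pipeline needs offline, with
ground truth. Design choices:

* **Substitution model.** Replacement probabilities are the row-wise
  softmax of BLOSUM62 on its own ungapped log-odds scale
  (λ_u ≈ 0.321 solved from the background), so simulation and scoring
  are mutually consistent without importing an external rate matrix.
  Background frequencies are the matrix's marginal target frequencies
  (the classic BLOSUM62 composition: L ≈ 9.9%, W ≈ 1.3%). A site
  substitutes along a branch of length t with probability
  1 − exp(−rate·t), the replacement drawn from the exchange row
  (self-replacement allowed; ~29% on average). `expected_mismatch_fraction`
  gives the exact single-branch mismatch expectation used in tests.
* **Indels.** Geometric length (mean 3), probability 0.01 per site per
  branch, insertions drawn from the background. Low enough that
  aligned coverage stays high at default divergences.
* **Trees.** Random topologies by sequential joins; branch lengths
  uniform on (0.02, 0.12) — "moderate divergence": typical leaf-leaf
  paths of 0.2–0.5 substitutions/site, where distance estimation is
  informative but not saturated. Defaults: 8 taxa, 300-residue root.
* **Coiled-coil proteins.** Drawn position-wise from heptad
  distributions built as a 0.35/0.65 mixture of sharpened
  (exponent 2.5) propensity columns with their position average. The
  dominant shared component makes the sequences low-complexity
  (E/K/L/A/Q-rich), which is what lets shuffled analogs retain most of
  the alignment score — the mechanism behind the exclusivity
  phenomenon; the positional component carries the a/d hydrophobic
  period the scanner detects. Position-independent draws do *not*
  reproduce the phenomenon (shuffles then lose half the score), which
  is why the mixture, not a pure heptad model, is the default.
* **Exclusive chimera.** A background-composition head plus a
  coiled-coil tail occupying the final third of (by default) 4000
  residues, emulating the giant proteins whose SC-protein similarity
  is confined to C-terminal α-helical regions. Note that shuffling the
  *whole* chimera dilutes the tail composition below detectability;
  the exclusivity phenomenon concerns shuffles of the query (or of the
  similarity-bearing region), and that is what the tests assert.
* **Survey fixture.** Three queries (conserved 350-residue family;
  a query sharing only a 40-residue core, mutated at t = 0.1, with its
  orthologs — calibrated to land mid-band at ~70–90 bits; a
  250-residue coiled-coil query) against four taxa: two ordinary, one
  decoys-only, one additionally carrying the chimera. Expected tiers
  are fixed by construction with ≥ 3σ margins to the 50/100
  boundaries; the chimera cell lands in the 50–100 band, matching the
  published range of exclusive scores, and is the unique cell expected
  to trip the exclusivity flag.

What the generator does **not** emulate: real taxon-specific proteome
composition and size, domain architectures, HORMA-domain sequence
motifs, genuine remote homology at the twilight zone, and assembly
artifacts. Passing fixture tests therefore validates the machinery
(scoring, statistics, flags, trees) and the stated phenomena, not
database-scale survey performance.

## Problem sizes

Default problem sizes were chosen for interactive desk use: proteomes
of ~15 sequences per taxon, sequences ≤ 4000 residues, 1000 null
simulations, 50 tree-recovery replicates, 100 NJ replicates. The full
test suite and the acceptance script each complete in well under a
minute on one core.

## Known limitations

* No composition-based score adjustment; printed-score reproduction is
  a ±10% check, not exact.
* The E-value uses the raw m·n search space (no finite-size
  length correction).
* The coiled-coil propensity table is package-constructed; absolute
  probabilities are not comparable to those of the original published
  tool, only the qualitative behavior is.
* Trees come from pairwise distances, not a multiple alignment; with
  real, domain-shuffled proteins the p-distances of different pairs
  can be measured on non-homologous regions.
* The exclusivity flag's 0.7 ratio and 50-bit floor are heuristics
  exposed in config, not estimated quantities.
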