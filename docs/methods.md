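# Methods

`fvrin` turns a protein structure into a residue interaction network (RIN),
quantifies each residue's structural importance, relates those measures to
reported deficiency-causing missense mutations, and trains a classifier
ensemble that scores the mutation risk of every residue.  The package was
built around Coagulation Factor V (FV), whose loss-of-function variants
cause a rare bleeding disorder, but nothing in the code is FV-specific: any
single-conformation structure with a per-residue conservation column and a
position → phenotype label table can be analysed.

## Contact network

Residues are nodes.  An edge connects residues *i* and *j* when some atom
pair (a ∈ i, b ∈ j) satisfies

    dist(a, b) ≤ vdW(a) + vdW(b) + 2·r_probe,      r_probe = 0.25 Å.

This is the first-order approximation of two van der Waals surfaces both
touched by a probe of radius r_probe rolled over them.  Probe-rolling
surface algorithms (as used by RIN-construction tools built on molecular
surfaces) differ in detail; the distance criterion was chosen because it is
deterministic, dependency-free and verifiable against an all-pairs
brute-force oracle.  Exact reproduction of any particular surface-based
tool's edge set is not claimed, and published node/edge counts for the real
protein are treated as approximate external reference points only.

Choices that matter:

* **Hydrogens.**  Structures with or without protons are accepted; by
  default only heavy atoms enter the criterion, with slightly generous
  radii (C 1.70, N 1.55, O 1.52, S 1.80 Å, editable) compensating for the
  missing hydrogens.  This removes any dependency on protonation software.
* **Sequence neighbours.**  Residues adjacent in sequence are kept as edges
  (`min_seq_separation=1` excludes only self-contacts); callers can raise
  the separation to study long-range contacts only.
* **Edge annotation.**  Each edge is tagged SS/SM/MM according to whether
  the closest qualifying atom pair is side-chain or main-chain on either
  end; the annotation is metadata — every analysis uses the simple
  unweighted graph, simplified (no self-loops or parallel edges) on
  construction.

On an ideal poly-alanine α-helix the resulting contact graph has mean
Cα–Cα distance ≈ 5 Å between interacting residues, matching the scale
expected for atomic-contact networks of folded proteins.

## Centralities

Seven measures per node: degree, betweenness, closeness, k-core number,
Burt's constraint, HITS authority and PageRank.  Conventions are fixed and
documented because the downstream analysis (ranks, bins over observed
ranges, Pareto dominance) is invariant to them:

* betweenness is **unnormalized** shortest-path pair counts, so its log10
  on a ~1400-node protein graph spans roughly 0–5 — the scale on which the
  criticality bins are defined;
* closeness is the Wasserman–Faust component-scaled form
  `(n_c−1)/Σd · (n_c−1)/(n−1)`, in (0, 1] on connected graphs;
* authority: on an undirected graph HITS authority coincides with
  eigenvector centrality; computed by power iteration (tolerance 1e-12)
  and max-normalized;
* PageRank damping is 0.85 and the scores sum to 1.

networkx provides the graph algorithms; the test suite re-derives every
measure with independent brute-force oracles (BFS path counting, iterative
peeling, dense power iteration, the explicit constraint formula) on seeded
random graphs up to n = 50.

## Criticality bins and the supercritical set

The (degree, log10 betweenness) plane is divided into 4 uniform bins per
axis spanning the observed range; the lowest edge is nudged down by 0.1% of
the range so the minimum falls inside the first half-open bin `(lo, hi]`.
Nodes with zero betweenness have no position on the log axis; they are
excluded from binning and labelled UNCLASSIFIED — the same rule that later
discards them from the learning matrix.  Named classes: HDHB (top degree ∧
top log-betweenness bins), LDHB (bottom ∧ top), LDLB (bottom ∧ bottom);
the remaining bin combinations stay unnamed.  For a degree range of
[2, 13] the edges are 1.989, 4.75, 7.5, 10.25, 13.0 — bin width 2.75.

The *supercritical* residues are the Pareto front of (degree, betweenness,
closeness) under maximization with weak dominance: a residue is kept unless
some other residue is ≥ on all three and > on at least one; all
non-dominated ties are kept.  The front is invariant under strictly
monotone transforms of any axis, so the choice of betweenness scale cannot
affect it.

## Structural features and the 14-feature matrix

Per residue: Kyte–Doolittle hydrophobicity (fixed 20-entry table);
solvent-accessible surface area by Shrake–Rupley sampling (probe 1.4 Å,
960 points per atom on a deterministic Fibonacci-sphere lattice — doubling
the density changes per-residue areas by < 2%); solvent-excluded surface
area (SESA), an **imported** column by default since exact molecular-surface
computation is a computational-geometry project of its own (a probe-0
Shrake–Rupley approximation is available behind a flag and recorded as such
in the provenance map); relative SESA = residue area / reference area of
the same residue type in a Gly-X-Gly tripeptide (bundled editable table of
Tien-style theoretical values); and backbone dihedrals φ/ψ in the IUPAC
sign convention, with chain breaks (C–N distance > 2.5 Å) treated as
termini and missing atoms giving missing angles.

The learning matrix joins 6 structural + 7 centrality + 1 conservation
features (the conservation score is imported; low values mean high
conservation).  Rows with any missing value or zero betweenness are dropped
and itemized in a drop log; the retained matrix is complete, with a binary
label marking residues with a reported deficiency mutation.

## Subsample-bootstrap median test

To compare 63 deficiency residues against ~1254 others without the huge
group-size disparity driving the statistic, each feature is tested by
drawing |small| elements from the large group (without replacement — a
subsample; with-replacement resampling is available), 10,000 times, and
counting the iterations in which the subsample's median strictly exceeds
the small group's median.  p = count / 10,000, one-sided, granular in
units of 1e-4.  p near 0 means the small group sits high, p near 1 low.
The definitional statistic is the median (a mean variant is configurable);
a two-sided convenience value 2·min(p, 1−p) is exposed but never the
default.  Under the null both group medians are exchangeable, so the
p-value is approximately uniform; calibration is asserted on the
seed-averaged p, and power on ±2-SD planted shifts (p < 0.01 / > 0.99 at
n = 63 vs 1254).

## Classifier ensemble

Four preprocessing regimens (standardize always; ± PCA; ± ADASYN
oversampling) × five estimator families (decision tree, random forest,
gradient-boosted trees, SVM, k-NN), each grid-searched under 10-fold
stratified cross-validation and selected by mean validation ROC AUC
(ties → first grid point in deterministic order).  Leakage discipline is
strict and deliberate: scaler, PCA and ADASYN are fit on training folds
only; validation folds are transformed but never oversampled, so their
class ratio equals the full-data ratio ± 1 instance.  A pure-noise table
therefore scores at chance (mean AUC 0.40–0.60 across 20 permutation
seeds) — the standard symptom of fit-before-split bugs is an inflated null.

* **Grids.**  The full grids ("paper" preset) enumerate the documented
  ranges (e.g. k-NN neighbours 3–50; SVM γ 0.01–1.46 step 0.05, polynomial
  degree 2–5; forest sizes 50–1500 step 50; tree pruning strengths
  1…1e-4).  They are hours-scale; a reduced "fast" preset with the
  identical contract is the default for routine runs.
* **ADASYN** is implemented in-package (He et al.'s adaptive scheme:
  synthetic minority samples by interpolation toward minority neighbours,
  apportioned by the local majority fraction among k = 5 neighbours,
  largest-remainder rounding to exact class parity; random duplication
  fallback, with a warning, when the minority class has no neighbours).
* **PCA** keeps the smallest component count explaining ≥ 95% variance
  unless an integer override is given.
* **Gradient boosting** uses exact greedy splits (`tree_method="exact"`):
  at ~1300 rows the exact method is cheap and places wide-margin split
  thresholds mid-margin rather than at a histogram bin edge.
* **AUC** is computed from continuous scores (probabilities, or decision
  values for the SVM), never from hard labels.

The five selected models are refit on the full matrix (zero-variance
features dropped with a warning before standardization) and vote on every
residue at their decision boundaries (0.5 for probabilistic models).  The
vote score 0–5 counts models predicting the deficiency class: 0 reads as
"safe to substitute", 5 as most likely detrimental.

## Synthetic data: what it emulates and what it does not

* `generate_toy_structure` builds poly-alanine backbones from ideal bond
  lengths/angles and requested torsions (natural-extension-reference-frame
  placement, Cβ included).  It provides exact geometric ground truth; it
  does *not* emulate side-chain packing, so contact networks from it are
  backbone-dominated.
* `generate_feature_table` draws unit-SD Normal features with a shared
  latent factor injecting pairwise correlation ρ.  The latent factor plays
  the role of burial depth: each feature loads on it with the sign of its
  association (surface areas negatively, centralities positively), so the
  correlation structure carries the same sign pattern as the planted
  effects.  Deficient rows are shifted by per-feature effect sizes in
  pooled-SD units.
* The **study-calibrated preset** fixes the real dataset's conditions:
  1317 residues, 63 deficiency-labelled (4.78% / 95.22%), ρ = 0.5, and
  moderate effects in the observed directions (±0.2–0.4 SD per feature).
  Under these conditions the best estimator × regimen lands a mean CV AUC
  near 0.65–0.70 — a fair-but-imperfect signal of the same order as
  reported for the real protein.  Passing tests on this preset show the
  machinery extracts a planted multivariate signal at the right imbalance;
  they do not show that real mutation data carries that signal, and
  Gaussian features with a single latent factor understate the heavy tails
  and nonlinear couplings of real structural measures.
* Centrality columns in generated tables are drawn, not computed from a
  generated graph, to decouple the learning tests from the graph stack;
  the pipeline smoke tests cover the computed-end-to-end path.

## Numerical choices and degenerate inputs

* Bin assignment uses `searchsorted(side="left") − 1`: values exactly on an
  edge fall in the lower bin; fewer than two distinct values on an axis is
  an error (degenerate bins).
* Dihedrals: collinear backbone atoms give NaN, as do missing atoms.
* Alternate locations: highest occupancy wins, ties to file order; a
  "first" policy is available.
* Spearman correlations involving a constant column are reported as
  missing (NaN), never coerced to 0.
* Bootstrap subsampling without replacement is vectorized by taking the k
  smallest entries of a random row (a uniform k-subset), in blocks of 2000
  iterations to bound memory.
* All randomness flows from explicit integer seeds; the pipeline fans its
  config seed out per stage with fixed offsets, so stage outputs are
  byte-reproducible.

## Problem sizes

Routine runs use the sizes exercised throughout the tests: oracle graphs up
to n = 50, 500-point binning clouds, 10,000-point Pareto clouds, 10,000
bootstrap iterations at 63 vs 1254, and the 1317-row study-calibrated
table with the fast grids (the full grids enumerate tens of thousands of
grid points and are provided for completeness).

## Known limitations

* The contact criterion approximates probe-rolling surface contact; counts
  on real structures will differ from surface-based tools in the few-percent
  range, and no attempt is made to match a specific tool's output.
* SESA is imported, not computed; the probe-0 fallback is an approximation
  and is labelled as such in provenance.
* Conservation is an imported column; no alignment pipeline is included.
* The vote score depends on an assumed 0.5 decision threshold for
  probabilistic models.
* Multiple-testing correction is deliberately not applied to the per-feature
  bootstrap p-values; downstream users should account for the feature count.
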