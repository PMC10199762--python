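# Methods

This note documents the models, conventions and design choices behind
`epitopekit`, in the spirit of a statistical-software methods appendix.

## Problem setting

Binary classification of short peptides (6–25 residues) into linear
B-cell epitopes vs non-epitopes, under heavy class imbalance (about one
epitope per six non-epitopes in assay databases), with the source
organism known for most peptides.  The package covers dataset curation,
featurization, model fitting/evaluation, and post-hoc interpretation.

## Curation pipeline

Filters run in a fixed order: assay-evidence threshold → length window →
dual-class removal → organism requirement → redundancy removal →
stratified split.  Conventions:

- **Evidence** (default ≥ 2): inclusive threshold on the count of
  distinct confirming assays.
- **Length** 6–25, both bounds inclusive; this window covers the vast
  majority of reported linear epitopes.
- **Dual-class removal** deletes *all* records of any sequence reported
  in both classes; same-class duplicates survive to the redundancy step.
- **Redundancy removal** is a greedy, CD-HIT-like clustering implemented
  internally: sequences are processed in (length descending,
  lexicographic, input order); each joins the first cluster whose
  representative is at least the identity threshold similar, else founds
  a new cluster; the representative (first-seen longest) is retained.
  Identity = matches / alignment length under a global alignment with end
  gaps penalized (Biopython `PairwiseAligner`, match 1, mismatch 0, tiny
  gap penalty for determinism); for equal-length strings this is exactly
  Hamming matches / length.  Clustering runs **within each class**
  independently, so it can never silently delete a cross-class conflict.
  A coarser threshold never retains more representatives (verified
  against a brute-force all-pairs oracle in the tests).
- **Stratified split**: per-class test counts are
  `round(n_class · test_fraction)` (clamped so both sides are
  non-empty), preserving class proportions within one record per class;
  reproducible under the seed.  The 1:6 ratio is a property of the data,
  never enforced.

Open points in the original procedure (per-class vs pooled clustering;
whether the 2-assay rule counts positive assays only) were resolved as
above and are reported in the curation report's `engine` field.

## Graph-based signatures

Nodes are residues; an edge exists between positions `i` and `j` when
`|i−j| ≤ d` for a cutoff `d`.  The signature is the per-cutoff count of
edges per unordered node-label pair, *cumulative* (distance ≤ d, the
default) or *non-cumulative* (distance = d).  Label families:

- **Physicochemical classes** — Apolar {A,G,I,L,M,P,V}, Aromatic
  {F,W,Y}, PolarNeutral {C,N,Q,S,T}, Acidic {D,E}, Basic {H,K,R}.  This
  is the standard pharmacophore-style five-class table; it is
  configurable.
- **Scale-binary** — each of the four propensity scales (Parker
  hydrophilicity, Chou–Fasman beta-turn, Emini surface accessibility,
  Kolaskar–Tongaonkar antigenicity) binarized High/Low at the unweighted
  mean of its 20 per-residue values.  Midpoint-at-mean is parameter-free;
  any other threshold can be passed explicitly.

Cutoff grid defaults to 1..24 (the maximum separation in a 25-mer); at
peptide scale the full grid is cheap and feature selection can prune it.
Pair names are canonicalized by the scheme's label order, which is
alphabetical for the physicochemical scheme (`Acidic:Apolar-2`, never
`Apolar:Acidic-2`); non-default schemes carry a `~scheme` suffix and, in
`both` mode, non-cumulative copies carry `~nc`.

Useful exact invariants (all tested): the signature is invariant under
sequence reversal; cumulative counts are monotone across cutoffs; the sum
of cumulative counts at cutoff `d` equals `Σ_{k=1..d}(L−k)`.

## AAT antigenicity-ratio scale

With overlapping triplet counts `c_epi(t)`, `c_non(t)`, class totals
`N_epi`, `N_non`, and pseudocount `a` (default 1):

```
score(t) = ln[(c_epi(t)+a)/(c_non(t)+a)] + ln[(N_non+8000a)/(N_epi+8000a)]
```

The second term removes the class-size offset, making the score a
frequency log-odds: identical classes give all-zero scores, swapping the
classes negates every score, and scores shrink to 0 as `a → ∞`.  Unseen
triplets score 0 at prediction time (no evidence either way).  The scale
records a sha256 fingerprint of the sequences it was fitted on;
`AATScale.assert_fitted_on` raises on mismatch, enforcing that the scale
is fitted on training data only.

The per-peptide summaries are the max, min, sum and mean over the
peptide's overlapping triplet scores.  `AAT_max` (the maximum) is the
primary feature; `AAT_sum` exposes the alternative cumulative-sum
reading of "maximum antigenicity rate" that appears in parts of the
literature, and selection is free to drop either.

## CTD descriptors

Per property, 21 values: composition (fraction of residues per group,
sums to 1), transition (fraction of the `L−1` adjacent pairs crossing
each unordered group pair), and distribution (the 1-based position, as %
of length, of the first, 25%, 50%, 75% and 100% occurrence of each
group, using the `ceil(q·n)`-th occurrence).  Groups absent from a
peptide contribute 0 to all five of their distribution slots, keeping the
vector length fixed.  The shipped 3-group tables are the standard
Dubchak-style partitions; six properties are enabled by default
(hydrophobicity, normalized van der Waals volume, polarity, secondary
structure, solvent accessibility, charge — charge.G3 = {D,E}) with
polarizability available.  The original work's exact supplementary
tables are not public, so standard published partitions are used; tables
are data files and overridable.

## Taxonomy encoding

A fixed, ordered 20-class lineage vocabulary (8 Virus, 5 Eukaryota, 7
Bacteria classes).  One-hot slots are positional; `unknown` encodes as
all zeros rather than a 21st slot, so organism-less peptides carry no
taxonomy signal.  Mapping raw species names to the 20 classes is
table-driven and user-supplied; no ontology service is queried.

## Modeling and evaluation

- **Metrics.** MCC is computed from the confusion matrix with the
  convention MCC = 0 when any marginal factor is 0 (this makes a
  majority-class predictor score exactly 0 on imbalanced data).  AUC is
  the tie-aware rank statistic (equivalently concordant pairs + half the
  tied pairs) and is reported as undefined — not 0.5 — when only one
  class is present.  Both are verified against exhaustive oracles
  (all confusion matrices n ≤ 8; pair counting at n ≤ 30) and against
  scikit-learn.
- **Decision threshold** 0.5 on the predicted probability.
- **Cross-validation** is stratified; `cross_validate_records` refits the
  AAT scale inside each fold and featurizes both splits with the
  fold-local scale, so no training-fitted statistic touches its own test
  fold.  Default k = 10; smaller k is used where class counts demand it.
- **Greedy forward selection** adds, per round, the feature maximizing
  mean CV MCC; it stops when the best gain is ≤ 1e-4 for one round
  (patience 1).  Ties break toward the earlier column, so a duplicated
  informative column is selected once.  Nested use (selection inside each
  outer fold) is the safe default; the non-nested variant is a flag.
- **Algorithms**: random forest (default, fast and strong on tabular
  counts), extra trees, gradient boosting, AdaBoost, SVM (probabilities
  via Platt scaling), k-NN, MLP, and `additive_boosting` — an
  interpretable additive model when the optional `interpret` package is
  installed, else gradient boosting whose per-feature effects are read
  through partial-dependence response curves.  Hyperparameters are
  library defaults with a fixed seed, recorded in the bundle.
- **Interpretation**: Gini importances (non-negative, sum to 1),
  permutation importance (mean MCC drop over seeded shuffles; features
  outside the model's selected set score 0), optional SHAP, and
  clamp-and-average response curves.

## Synthetic benchmark generator

Emulates an assay-database export: uniform lengths 6–25, 1:6 class
ratio, organism classes uniform over the vocabulary (optionally biased
for epitopes), assay counts uniform on 1..5 so the evidence filter is
exercised, and a planted 3-mer motif written into epitopes at a
configurable rate (default 0.9).  The residue background is uniform by
default, which makes the planted-signal arithmetic exact: a specific
triplet occurs by chance at 20⁻³ per position, so the motif dominates
the fitted AAT scale.  A conflict injector appends k fresh sequences
once per class to exercise dual-class removal (removing exactly 2k
records).

What the generator does **not** emulate: realistic amino-acid
composition, homology structure within organism classes, assay noise
correlated with peptide properties, or multiple overlapping epitopes per
antigen.  Passing tests on this benchmark therefore demonstrate that the
pipeline recovers a known signal without leakage — not that any given
real-data accuracy will be achieved.

## Problem sizes and numerical choices

The standard benchmark used by the tests and the acceptance script is
n = 2,000 (286 epitopes, 1,714 non-epitopes) with 5-fold CV — large
enough for stable null behavior (chance AUC within ±0.05) while keeping
a full run in minutes on one CPU.  Exhaustive checks use a 3-letter
{A,F,D} alphabet up to length 6 (1,089 sequences).  Floating-point
round trips are exact to 1e-12 via repr-precision CSV formatting; all
stochastic components (generator, splits, folds, forests, shuffles) are
seeded, and pipeline runs with identical configuration and seed produce
byte-identical reports.

## Known limitations

- The greedy redundancy clustering matches CD-HIT's semantics, not its
  word-filter heuristics; at very large n it is O(n²) in identity
  computations.
- `AAT_max`'s empirical range and the importance ranking of features are
  dataset properties, not invariants; the package asserts only the
  structural guarantees listed above.
- Taxonomy aggregation from raw species names is out of scope; inputs
  must already carry one of the 20 lineage classes (or `unknown`).
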