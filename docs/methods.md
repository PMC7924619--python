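# Methods

## Problem setting

Pupylation attaches the prokaryotic ubiquitin-like protein (Pup) to a
substrate lysine through an isopeptide bond, marking proteins for
degradation in actinobacteria. Experimentally confirmed sites are
scarce, so the prediction task is cast as binary classification of
lysine-centered sequence windows: positives are confirmed sites,
negatives are all other lysines of the same proteins. This package
implements that pipeline end to end and validates it on synthetic data
whose ground truth is known by construction.

## Windows and datasets

A candidate site is represented by a window of W residues (W odd,
default 57, offsets −28…+28) centered on the lysine. Positions outside
the protein carry a reserved pad character `-`, chosen because the
source conventions leave terminus handling open; an explicit pad lets
every encoder define its contribution (zero) unambiguously. Rare
ambiguity codes (B, Z, X, U, O) are tolerated on input and treated as
pad-equivalent by all encoders, with a logged warning — dropping whole
proteins would silently shrink the data. A site annotated on a non-K
residue is a hard error, never skipped: that is a data-integrity
failure that should be loud. Annotations are 1-based (biological
convention); indexing is 0-based internally, converted at the parser.

Redundancy reduction is a greedy longest-first identity clustering: a
record is discarded when its global-alignment identity
(matches / alignment columns, Needleman–Wunsch path computed with
edlib) to any retained record reaches the threshold (default 0.8). It
approximates the behavior of word-filter clustering tools without their
heuristics and is deterministic (length descending, id ascending) and
idempotent. Class balancing subsamples negatives without replacement to
a declared ratio (1:1, 1:2 or all) under a fixed seed.

## Encoders

All five encoders share the pad rule (pads and ambiguity codes
contribute nothing) while denominators keep their nominal values
(W−k−1 pair positions, W−2 triple positions), so a heavily padded
terminal window scores lower rather than being silently rescaled.

* **Binary** — one-hot per position, dimension 20·W.
* **AAI** — per-position values of N physicochemical scales
  (default N = 15), dimension W·N. The shipped scales are classical
  published per-residue indices (Kyte–Doolittle hydropathy, Hopp–Woods
  hydrophilicity, Grantham polarity/volume/composition, Zimmerman
  bulkiness and pI, Klein net charge, Chou–Fasman helix/sheet/turn
  propensities, Eisenberg consensus hydrophobicity, Fauchère–Pliska
  hydrophobicity, Bhaskaran–Ponnuswamy flexibility, residue molecular
  weight), stored as TSV and overridable; the encoder mechanism, not
  the particular scale list, is the tested content.
* **TPC** — tripeptide composition, dimension 8000; counts of fully
  standard triples divided by the number of valid triple positions
  (zero vector when none), since "composition" conventionally means
  frequency.
* **CKSAAP** — for each spacing k = 0…k_max and ordered pair (a, b),
  the count of occurrences normalized by (W−k−1); dimension
  400·(k_max+1), 2000 at the defaults.
* **pbCKSAAP** — the same pair structure scored on a W×20 profile:
  S_ab = Σ_t max{min{P(t,a), P(t+k+1,b)}, 0}, then divided by (W−k−1).
  The log-odds block of PSI-BLAST ASCII PSSMs is used (first 20 numeric
  columns, header order A R N D C Q E G H I L K M F P S T W Y V): the
  clamp to zero only makes sense on signed scores, which the percentage
  block is not. The summation runs over the pair positions of the
  single window; each sample is one window, so no cross-occurrence
  aggregation applies. With a one-hot pseudo-profile at scale 1 the
  encoding reduces elementwise to CKSAAP — the test suite uses this as
  a free cross-encoder oracle, and a brute-force triple-loop
  implementation as an independent numerical oracle.

Feature names follow a fixed grammar (`CKSAAP|k=2|A-R`,
`Binary|pos=-28|C`, `TPC|ACD`, `AAI|pos=+3|index=KYTJ820101`) so
selection results stay traceable across runs.

## Feature selection

Each feature is discretized into at most 10 equal-width bins over its
observed range (constant features score 0) and scored by the Pearson
chi-squared statistic of the bin×class table, zero-count bins dropped.
Equal-width binning is simple, deterministic and invariant to positive
affine rescaling; the bin count is exposed. Ranking is score-descending
with ties broken by ascending feature index, making top-k prefixes
stable. The top-k sweep (default grid 20…500 step 20) evaluates mean
cross-validated AUC with the ranking recomputed inside each training
fold — selection on the whole matrix leaks label information and is
available only behind an explicit `selection_scope="whole"` flag for
replicating the common but optimistic practice.

## Classifiers and fusion

Random forest (default 500 trees — a common default; the tree count is
configurable and recorded in the config hash), RBF-SVM, and KNN
(default 5 neighbors) share a probability-score contract in [0, 1]:
tree-vote fraction, sigmoid-calibrated probability, and positive
neighbor fraction respectively. SVM features are standardized with
training-fold statistics because the RBF kernel is scale-sensitive;
(C, γ) are chosen from the 16×16 grid 2⁻⁷…2⁸ by 10-fold CV accuracy
(the default objective of the reference SVM implementation), ties going
to the smallest C then the smallest γ for determinism.

Fusion computes Cl = Σ w_i s_i with nonnegative weights summing to 1.
The weights are optimized by exhaustively enumerating the step-0.1
simplex grid (1001 candidates for five encodings — trivial cost) and
maximizing ROC AUC of the fused scores on pooled out-of-fold
predictions; ties break to the lexicographically smallest vector in the
canonical encoding order. Out-of-fold scores are used because
resubstitution scores reward overfit encodings; a resubstitution path
exists for comparison. Since each vertex of the simplex is a candidate,
the fused pooled AUC can never fall below the best single encoding on
the same scores.

## Evaluation

Predictions at a threshold use `score ≥ t` (ties positive) — fixed for
bit-reproducibility. Sensitivity, specificity, accuracy, MCC, precision
and recall are computed from the confusion counts; a zero-denominator
metric is reported as NaN (undefined), never coerced to 0, except MCC's
standard 0 convention when a factor under the root vanishes. ROC AUC
uses the trapezoid rule over all distinct score thresholds (it equals
the Mann–Whitney U statistic divided by n₊n₋, asserted in tests);
the precision-recall area uses the step rule to avoid optimistic linear
interpolation. Cross-validation is stratified and seeded; feature
selection and training happen strictly inside training folds;
out-of-fold scores are pooled for curves and the operating point, and
per-fold AUCs feed a Welch two-sample t-test (the unequal-variance form
is the safer default when only "two-sample t-test" is specified).
Whether reported operating-point metrics should be pooled or averaged
per fold is a genuinely open convention; pooled is implemented as the
default, per-fold values remain available from the report. The
specificity-controlled threshold is the smallest score threshold whose
specificity reaches the target (prediction defaults to the 90%
operating point).

## Enrichment analysis

For every (offset, residue) cell excluding the fixed central K, the
positive and negative frequencies (pads excluded from denominators) are
compared by a pooled two-proportion z-test; cells with p < α (default
0.05) are called enriched or depleted by the sign of the difference.
No multiple-testing correction is applied by default, matching the
convention of two-sample logo displays; a Bonferroni flag exists. On
null data the false-call rate is ≈ α by construction, which the tests
check at binomial tolerance.

## Synthetic data generator

The generator emulates the *structure* of real pupylation windows — a
small set of residues over- or under-represented at specific offsets in
positives — not pupylation biology itself. Negatives draw each position
i.i.d. from a background distribution (default uniform over the 20
standard residues, which keeps power calculations analytic; a
natural-frequency preset is included). Positives apply per-position
deltas: an enrichment of δ sets the target residue's frequency to
background+δ exactly and rescales the rest proportionally, so the
planted frequency is recoverable to binomial error. Optional pair
effects overwrite two offsets with a fixed residue pair with
probability δ, producing co-occurrence signal aimed at pair encoders.
The default study condition plants R, Y and L enrichment (δ = 0.3) at
six offsets flanking the site, P and K depletion at one offset each,
and two spaced pairs, on 500 positives and 500 negatives — strong,
multi-position signal of the kind two-sample logos show around real
sites. Fixture PSSMs are one-hot × scale (default 8) plus independent
integer noise in [−2, 2], exercising the min/clamp path with signed
values.

What passing on this generator does **not** show: real windows have
positional dependence beyond the planted pairs, homology between
proteins, and compositional biases; absolute performance numbers on
synthetic data say nothing about performance on curated pupylation
datasets. The generator validates correctness and qualitative behavior
(signal recovered, fusion dominates singles, nulls stay at chance), not
biological accuracy.

## Problem sizes and numerical choices

Test and acceptance runs use deliberately modest sizes chosen as the
smallest that make the statistical assertions stable: null-behavior
checks at 250/250 windows, signal-recovery at the 500/500 study
condition, unit oracles at windows of 5–13 residues. Weight-sum
invariants are asserted to 1e-12; frequency recoveries use 4σ binomial
tolerances; the null AUC band is ±0.05. Degenerate inputs fail loudly:
empty datasets, single-class labels, zero-variance matrices for SVM,
profile/window size mismatches, and simplex steps that do not divide 1.

## Known limitations

* The greedy identity clustering is O(n²) alignments and approximates,
  not reproduces, CD-HIT's word-filtered clusters.
* Binary PSI-BLAST checkpoint profiles and profile databases are not
  parsed; only the ASCII PSSM dialect is supported.
* The SVM probability comes from the standard sigmoid fit; no further
  calibration research is attempted.
* auPRC by the step rule is conservative relative to interpolated
  variants; comparisons across packages should use matching rules.
* DeLong variance and bootstrap confidence intervals for AUC are not
  implemented.
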