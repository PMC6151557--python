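# Methods

This note records the model, the defaults, the points where the published
description of each feature family is under-determined and what this
implementation chose, and what the synthetic data generator does and does
not emulate.

## Problem and pipeline

The task is binary classification of protein chains into DNA-binding and
non-binding, from the sequence plus two standard profile inputs: a
PSI-BLAST position-specific scoring matrix (L×20 integer log-odds) and a
PSI-PRED secondary-structure prediction (per-residue H/E/C state and a
C/H/E probability triple). The pipeline is

    encode (it | ksng | ssf, any subset) -> fuse -> MRMD reduce -> SVM / RF
    -> k-fold CV | jackknife | stratified train/test split

All 20-wide vectors use the alphabetical residue order
`ACDEFGHIKLMNPQRSTVWY`; parsers remap whatever column order a file
declares, so encodings are independent of tool-specific layouts.

## Encoders

**Information theory.** Composition entropy SEn, relative entropy RSEn
(KL divergence from uniform, so RSEn ≥ 0 with equality only for an exactly
uniform composition), and IGS = SEn − RSEn. `0·log 0` is taken as 0, the
standard convention. Frequencies are computed over the sanitized sequence.

**K-skip-n-grams.** The gram multiset unions all ordered pairs at skip
distances d = 0..k; the union is a *multiset* (an identical pattern
occurring at two distances counts twice), which makes the normalised
frequencies sum to exactly 1 — the alternative set-union reading would
break that normalisation. The skip distance d counts residues *between*
the two selected positions, so d = 0 is the contiguous bigram. The maximum
skip is not pinned down by the published description (its constraint
expression is garbled); the default k = 3 keeps the multiset dominated by
local pairs, and the per-sequence cap min(k, L−n) guarantees every
sequence of length ≥ n admits at least the contiguous grams. n is fixed to
2 in practice (400 features); n = 1 and 3 are supported, larger grams are
refused.

**SSF.** Five concatenated blocks, 473 features at the defaults:

| block | width | definition |
|---|---|---|
| PSSM averages | 20 | column means of the log-odds matrix |
| consensus n-grams | 420 | 20/420 × 1-gram + 400/420 × 2-gram frequencies of the consensus sequence |
| SS sequence | 6 | f_H, f_E, f_C, maxrun_H/L, maxrun_E/L, E-H-E motif frequency |
| SS global | 3 | column means of the probability matrix |
| SS local | 24 | per-segment column means, λ = 8 segments |

Choices where the published description is not recoverable exactly:

* *Background frequencies* p_j weighting the consensus argmax
  (2^S[i,j]·p_j): the published method cites database-derived frequencies
  but tabulates none; the default is uniform 1/20, which is reproducible
  and declared, with a config slot for user-supplied values. Argmax ties
  break to the alphabetically first residue.
* *The six state-string features* are described only loosely ("lengths of
  the continuous subunits", "frequency of the strand–helix–strand
  fragment"). Here they are: the three state fractions; the longest H run
  and longest E run, each normalised by L; and the count of consecutive
  (E, H, E) run triplets in the coil-free run sequence divided by the
  number of triplet windows (floored at 1 so short sequences are defined).
  These are unit-tested definitions, flagged as this package's
  interpretation.
* *Segmentation remainder*: when L is not divisible by λ the earliest
  segments take the extra row (`np.array_split` convention) —
  deterministic and standard.
* *Structural order n*: only n = 1 (the setting reported to work best and
  the one that yields 20+420+6+3+24 = 473) is implemented; the config
  rejects n > 1 explicitly rather than guessing the product semantics.
* *PSSM scale*: whether raw log-odds or sigmoid-squashed scores feed the
  averages is unstated; both are exposed (`pssm_scale`), default raw,
  since the formula averages "scores".

## Fusion and MRMD

Blocks concatenate column-wise over identical sample lists; names stay
block-prefixed. MRMD scores each feature by

    combined_i = w_rel · |pearson(x_i, y)| + w_dist · dist_i

with both weights defaulting to 1 (the published account says only "a
certain weight ratio"). Columns are standardised first, so the ranking is
invariant to affine rescaling; zero-variance columns get relevance 0.
`dist_i` is the mean Euclidean distance from standardised column i to all
other columns, divided by the largest such mean so it lies in (0, 1] —
max-scaling rather than min–max, because min–max would force some feature
to 0 and amplify tiny spreads between otherwise similar columns.
Ties in the combined score keep the original column order. `m='auto'`
sweeps {1, 2, 5, 10, 20, 50, 100, 200, all} (clipped to the width) and
keeps the smallest m maximising seeded 5-fold CV accuracy.

`pipeline.cv_with_selection` re-fits the MRMD ranking inside each CV
training fold and applies the selected columns to the held-out fold.
Ranking on the full dataset and then cross-validating the selected columns
on the same samples leaks the selection step — with hundreds of candidate
columns and ~100 samples it inflates accuracy on *uninformative* labels to
well above chance — so the fold-internal variant is the pipeline's honest
cross-validation estimate and the one the acceptance script reports.

## Classifiers and evaluation

* SVM: Gaussian kernel, C = 1 and σ = sqrt(d/2) for d features by default
  (equivalently kernel coefficient γ = 1/d on standardised inputs, the
  usual automatic-width heuristic); features are standardised with
  training-fold statistics before the kernel, because heterogeneous
  feature scales otherwise dominate the distance. Both hyperparameters
  are configurable; no published values exist to match.
* Random forest: 500 trees, seeded.
* Metrics: SN, SP, ACC from the confusion counts; MCC with the convention
  MCC := 0 when any denominator factor vanishes. SN/SP are reported as 0
  when their own denominator is empty (only possible in degenerate folds).
* k-fold CV is stratified and seed-shuffled; the reported value is the
  mean of per-fold accuracies. k equal to the sample count degenerates to
  leave-one-out (stratification is vacuous at fold size 1), which makes it
  agree with the jackknife's pooled counts. Jackknife pools all
  leave-one-out predictions into one confusion matrix before computing
  metrics.
* The stratified split puts floor(fraction·n) samples in training,
  allocated to classes by largest fractional remainder, so a balanced
  186-sample set at 80 % gives 74+74 training and 19+19 test.

## Synthetic data generator

`fixtures.generate_fixture_dataset` fabricates coherent triples of FASTA
sequence, PSSM and `.ss2` files plus labels:

* positives draw residues from (1−s)·uniform + s·uniform{K,R,G,S} where
  s = `signal_strength` (default 0.5); negatives draw uniformly. The
  {K,R,G,S} subset is an arbitrary synthetic signal carrier, not a
  biological claim;
* PSSM rows give the emitted residue a score in [4, 8] and others noise in
  [−6, 2], clipped to [−9, 13] (the range real PSI-BLAST files occupy);
* `.ss2` rows are Dirichlet draws over (C, H, E) with the helix
  concentration raised by `ss_bias` (default 0.3) in positives, rounded to
  3 decimals as the real tool prints, states set to the row argmax.

Default sizes are 50 positives + 50 negatives of length 50–80. Everything
is deterministic given the seed, and every written file parses back
through the package's own readers.

What it does **not** emulate: real evolutionary covariance along the
sequence (PSSM columns are conditionally independent given the residue),
realistic secondary-structure run lengths (states are i.i.d. across
positions), homology between chains, or class overlap structure of real
benchmarks. Passing the recovery tests therefore demonstrates that the
pipeline transmits a composition/structure signal of known size without
leaking labels — not that any particular accuracy would be reached on
real DNA-binding datasets, whose published headline numbers additionally
depend on external database searches and unstated hyperparameters.

## Numerical and degenerate-input conventions

* Non-standard residues (B, J, O, U, X, Z): dropped by default; optional
  `map` policy sends B→D, Z→E, U→C and drops the rest.
* Empty sequences, empty profiles, single-class label vectors, and
  length-mismatched profile pairs raise `ValueError` with the offending
  identifier where available.
* Feature tables round-trip through CSV at better than 1e−9; LIBSVM export
  uses 1-based indices and ±1 labels.
* Problem sizes in the tests and the acceptance script (100-sample
  datasets, 10-fold CV, top-100 selection) were chosen as the smallest
  sizes at which the stochastic checks are stable across seeds.

## Known limitations

* MRMD offers only the Euclidean distance variant; mutual-information
  (mRMR-style) selection and wrapper elimination are out of scope.
* No probability calibration and no multi-class support.
* The package parses PSI-BLAST/PSI-PRED output but never runs the tools;
  users supply profiles, or use the synthetic generator.
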