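# Methods

## Sequence handling

Inputs are FASTA protein sequences over the 20 standard one-letter codes.
Validation is strict: ambiguous residues (B, J, O, U, X, Z), stop characters
(`*`), internal whitespace and any other non-standard character invalidate a
sequence, and the validation report lists each offending character with its
1-based position. Lowercase residues are uppercased before validation (FASTA
dialects vary) and the normalization is logged. Invalid sequences are either
dropped with a logged count or abort the load, per caller choice; a class
left empty after filtering is always an error. Duplicate FASTA ids are
permitted but logged — all downstream rows are keyed by position, never by
id. Redundancy reduction (e.g. clustering at a sequence-identity cutoff) is
deliberately out of scope; it belongs to upstream dataset curation.

A sequence is encodable at gap *k* only if *L* ≥ *k*+2 (it must contain at
least one *k*-spaced pair). Shorter sequences fail at encode time — not at
load time — with an error naming the sequence and the gap, since the same
loaded dataset may be encoded at several gaps.

## Descriptors

**AAC.** *f<sub>i</sub>* = *N*(*i*)/*L* over the alphabetized one-letter
codes (A, C, D, …, Y); components sum to 1.

**CKSAAP.** For gap *k*, *N*(*i,j*) counts ordered pairs at positions
(*p*, *p*+*k*+1), *p* = 1…*L*−*k*−1, so ΣN = *L*−*k*−1 always. Columns are
row-major over the alphabet (AA, AC, …, AY, CA, …, YY); blocks for several
gaps are concatenated by ascending *k* after the AAC block. Two denominators
are supported:

- `paper` (default): *f<sub>i,j</sub>* = *N*(*i,j*)/(*L*−*k*), the formula
  as conventionally printed. Components sum to (*L*−*k*−1)/(*L*−*k*).
- `pair-count`: divide by *L*−*k*−1, the actual number of *k*-spaced pairs,
  so components sum to 1.

The default follows the printed convention for fidelity with published
feature tables; the self-normalizing alternative is one flag away. For
typical protein lengths the two differ by less than 1% per component, and
the ANOVA ranking is unaffected by any common per-row rescaling only when
lengths are equal — hence both conventions are carried through the entire
pipeline rather than converted.

Frequencies are computed in double precision; TSV output rounds to a
configurable number of decimals (default 6), and a JSON sidecar records the
encoding spec (gap list, convention, column order) for exact reload.

## Feature selection

For two classes with sizes *n*₁, *n*₂ (*n* = *n*₁+*n*₂):

    MSB = [n₁(x̄₁−x̄)² + n₂(x̄₂−x̄)²] / (g−1),  g = 2
    MSW = Σ within-group squared deviations / (n−g)
    F   = MSB / MSW

For two groups F = t² of the pooled-variance two-sample t statistic; the
test suite verifies this identity, and agreement with an independent
library implementation, on random matrices. Degenerate cases are explicit:
MSW = 0 with MSB > 0 (a perfectly separating feature) gets +∞ and ranks
first — maximally informative under the criterion; MSB = MSW = 0 (a constant
feature) gets 0 and ranks last. Because a numerically constant column yields
MSB and MSW that are both rounding noise rather than true variance, zeros
are detected with a tolerance relative to the squared column scale
((10⁻⁹·scale)²). Ties in F are broken by canonical feature name, ascending,
making the ranking fully deterministic.

Incremental forward selection scores, for each *m* = 1…*m*<sub>max</sub>,
the feature set {full AAC block} ∪ {top-*m* ranked *k*-spaced pairs} by
pooled cross-validated accuracy, and returns the whole curve plus the best
*m* (ties resolved toward the smallest *m*). The AAC block is always fully
included while *m* varies — the selection operates on the pairs only. By
default the ranking is computed once on the full training matrix, matching
the usual published protocol; this leaks selection information into the CV
estimate, so a fold-safe mode that re-ranks within each training fold is
provided. Fold-safe mode requires a fixed SVM configuration (combining
per-fold re-ranking with per-subset grid retuning would multiply the model
count without changing what the mode demonstrates).

## Classifier

An RBF-kernel SVM (via scikit-learn's libsvm binding). Features are used as
raw frequencies without rescaling by default — they already live in [0, 1] —
with an optional standardization step. Class-imbalance weighting is off by
default. Grid search evaluates every (a, b) in the supplied log₂ grids with
c = 2^a, γ = 2^b, using one fixed seeded fold assignment across all points
so the accuracy surface is comparable; the argmax of pooled accuracy wins,
ties going to smaller a then smaller b. The default fine grid steps both
exponents by 0.2 (a ∈ [−5, 15], b ∈ [−15, 8]); a step-2 coarse grid is the
pragmatic default in the pipeline, with coarse-to-fine refinement available
by passing narrowed grids.

Cross-validation uses seeded, shuffled, by-default-stratified folds; every
sample is validated exactly once, per-fold confusion matrices are pooled by
summation, and out-of-fold decision scores are retained for the ROC.
"Jackknife" is the *n*-fold (leave-one-out) limiting case of the same
machinery. Stratification requires the fold count not to exceed the smaller
class size.

Models are serialized as a joblib bundle embedding the fitted SVM, its
(c, γ), and the full encoding spec, so prediction on a new FASTA is
self-contained. Unencodable records during prediction (e.g. too short for
the model's gap) produce per-record error rows rather than aborting the run.

## Evaluation

ACC = (TP+TN)/total·100%. The class-conditional rates follow the study
convention: SP = TP/(TP+FN) (rate on positives) and SE = TN/(TN+FP) (rate on
negatives) — the reverse of the standard sensitivity/specificity naming.
Both namings are emitted (`sp_paper`/`se_paper` and
`sensitivity_std`/`specificity_std`) so published tables can be reproduced
without silently misreading them. A zero-denominator ratio is reported as
NaN with a warning, never coerced. The ROC is a descending-threshold sweep
over the unique decision scores; tied scores advance the curve diagonally in
one step; AUC is the trapezoidal area, which the tests verify equals the
Mann–Whitney pair-ordering statistic.

## Synthetic data generator

Sequences are drawn i.i.d. from a 20-component background (uniform 0.05 by
default), then each enriched pair (i, j, k, rate) overwrites positions
(p, p+k+1) at each eligible start p independently with probability `rate`,
in the positive class only. Overwriting rather than inserting keeps lengths
fixed and the background marginal nearly intact, isolating the pair signal
the selection stage must find. Note one real side effect: planting A···A and
L···L also raises the frequencies of cross-pairs such as A···L, and of the A
and L compositions themselves — so recovery tests assert the planted pairs
rank among the top few hundredths of the 400 candidates, not that they are
the only signal.

Defaults encode the study conditions used throughout the tests and the
acceptance script: 100 positives + 100 negatives, lengths uniform on
[100, 400] (approximating real protein lengths), uniform background, pairs
(A, A, k=3) and (L, L, k=3) at rate 0.15. One shared generator stream per
dataset, fully determined by the config's single seed, which is recorded in
the emitted manifest.

What the generator does **not** emulate: homology/phylogenetic correlation
between sequences, realistic residue composition or domain structure, and
any length–class dependence. Passing tests therefore demonstrate that the
pipeline recovers and exploits k-spaced pair enrichment under i.i.d.
backgrounds; they do not certify accuracy levels on real enzyme datasets,
where signal is far weaker and redundancy structure matters.

## Problem sizes and numerical choices

The test suite and acceptance script run at n = 200 sequences (and one
imbalanced 80+160 end-to-end run), with selection up to m = 10 and a step-2
or step-4 coarse grid — sizes chosen so the full pipeline remains a
desk-scale computation while leaving the planted signal comfortably
recoverable. Real datasets of a few thousand sequences run the identical
code path in minutes. Metrics JSON output is written with sorted keys and no
timestamps, so a rerun of the same run configuration is byte-identical.

## Known limitations

- The published accuracies for real human-enzyme data (≈76% with 40
  features) depend on the original curated datasets and fold randomization;
  this package reproduces the method, not those exact numbers.
- ANOVA F scores features marginally; jointly informative but marginally
  weak pairs will rank low (the usual argument for mRMR-style criteria,
  which are out of scope here).
- The default selection protocol shares information between ranking and CV
  scoring, as published; use `fold_safe=True` for an unbiased curve.
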