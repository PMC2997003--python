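# Methods

## Model and assumptions

The predictor treats aaRS identification as two nested binary problems:
aaRS vs non-aaRS, then class-1 vs class-2 on the positives. Both stages
share one model family — a soft-margin SVM over fixed-length feature
vectors — and differ only in their feature lists and training sets.
Class-1 is the stage-2 positive label; stage-2 fields of a cascade
prediction are populated only when stage 1 calls the protein an aaRS.

Underlying assumptions: (i) family membership leaves a footprint in
low-order composition statistics (residue and dipeptide frequencies);
(ii) PROSITE domain presence is informative but incomplete — a large
minority of true aaRSs carry none of the distinguishable domains, which
is why domain bits are combined with composition rather than used as a
rule; (iii) the two information sources are best fused early, by
concatenating them into one input vector, rather than by cascading two
separate predictors.

## Features

Composition is expressed in percent. The amino-acid block (20 dims) sums
to 100 exactly; the dipeptide block (400 dims, overlapping windows,
denominator L−1) likewise. Percentages are fed to the SVM without
further scaling: the two block types then live on comparable scales
(single dipeptide percentages are small, domain bits are 0/1), and the
RBF width is chosen with that geometry in mind. Feature order is fixed
(alphabetical; dipeptides in 20×20 grid order, first letter major) and
serialized with every trained model; scoring refuses a vector whose
spec differs, naming the offending features.

Non-standard residues (B, Z, X, U, O, J) are dropped with a warning by
default (`strict` mode refuses them), and composition denominators use
the cleaned length. This keeps the feature spaces exactly 20- and
400-dimensional.

The selected-dipeptide lists (18 for stage 1, 14 for stage 2) are
shipped as constants and used by the default pipelines; `rank_features`
re-derives such subsets on new data but the shipped lists are not
recomputed at import time, since their exact membership is a property of
the data they were derived from.

## Domain features

Only pattern-type signatures are matched internally (PROSITE pattern
syntax → regex; 1-based, overlapping, anchors honored). Generalized
profile scoring is out of scope: profile-type accessions (PS50862,
PS50860, PS50861, PS50889) enter through a two-column hit TSV such as a
reformatted InterProScan/ProfileScan output. Presence is taken as
reported — no score cutoff is applied on top of the scanner's own
calling. Hit multiplicity is deliberately discarded: the feature is
presence/absence.

## Learning and evaluation

Default SVM: RBF kernel, C = 10, γ = 0.05. These were fixed once as
round values appropriate for percent-scale features on the synthetic
benchmark; `grid_search` (C ∈ {0.1, 1, 10, 100}, γ ∈ 2⁻⁷…2³, selection
by mean 5-fold CV accuracy with MCC tie-break) is provided for new
datasets where no defaults can be assumed. SVM-RFE ranking uses a
linear kernel with C = 1 and eliminates one feature per round once ≤ 50
survive, otherwise 10% of survivors per round; ties break
lexicographically by feature name, making rankings bit-reproducible.

Cross-validation is stratified (per-fold class counts within one of
perfect balance) and seeded. Reported aggregates are the unweighted
mean over folds; pooled-count metrics are attached separately because
the two conventions differ and both are useful — fold means for
comparability, pooled counts for count-level arithmetic. Metrics with a
zero denominator are `None` (undefined), not zero, except MCC where the
zero-denominator convention is 0. Rounding to two decimals happens only
at presentation. ROC curves are computed internally (ties grouped,
trapezoidal area); the area equals the normalized Mann-Whitney
statistic, which the tests exploit as an independent oracle.

Threshold sweeps cover −1.0…+1.0 in steps of 0.1 (21 rows), with
sensitivity non-increasing and specificity non-decreasing in the
threshold by construction.

## Similarity baseline

The baseline classifies a query by the label of its best local-alignment
hit against the training folds (Smith-Waterman, affine gaps: a gap of
length k costs open + k·extend; BLOSUM62 default, open 10 / extend 1).
A score threshold stands in for an E-value cutoff; the two are not
equivalent, and no alignment statistics are computed. The historical
no-hit accounting — no-hit positives are false negatives and no-hit
*negatives* are false **positives** — is implemented as the default
because it is what the original protocol states; a corrected mode
(no-hit negative → true negative) is available behind a flag. The
aligner is Biopython's `PairwiseAligner` in local mode, verified in the
tests against an exhaustive alignment enumerator on small strings.

## Synthetic data

The generator emulates the three signals the classifier consumes, not
real aaRS biology:

* **Dipeptide bias** — extra copies of target dipeptides inserted at
  random interior positions, with the insertion count solved so the
  expected composition excess (in percent points of windows) matches the
  request after accounting for the length the insertions themselves add.
  This gives direct, verifiable control of exactly the features the
  model uses; it does not reproduce the covariance structure of real
  proteomes.
* **Motifs** — exact HIGH and KMSKS peptides inserted with per-class
  probability; planted positions are recorded in a truth record and
  shifted correctly under subsequent insertions.
* **Domain hits** — emitted per an emission probability; a coupled
  domain (PS00178 ↔ HIGH) is only ever reported when its motif actually
  occurs in the final sequence, so hit tables and sequences never
  contradict each other.

Background residues are i.i.d. uniform over the 20 letters. Real
proteins are not i.i.d. and real domains are detected by profile
scoring, so passing tests demonstrate that the pipeline recovers the
signal it was told to plant — not that these accuracy levels transfer
to Swiss-Prot-scale data.

Preset conditions, chosen once: `stage1` uses 200 sequences per class,
lengths 300–600, six of the 18 stage-1 dipeptides enriched by +1
percent point in positives, HIGH/KMSKS at probability 0.9, and domain
emission rates giving roughly 60–70% of positives at least one of the
four stage-1 domains versus ~10% of negatives — the coverage contrast
reported for real aaRS data. `stage2` uses 150 per class; both classes
carry the shared aaRS dipeptide enrichment (both are synthetases) plus
three class-specific dipeptides each, and each class emits only its
preferred domain accessions. `null` plants nothing and is used for
chance-level controls. 150/class for stage 2 was picked as the smallest
size giving stable 5-fold estimates; the real non-redundant class-1 and
class-2 sets are smaller still, so the synthetic stage-2 problem is the
easier one.

## Numerical and degenerate-input choices

* Dipeptide composition requires length ≥ 2; empty sequences and empty
  datasets are rejected with typed errors (`InputError` family → CLI
  exit code 2, `ComputationError` → 3).
* Requested dipeptide excess is validated against sequence capacity
  (total excess ≥ 40% of windows is refused, as is any single sequence
  where insertions would exceed its length).
* Top-hit ties break by database order, then id — deterministic for a
  fixed database file.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; model persistence stores the feature
  spec, kernel, hyperparameters and a training-data hash so a loaded
  model scores bit-identically.

## Known limitations

* No generalized-profile scoring: the package cannot discover
  profile-type domains in raw sequence; it trusts hit tables.
* The shipped 18/14 dipeptide lists cannot be re-derived without the
  original training data; on new data SVM-RFE will produce different,
  equally valid subsets.
* The similarity baseline's score threshold is not an E-value; absolute
  baseline numbers are not comparable to published BLAST accuracies.
* Probability calibration, multi-class extensions beyond the fixed
  cascade, and confidence intervals on metrics are out of scope.

## Problem sizes

The test suite and the acceptance script run the full pipelines at the
preset sizes above (400/300/200-sequence datasets, 5-fold CV), the
exhaustive composition and alignment oracles on small alphabets
(lengths ≤ 6–8 over 3–4 letters, plus seeded random pairs), and SVM-RFE
recovery over 10 generator seeds at 200 sequences each. These sizes
were chosen to make every check rerun from scratch in seconds while
keeping each estimate stable across seeds.
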