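# Methods

## Interface definition and structure handling

A residue is an *interface residue* when at least one of its heavy
(non-hydrogen) atoms lies within 5 Å (inclusive) of any atom of the bound
RNA. The cutoff is a parameter of `label_interface`; the inclusive boundary
is a deliberate reading of "within" and is tested explicitly at 5.0 Å.
Distances use a k-d tree over the RNA atoms; correctness is checked against
a brute-force all-pairs scan in the tests and the reproducibility script.

Residues present in a chain's sequence but absent from the coordinate
section cannot be labeled geometrically. Both conventions in use are
supported as an explicit enum: `exclude-unresolved` (leave them out of all
counts) and `unresolved-as-negative` (count them as non-interface). The
latter is the default because it is the convention of the training-style
datasets this pipeline emulates; IC-score computation always *excludes*
columns where either sequence is unresolved, since a fabricated negative
would bias the conservation estimate.

PDB input goes through Biopython with the highest-occupancy altloc and
hydrogens ignored; positions are sequential 1-based indices with author
numbering kept as metadata. Gaps in author numbering are (optionally) filled
with unresolved `X` residues. Curation filters mirror standard dataset
construction: reject chains shorter than 40 residues or with fewer than 5
interface residues; reject resolution > 3.5 Å, non-X-ray entries and
CA-only chains when the metadata/geometry allows the check (missing
metadata skips the rule with a logged warning rather than guessing).

## Alignment statistics and the IC score

Six statistics summarise a local alignment: positive score PS = positives/L,
identity score IS = identities/L, −log₁₀ E, log₁₀ L, and the two length
fractions L/L_Q and L/L_H. Log base 10 is the package default and is
recorded in model metadata; E = 0 (BLAST underflow) maps to a configurable
cap (`e_cap`, default 200). Fractions are capped at 1 with a warning when an
alignment is nominally longer than a chain.

The IC score of a query/homolog pair is the φ (Pearson) correlation of the
aligned binary interface labels, computed from the integer 2×2 contingency
table so the boundary values ±1 are exact. It is identical to the Matthews
correlation of the homolog labels read as predictions of the query labels.
Constant label vectors carry no conservation signal; they return 0 with an
explicit `degenerate` flag instead of raising, because such pairs are common
(e.g. a fully non-interface fragment) and should simply not contribute.
This correlation definition is the single most consequential interpretation
in the package and is isolated in one function (`ic_score`) so an
alternative could be swapped in.

## The linear IC model and homology zones

Predicted IC is an affine function of four predictors: −log E, log L, PS,
and a single length fraction taken as L/min(L_Q, L_H) (the alignment's
coverage of the shorter chain; both per-side fractions remain available in
`AlignmentStatistics`). The shipped coefficients are
(−0.532, 0.001, 0.005, 0.600, 0.089). Identity score is excluded from the
model (it is nearly collinear with PS) but retained in the statistics.
Predicted values are *not* clamped to [−1, 1]: clamping would silently move
hits across zone boundaries.

`ICRegression` refits the model by OLS (statsmodels under the hood) and
reports coefficient standard errors, adjusted R², and Type II sums of
squares (computed as t²·MSE, which for a main-effects linear model equals
the SSE increase from dropping the predictor). A rank-deficient design is an
error that names the collinear predictors.

Zones are closed below: Safe ŵ ≥ 0.70, Twilight ≥ 0.20, Dark ≥ 0.15,
below Dark the hit is discarded. Thresholds serialize to a plain-text
config shipped with defaults.

A reachability note that matters for anyone refitting or simulating: with
the shipped coefficients the PS term contributes at most 0.6 while the
intercept is −0.532, so predicted IC can exceed the Safe cutoff only when
the −log E term contributes several tenths — i.e. for extreme E-values.
Under a strict base-10 cap of 200 the Safe zone is unreachable for any
alignment whose PS survives the 0.95 similarity exclusion. The E-cap is
therefore a per-database convention: the synthetic database writes
`e_cap = 744.4` (−ln of the smallest positive double, the natural-log
reading of an underflowed E-value) into its config, which makes all three
zones reachable with a contiguous range of attainable predicted-IC values.
The package-wide default for externally supplied alignments stays 200.

## Homology transfer

Hits are deduplicated to one HSP per query/homolog pair (highest predicted
IC, then lower E-value, then first occurrence), near-identical hits
(PS > 0.95 by default; identity-based exclusion available) are removed, and
the best non-empty zone is taken hierarchically: all Safe hits if any,
otherwise all Twilight, otherwise all Dark, otherwise no prediction.

The vote at query position i is the weight-normalized mean of the interface
indicators of the homolog residues aligned to i, with weights w_k = ŵ_k.
The denominator sums only the homologs aligned at i, so positions some
homologs fail to cover are not diluted toward zero. Columns aligned to an
unresolved homolog residue are skipped. Scores are binarized at 0.5
(inclusive); threshold and exclusion cutoff are CLI flags. Unaligned
positions and queries with no usable homolog stay MISSING (NaN / `NA`) —
never silently 0 — and are resolved by the hybrid stage.

## PSSM-window SVM

Features are the PSSM rows in an odd-width window centered on the residue,
flattened (window × 20), with zero-vector padding beyond the ends; the
default width 21 is the tuned value from the published protocol. Features
are standardized; the SVM is an RBF-kernel SVC with class weights inverse
to class frequency (interface residues are the minority class). The cost
parameter is a *total budget*: the per-sample cost is C/n_train, which makes
the fitted decision function invariant to duplicating the training set (the
solver tolerance is tightened to 1e-7 so this holds numerically). Margins
are mapped to [0, 1] by a logistic (Platt-style) calibration fitted on mean
log-loss over the training margins — mean, not sum, again for duplication
invariance; raw margins remain exposed.

Hyper-parameter tuning follows the published protocol exactly: chains are
split into six seeded parts; one part is a held-out test set untouched by
selection; each (C, γ, window) candidate is scored by mean validation MCC
over sequence-based 5-fold CV on the rest; the winner is refitted on all
training+validation chains. Fold assignments partition whole chains —
chain-level disjointness is asserted programmatically, and a violation is an
error, not a warning. Default grids are powers of two (C: 2⁻⁵…2¹⁵,
γ: 2⁻¹⁵…2³) and odd windows 15–27. The tuned (C, γ) constants of the
original study are not recoverable from the text, so the package ships the
protocol plus configurable defaults rather than claiming specific values.
The PSI-BLAST recipe that produces real PSSMs (3 iterations, inclusion
E-value 0.001, against nr) is documented here as an external step; the
package consumes its ASCII output or synthetic PSSMs.

## The hybrid stage

The stacker is a logistic regression on the 2-D score vector with ridge
penalty on the weights (bias unpenalized), default ridge 1e-8 — effectively
maximum likelihood, matching the cited implementation's default. Missing
homology scores ('?') are imputed with the training-set mean of the
non-missing scores; the imputation value is stored in the model so
prediction is self-contained, and supplying the mean explicitly is exactly
equivalent. If *all* training homology scores are missing, the fit
degenerates to an SVM-only logistic model with a warning. Training uses
out-of-fold SVM scores (sequence-based k-fold) by default, an interpretation
chosen to prevent within-chain leakage into the stacker. Fitting is
Newton/IRLS with step damping for separable data; standard errors come from
the unpenalized Fisher information at the estimate. Output probabilities
are clipped to (1e-12, 1 − 1e-12) so they are strictly inside (0, 1) even
when the logit saturates.

## Evaluation conventions

"Specificity" here is TP/(TP+FP) — a precision — and is always reported
with the alias `specificity_precision` to prevent misreading. Degenerate
denominators (e.g. a predictor that makes no positive predictions) yield 0
plus an explicit flag, never a trivial 1. AUC is the Mann–Whitney
probability that a positive outranks a negative with ties counted ½,
computed from rank sums; it equals the ROC threshold sweep by construction
and is checked against the brute-force pairwise estimator. Residue-pooled
metrics are the default; per-chain macro-averages are available
(`per_chain_macro`) since published tables in this area rarely state which
aggregation they use.

## Synthetic data: what it emulates, what it does not

The generators are pure functions of their seeds and target *statistical
structure only*:

- **Complexes**: residues on a line 20 Å apart (two heavy atoms each, so
  chains are never CA-only), one RNA atom 3 Å from each planted interface
  residue — the 5 Å rule recovers the planted interface exactly, by
  construction. No realistic geometry.
- **Homolog databases**: homolog labels are the query's flipped
  independently with the probability whose expected label correlation equals
  the requested `target_ic` (exact root of the closed-form correlation
  expression); indels are applied after label assignment so position maps
  stay correct. Alignment statistics are chosen by inverting the linear
  model so the predicted IC lands on `target_predicted_ic` (up to the
  integer quantization of the positives count, ≤ 0.6/(2L)), with PS kept at
  or below 0.93 so the similarity exclusion never fires accidentally.
- **PSSMs**: integer background scores uniform on [−3, 2] (the range real
  log-odds concentrate in), with interface rows shifted by the effect size
  on designated columns, optionally at window offsets away from the labeled
  residue (so that only sufficiently wide windows can see the signal);
  values are clipped to [−10, 12] and round-trip through the ASCII format.
  With the default effect (+4 on 3 of 20 columns) the planted signal is
  strong but not degenerate: a correctly trained SVM reaches held-out MCC
  around 0.9 at 400 training residues, while permuted labels stay at chance.

Passing on these fixtures demonstrates correctness of the machinery —
labeling, statistics, selection logic, voting, CV hygiene, stacking,
metrics — not real-world accuracy: synthetic homologs have no real
evolutionary covariance, and synthetic PSSMs have independent rows. The
published benchmark numbers depend on external PDB/PRIDB snapshots and
nr-derived PSSMs and are out of scope at desk scale.

## Problem sizes and numerical choices

The test suite and the reproducibility script use deliberately small
problems (chains of 40–150 residues, 8–12 chains, 400-residue SVM training
sets, n = 2000–5000 for regression recovery), chosen so the full study runs
in well under a minute on one CPU while keeping each statistical check's
sampling error far from its decision boundary. Other numerical choices:
zone boundaries closed below; binarization threshold inclusive at 0.5;
IC of constant vectors 0 + flag; E = 0 capped; OLS via QR (statsmodels);
IRLS steps damped at norm 20 for separable data; SVC tolerance 1e-7.

## Known limitations

- No built-in BLAST/PSI-BLAST invocation: alignments and PSSMs are inputs
  (the CLI consumes tables/files), keeping the package fully offline.
- Redundancy reduction (PISCES/CD-HIT) is external; the database builder
  accepts whatever chain set it is given.
- The combiner stacks exactly two base predictors.
- Calibration of homology vote scores is not modeled beyond the logistic
  stage.
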