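# Methods

This note documents the models, the synthetic-data design, and the numerical
and protocol choices the package makes, in the order data flows through it.

## Cohort model and clinical rules

A cohort is a patients × 305 table of numeric/binary features in six blocks
(history, cardiovascular risk factors, questionnaires, videooculography (VOG),
subjective visual vertical (SVV), posturography), plus a stroke/neuritis label
and an AVS-presentation flag per patient. Missing entries are explicit
(`NaN` internally, `NA` in files, surfaced as a boolean mask) so that matrix
completion can distinguish an observed zero from an absent measurement. The
write/read round trip is bit-exact: floats are serialised with their shortest
round-trip representation and re-parsed with correctly rounded conversion.

Three fixed clinical thresholds are implemented as pure three-valued
functions (missing inputs propagate as missing unless the observed input
already decides the outcome):

* vHIT pathological ⇔ VOR gain < 0.7 **or** refixation saccades present.
  A gain of exactly 0.7 is normal.
* SPN suppressed ⇔ slow-phase velocity decreases by **at least** 40% on
  fixation (either horizontal or vertical component qualifies); undefined
  when the without-fixation SPV is zero.
* SVV abnormal ⇔ |mean deviation| > 2.5°; exactly 2.5° is inside the normal
  range.

The schema names only the clinically meaningful features (the ten
top-discriminative ones among them); each block is padded with systematically
named filler features (`<block>_q###`) to reach 305, since only the block
structure and the headline features of the assessment battery are publicly
recoverable. The schema ships as a versioned CSV asset and is asserted
identical to the in-code builder.

## Synthetic cohort generator

**What it emulates.** The study composition (40 vestibular strokes, 19
presenting as AVS; 68 vestibular neuritis) and the published per-class
distributions of the informative features, e.g. pathological vHIT in 100% vs
12.5% (neuritis vs stroke), vHIT gain 0.6 ± 0.3 vs 0.9 ± 0.3, horizontal SPN
present in 95.5% vs 47.5%, horizontal SPN SPV 4.7 ± 4.0 vs 1.0 ± 1.0 °/s,
fixation suppression of SPN in 94% of neuritis patients with SPN, age
55.6 ± 14.6 vs 64.1 ± 12.2 years, male 64.7% vs 67.5%. Quantities that cannot
be negative (gains, SPVs, ages, amplitudes) are drawn from zero-truncated
Gaussians; truncation shifts the realized mean, and
`truncated_normal_mean(mu, sd, lower)` reports the implied moment (for the
stroke gain, 0.9013 rather than 0.9000). Missingness is MCAR at a
configurable cell rate (default 5%), never applied to labels or the AVS flag.

**Enforced couplings.** Within a class, features are sampled independently
except where logic demands otherwise:

* The AVS subgroup realizes the stroke SPN rate: AVS is defined by the
  presence of spontaneous nystagmus, so the 19/40 AVS strokes have SPN and
  the non-AVS strokes do not (19/40 = 47.5%). SPN SPVs and amplitude are zero
  when SPN is absent, and SPV parameters are interpreted as conditional on
  SPN presence (an SPV is only measurable when nystagmus exists).
* With-fixation SPVs are derived from without-fixation SPVs through a sampled
  suppression fraction — uniform on [0.40, 0.95] for suppressed patients,
  on [0, 0.39] otherwise — so applying the ≥ 40% rule to the generated SPV
  pairs recovers the configured suppression probability exactly.
* Refixation saccades occur only in patients rated vHIT-pathological, and
  every pathological rating is supported by a sub-0.7 gain (either side) or
  saccades. The converse is deliberately not enforced: the recorded
  right-side gain follows its published marginal (0.9 ± 0.3 in stroke), which
  implies ~25% of raw stroke gains fall below 0.7 while only 12.5% of strokes
  are rated pathological — the two published numbers are incompatible under a
  strict two-way rule, so the rating is modelled as the clinician's aggregate
  judgement, which dominates a single raw gain value. The HINTS head-impulse
  item is always the exact negation of the rating.
* The ABCD² age item is derived from the sampled age (≥ 60), the BP item
  from sampled systolic/diastolic pressures, the duration item from sampled
  symptom duration; the stored category flags are consistent with the
  minutes by construction.

**Chosen, not published.** Parameters the source tables do not print were
fixed once at clinically plausible values and are declared in
`synth.BINARY_PARAMS` / `synth.CONTINUOUS_PARAMS`: stroke fixation
suppression of SPN at 0.25 (central nystagmus is typically not suppressed by
fixation), skew deviation in 25% of strokes (its reported manifestation
rate) vs 2% of neuritis, direction-changing gaze-evoked nystagmus 35% vs 2%,
ABCD² component rates (weakness 15%/1%, speech impairment 10%/1%, diabetes
25%/12%, BP distributions around 155/88 vs 145/84 mmHg), and mild
posturography effects. Questionnaire scores and filler features are
class-independent, which makes planted-signal recovery tests well defined.

**Class-separation scale.** A single multiplier interpolates *every*
per-class parameter — probabilities, means, and standard deviations — between
the pooled class midpoint (scale 0) and the configured values (scale 1).
Interpolating the SDs matters: with truncation at zero, a residual variance
difference alone would shift realized means and leave class signal in a
supposedly null cohort. At scale 0 the two classes are distributionally
identical.

**What it does not emulate.** Between-feature correlation beyond the enforced
couplings (a `filler_correlation` hook exists for robustness experiments),
symptom time-courses, device artefacts, and informative missingness. Because
the planted univariate effects are large and independent, classifiers reach
higher absolute performance here than on real clinical data; passing tests
demonstrates pipeline correctness and calibrated generator fidelity, not
clinical performance.

## Index tests

HINTS and ABCD² are deterministic point scores (cutoffs ≥ 1 and ≥ 3). The BP
item counts if systolic ≥ 140 **or** diastolic ≥ 90 mmHg, the usual
convention in the TIA-score literature; duration points use the half-open
bands [10, 60) and [60, ∞) minutes. Missing items raise by default; the
cohort-level scorer uses an explicit missing-as-peripheral policy (0 points
for the missing item) and flags affected patients, since prospective
whole-cohort evaluation must produce a decision for everyone. Score AUCs come
from sweeping the integer cutoff; with ties counted one half this equals the
Mann–Whitney pair statistic, which the tests verify by exhaustive pair
counting.

## Baseline classifiers

All three baselines share one preprocessing contract, frozen at fit time from
the training data only: per-feature mean imputation (mode for binary
features), then z-scoring for the logistic regression and the MLP (the forest
sees unscaled values). The logistic regression is elastic-net penalised
(saga solver) with the L1/L2 balance and strength tuned on the validation
split; the forest size is tuned within 5–50 trees; the MLP has hidden layers
of 128 and 64 ReLU units with a 2-class probabilistic output (scikit-learn
parameterises the binary case with a single logistic output, which is the
same model up to reparameterization), Adam, and a fixed epoch cap declared in
the grid. Tuning maximises validation AUC over the declared grid; ties
resolve to the smallest-capacity spec (fewer trees, stronger regularisation)
and failing specs are skipped with a logged warning.

## Geometric matrix completion

**Graphs.** Binary patient-similarity graphs: an edge iff |Δage| ≤ 5 years or
|ΔABCD²| ≤ 1 point. A patient with a missing meta-feature gets no edges under
that criterion (conservative; logged). SingleGMC uses the element-wise sum of
the two graphs (weights {0, 1, 2}, used as-is in the Laplacian; a flag can
binarize); MultiGMC keeps them separate.

**Model.** The input is the masked patients × (305 features + 1 label)
matrix: feature columns are z-scored by observed-entry statistics and
zero-filled where missing; the label column is +1 (stroke) / −1 (neuritis)
for training patients and 0 where hidden. Per graph, one spectral
convolutional layer filters the input with Chebyshev polynomials of order
K = 3 on the symmetric-normalized Laplacian rescaled by the λ_max = 2 bound
(L̃ = L − I); a degree-0 node has an identity Laplacian row, so an edgeless
graph degenerates to a graph-independent linear map. Because the propagated
signals T_k(L̃)X are fixed, they are precomputed and the layer is a dense
linear map followed by ReLU into a width-32 embedding. With several graphs,
a per-patient scalar score per graph (a learned linear functional of that
graph's embedding plus a per-graph bias) is softmax-normalised across graphs
into attention weights that convexly combine the embeddings — the simplest
self-attention consistent with per-patient graph weighting; a single graph
fuses to itself with weight 1. Two linear heads map the fused embedding to
class logits and to reconstructed feature columns.

**Loss and training.** Masked loss = cross-entropy over observed training
labels + μ · mean squared reconstruction error over observed feature entries
(μ defaults to 1). Masked entries are never read anywhere — the tests verify
numerically that perturbing them leaves the loss bit-identical. Training is
full-batch with analytic gradients and Adam (default rate 0.02, 300-epoch
cap) or plain gradient descent (used by the monotone-loss contract test);
early stopping monitors validation AUC with patience 40 and restores the
best-validation parameters. Everything is deterministic given the seed.

**Transduction.** All patients are graph nodes in every fold; only validation
and test labels are masked. Flipping a hidden label changes no training-time
quantity (verified bit-wise), and prediction for a patient absent from the
graphs is an error — there is deliberately no inductive path.

## Evaluation protocol

Stratified k-fold CV (default k = 10 — the protocol's stated fold count,
recorded in every report since aggregate behaviour differs at other k) with
shuffled, seeded splits: test folds partition the cohort with class
proportions within one patient of global; a further stratified ~10% of each
training part is withheld as the validation set. Baselines are tuned on
(train, validation) and the selected spec's validation-fitted model predicts
the test part; completion models fit once per fold with validation-based
early stopping. Index tests are evaluated once on the full cohort at their
fixed cutoffs — their parameters are not learned, so CV would only shrink
their evaluation set — and reports flag them as such to prevent unfair
comparison.

Model pairs are compared by a two-tailed Wilcoxon signed-rank test on
per-fold accuracies: zero differences dropped, midranks for ties, the exact
null distribution (dynamic programming over doubled midranks, two-sided
p = 2·min(lower tail, upper tail) capped at 1) for up to 25 non-zero
differences, and a tie-corrected normal approximation above. The in-package
implementation exists because the exact path must accept tied ranks; tests
cross-check it against brute-force sign enumeration and against the
large-sample normal reference.

MDI feature importance is computed on a 50-tree forest fitted to the full
labeled cohort (a per-fold option exists), normalised to sum to one, ordered
descending with a stable tie-break in schema order. The univariate follow-up
table uses the 2×2 χ² test without continuity correction for binary features
and the two-sided tie-corrected Mann–Whitney U otherwise, with no
multiple-testing correction (noted in the output); degenerate tables and
zero-variance features report p = 1 with a note.

One top-level seed expands into per-component seeds via a stable label hash
(`_rng.derive_seed`), so the generator, the folds, and each model on each
fold are independently reproducible; pipeline reruns are byte-identical.

## Problem sizes used by the test suite

Generator-fidelity checks use 4,000 patients per class (binomial/Gaussian
3-standard-error bands); the type-I sanity check runs the five ML methods
under the full default protocol (declared tuning grids, default completion
configuration, ten folds) on twenty signal-free cohorts (separation scale 0,
n = 108), judging each method's AUC aggregated across the twenty seeds — a
single seed's mean over ten ~11-patient test folds has a null sd of ≈ 0.06,
so per-draw bands would flag pure noise; signal-recovery checks use ten
default cohorts; the Single-vs-Multi non-inferiority check is scaled to three
seeds at five folds. Example scripts and the acceptance script run in
seconds to a few minutes on one CPU.

## Known limitations

* Independence within class (beyond the enforced couplings) understates the
  redundancy of real VOG batteries; MDI rankings on synthetic data therefore
  spread importance differently than on correlated clinical data, although
  the aggregated vHIT rating still dominates.
* The completion model's classification head and embedding width are not
  recoverable from the source description; the declared defaults are the
  package's own and live in `GmcConfig`.
* Real-data headline results are not reproducible here by construction — the
  clinical cohort is not deposited — and nothing in this package should be
  read as a clinical performance claim.
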