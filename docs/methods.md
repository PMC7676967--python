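# Methods

## The model

A patient's body constitution (BC) is one of nine types; the CCMQ decides
it from 60 five-point Likert items grouped into nine subscales. For a
subscale with `n` items, the raw score is the sum of its item answers,
with reverse-keyed items contributing `6 − answer`, and the transformed
score rescales it to [0, 100]:

    TS = (raw − n) / (4n) × 100.

The judgment standard assigns per-constitution statuses — an unbalanced
type is "yes" at TS ≥ 40 and a "tendency" at TS ≥ 30; Balanced is "yes"
only when its own TS ≥ 60 *and* every unbalanced TS < 30. For training
labels, exactly one constitution per respondent is needed, so the primary
label is the argmax of the nine transformed scores; the statuses are
computed and reported but do not influence the label. Ties are broken
deterministically by the constitution listing order, by default in favour
of the *last* tied type (the behaviour of a scanning maximum that updates
on `>=`; this convention reproduces the reference label distribution —
see "Reconstruction" below), switchable to the first via
`tie_break="first"`. Transformed scores are rationals with denominator
`4n`, exactly representable in double precision, so the argmax needs no
epsilon.

The adaptive-inquiry pipeline then: (1) enumerates the 84 unordered
triples of distinct constitutions — every possible top-3 output of an
upstream image-based classifier; (2) filters the labeled dataset to each
triple's rows; (3) ranks questions by chi-squared importance and keeps the
top k; (4) trains a per-triple classifier on those k columns; (5) at
inference, serves the patient's triple model and predicts one member of
the triple. The prediction is closed-world by construction: the
classifier's classes are the triple.

## Synthetic respondents

Training data is simulated: every answer is an independent uniform draw
from {1..5}. Under this null model each subscale's transformed score has
mean 50 and standard deviation `25·sqrt(2/n)`, so *smaller subscales win
the argmax more often* — that alone shapes the label distribution, and is
why Damp-heat (the smallest subscale, 6 items) is the most frequent label.
Uniform answers carry none of the structure of real respondents: no item
correlations within a symptom domain, no response styles, no
subscale-level severity gradients. Consequently the high cross-validated
accuracies reported here certify that the pipeline can recover the scoring
rule from data at scale; they say nothing about accuracy on human
respondents, which the instrument's clinical validation must establish.

Duplicates among the 5^60 possible answer vectors are astronomically
unlikely at any feasible m, so no deduplication is performed. One
user-facing integer seed drives everything; substreams (per-combination
training, CV shuffling, fold models) derive child seeds deterministically
via `SeedSequence` + CRC32 of the stream name, all below 2^31.

## The shipped questionnaire configuration

The item↔subscale mapping is instrument metadata and ships as editable
YAML, never hard-coded. The shipped default is a **reconstruction**, not
the licensed instrument text:

* Unbalanced subscale sizes follow the published standard: Qi-deficient 8,
  Yang-deficient 7, Yin-deficient 8, Phlegm-dampness 8, Damp-heat 6,
  Stagnant Blood 7, Stagnant Qi 7, Inherited Special 7. Items are laid out
  in contiguous id blocks (1–58).
* The Balanced subscale has 8 items: 3 Qi-deficiency and 4 Yang-deficiency
  items reused with *reversed* keying, plus one positively keyed item of
  its own (id 59). Item sharing is what lets 66 subscale slots fit into a
  60-item questionnaire, and it is essential to the published behaviour of
  the pipeline: the best question-set size for the
  {Balanced, Yang-deficient, Qi-deficient} triple equals the 16 distinct
  items its three subscales actually span (8 + 7 + 1), and the Balanced
  scale's negative correlation with the deficiency scales raises its
  argmax-win share to the observed level. Because a shared item is keyed
  oppositely in its two subscales, reversal is configurable per subscale
  (`reversed:` list), not only per item.
* Item 60 — the instrument's gender-conditional question, merged into a
  single gender-neutral item — is left unscored by default.
* Judgment thresholds are the published 40/30 (unbalanced) and 60-with-
  others-below-30 (Balanced) values.

The reconstruction was selected by matching, under the uniform null, (a)
the reference per-label distribution of one million respondents (exact
argmax-probability computation over candidate subscale-size vectors and
both tie conventions, plus Monte Carlo for shared-item designs), and (b)
the published per-triple question-set sizes and LDA accuracies. It is the
best fit we found, not a verified copy: per-label agreement is within
0.25 percentage points for five of nine labels but Yang-deficient remains
about 1.2 pp high (the cost of not knowing *which* items the Balanced
scale truly borrows). Configurations holding the real instrument should
replace the default YAML; no code changes are needed. By default an item
may belong to only one subscale (violations are load errors); a config
must explicitly set `allow_shared_items: true` — as the shipped default
does — to permit sharing, which is then logged.

## Feature selection

Two chi-squared variants are provided; both are filter methods (they never
consult a classifier):

* `feature-sum` (default): Likert values are treated as counts; for item j
  the observed value per class is the class-wise answer sum, the expected
  value allocates the item's total by class frequency, and
  `W_j = Σ_c (O_cj − E_cj)² / E_cj`. This is the classic feature-scoring
  chi-squared (delegated to `sklearn.feature_selection.chi2`, which
  computes exactly this; a loop-based oracle in the tests pins the
  formula).
* `contingency`: Pearson chi-squared on the 5×C table of answer-level
  counts per class; cells with zero expected count contribute 0 (scipy's
  `chi2_contingency` rejects such tables, so this variant is computed
  directly).

Answers enter raw (1–5), neither centred nor one-hot. Top-k selection
breaks score ties toward the lower item id, making selections
deterministic and nested in k.

## Classifiers and evaluation

Per-triple classifiers use scikit-learn defaults: LDA (closed-form,
deterministic), a single-hidden-layer perceptron sized ~2k units, RBF-SVM,
random forest, k-NN. Evaluation is stratified 5-fold cross-validation
(stratification stabilises the rarer label in imbalanced triples): test
folds are disjoint and cover the data; both the fold-mean and best-fold
accuracy are reported because both conventions are used in practice; micro
precision/recall/F are computed on the pooled out-of-fold predictions and,
for single-label multiclass, coincide with pooled accuracy; macro metrics
average unweighted over the three classes. Prediction wall time is logged
per panel but is informational only (hardware-dependent).

The `sweep_k` operation evaluates one fixed ranking at each k and reports
the argmax-k and the smallest k within a tolerance (default 0.05
percentage points) of the maximum; `train_all`'s `k_policy="auto"` uses
that smallest-good-k per triple. Class imbalance across a triple is left
as-is (no rebalancing); counts are recorded in the registry manifest.

## Numerical and degenerate-input choices

* Scoring raises on answers outside [1, 5], non-rectangular input, or a
  column count that differs from the questionnaire.
* Chi-squared scoring requires ≥ 2 classes; a constant item scores 0.
* Cross-validation requires every class to have at least as many rows as
  folds; training a triple with a missing constitution raises an error
  naming it.
* Filtering a dataset to a triple with no matching rows warns (with the
  combination index) rather than raising, since downstream training gives
  the actionable error.
* An empty response matrix labels to an empty dataset.

## Known limitations

* The shipped mapping is calibrated, not transcribed; per-label
  distribution error up to ~1.2 pp remains (Yang-deficient), and the exact
  borrowed-item pattern of the Balanced scale is an informed guess.
* The idealization "LDA on all 60 items exceeds 99% CV accuracy for every
  triple" — motivated by the label being an argmax of linear scores — is
  only marginally true. LDA's shared-covariance decision rule cannot
  exactly represent an argmax of arbitrary linear scores; triples mixing
  very different subscale sizes (especially Damp-heat's 6 items against
  8-item scales) fall to 98.5–99.0% at m = 10⁵ (24 of 84 triples below
  99%) and only just clear 99% at m = 10⁶ (worst triple 99.03%). The
  corresponding pipeline-property test runs at m = 10⁵ and documents this
  gap; the two featured triples are unaffected.
* Sessions serve the whole question set at once; there is no
  question-by-question adaptation, no multi-constitution output, and no
  modelling of the "tendency" band as a soft label.
* Problem sizes in the test suite are scaled for a desk machine: the label
  distribution and featured-triple accuracies are checked at the full
  m = 10⁶, pipeline-wide properties (84 models, session replay) at
  m = 10⁵ with a 2×10⁴ probe.
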