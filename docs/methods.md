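# Methods

`ehrseq` implements a sequence-modeling pipeline for predicting chronic
disease onset from longitudinal electronic health records, together with a
synthetic-data generator that makes every stage testable without access to
real patient data. This note records the models, the parameters that
matter, the numerical choices, and what the synthetic experiments do and do
not demonstrate.

## Study design

Time is split into an **observation window** (2010 through the end of
2017), from which all features are drawn, and a **prediction window**
(2018-01-01 to 2020-12-31), in which a first diagnosis of the target
disease defines the positive label. The feature cutoff and the labeling
cutoff are both 2018-01-01, so no token can derive from an event on or
after the first day of the prediction window; the leakage guard in the
test suite proves this by reconstructing every timeline from pre-cutoff
events alone.

Cohort selection is a fixed-order exclusion cascade recorded in an
attrition table: (1) age under 18 at the cutoff, (2) fewer than 20 recorded
items inside the observation window, (3) disqualifying diagnoses (e.g.,
type 1 diabetes for the type 2 cohort), (4) pre-existing target disease,
(5) disease-typical medication classes (ATC prefixes) or repeated
diagnostic lab values without any target diagnosis. Step 4 is skipped for
acute recurrent outcomes (myocardial infarction), where any in-window event
is a positive label regardless of history. The "20 items" rule counts raw
tokenizable events before age/demographic token insertion, so the filter is
not diluted by synthetic tokens. The "diagnostic labs" rule is a
configurable predicate; the default requires at least two glucose values in
the top decile bin, on the argument that diagnosis by lab requires repeated
elevation — a single extreme value is common noise.

Patients are split 90/5/5 into train/validation, test, and a transfer pool.
Training uses a 60:40 control:case downsample; the test split is never
downsampled and always evaluated at its real class distribution.

## Tokenization

A patient's record becomes one token sequence under a closed grammar:
bare codes for diagnoses/procedures/medications; `code_outcome` for
categorical test results; `code_b` (b in 0..9) for numeric observation
values; `age_N` once per calendar year; `type_admission`, `habit_value`
and `insurance_type` tokens; terminal `race_*` and `gender_*` tokens.
Codes may not contain underscores; that restriction makes the grammar
unambiguous and every emitted token parses back to its kind and
components.

Numeric values are winsorized per code at the 1st/99th percentile (linear
interpolation between order statistics — documented so the test oracle
matches), min-max scaled against the saved training minima/maxima, and
assigned to ten bins, half-open `[0.0,0.1) ... [0.8,0.9)` with a closed top
bin `[0.9,1.0]`; boundary values promote to the upper bin. At inference,
out-of-range values are clamped to the saved training range, so every value
bins. Codes whose training range is degenerate (min = max) map to bin 0,
which avoids a division by zero while preserving the presence signal. For
reporting, bins are de-normalized back to original units so a ranked
feature reads "Systolic blood pressure, 143.3–149.9".

Events are ordered by date; within-date order (not meaningful in EHR
extracts) is randomized by a generator keyed on `(seed, patient_id)`, so
timelines are reproducible under any processing order. Age tokens open
each calendar year — placed before that year's events so age reads as
context for what follows — and years without events still emit their age
token, encoding elapsed time. Insurance tokens are emitted in-sequence at
their change dates; race and gender are appended at the end of the record.
Observation codes missing from the scaler fall back to the bare code by
default (preserving record-length statistics), with drop/error policies
available.

## Concept embeddings

Pre-training is skip-gram with negative sampling over pre-cutoff timelines:
5 negatives from the unigram distribution raised to 3/4, dynamic window
shrinkage, frequent-token subsampling at threshold 1e-3 (which both curbs
the dominance of near-universal tokens and keeps batched updates stable;
disable it on toy corpora where every token is frequent), linearly decaying
learning rate from 0.025, logits clipped to ±8. Defaults are dimension 128
and window 5. Training processes pair mini-batches (2,048 pairs) with a
sort/segment-sum scatter (orders of magnitude faster than naive buffered
scatter-add); a fixed seed reproduces vectors exactly because all sampling
comes from one generator. Epochs (5) and `min_count` (5) are configurable.

When pre-trained vectors initialize a classifier, rows are rescaled so
their mean norm matches the downstream uniform(±0.05) initialization.
Trained skip-gram norms are an order of magnitude larger, and initializing
a recurrent layer at that scale saturates its gates — in pilot runs it
reversed the sign of the transfer benefit. Rescaling preserves all cosine
geometry.

## Risk model

The classifier embeds the most recent `max_seq_len` (default 3000) tokens —
truncation keeps the terminal race/gender tokens, since demographics must
survive truncation — and runs one bidirectional GRU layer (hidden size 64
per direction by default), global max pooling over the per-position outputs
with padding masked out, and a sigmoid unit. A `simple_maxpool`
architecture (embedding, max pool, sigmoid) supports the feature-ablation
screening harness, which reserves a 10% holdout, trains a baseline on
diagnoses/procedures/medications/observation codes, and adds candidate
features individually or cumulatively.

Forward and backward passes are explicit numpy; gradients are verified
against finite differences in the tests. Training is Adam (1e-3), batch 64
bucketed by length, BCE loss, early stopping with the best epoch selected
by validation ROC AUC (the task metric; selection by validation loss is
available, as is learning-rate decay on plateau). Parameters are float32;
inference runs in float64, which makes scores invariant to batch
composition within 1e-9. The embedding mode is `random_init`,
`frozen_pretrained` (table bit-identical after training), or
`finetuned_pretrained`; pre-trained rows are rescaled to the downstream
initialization norm (see above).

Evaluation reports ROC AUC plus precision/recall among the top 1/5/10%
ranked patients — the operational question for population health
management is "if a care team works the top k% of the list, what fraction
of future cases do they reach?" Ties break by patient id for
reproducibility; incidence is the raw test-split rate.

## Transfer protocol

Small labeled samples (500–6,000 positives with 1.5 negatives each, i.e.
total sizes 1,250–15,000) are drawn from a pool disjoint from embedding
pre-training; each (size, seed) cell trains one model per arm
(random vs fine-tuned pre-trained) with an 80:20 train/validation split and
evaluates on a common test set at the real class distribution; per-seed
results are persisted so reported means are recomputable. Both arms train
to convergence under the same settings as the main model: with a truncated
epoch budget the fine-tuned arm is still mid-way through reshaping the
pre-trained geometry and measures worse than random initialization, so an
under-trained comparison systematically understates the transfer benefit. The
cross-region protocol excludes a region from pre-training entirely and
splits it 70:30 into pool and test. At desk scale the pool comes from a
freshly generated population in a distinct id namespace — statistically
exchangeable with the pre-training population — because a 5% slice of a
20,000-patient study cannot contain 500 cohort positives; manifest
disjointness is asserted before any run.

## Attribution

Each prediction is decomposed into a base value plus one additive
contribution per token. Two methods:

* **exact** — Shapley values over token positions by coalition enumeration
  (a coalition's value is the score of the subsequence keeping its
  positions); used for records of ≤ 12 tokens and as the reference in
  tests, where it is checked against an independent brute-force
  implementation.
* **integrated gradients** (default) — the straight path from the
  all-padding (zero-embedding) baseline to the embedded record,
  Gauss-Legendre quadrature starting at 64 nodes and doubling until the
  additivity gap |base + Σφ − score| is below the stated tolerance
  (default 0.01 on the probability scale) or 512 nodes. The achieved gap
  is recorded per explanation. A single zero baseline is used rather than
  a sampled background set: it keeps the additivity bookkeeping exact,
  which the toolkit treats as the contract worth testing.

Population ranking sums contributions per distinct token across patients
(magnitude times prevalence); duplicate positions within a patient sum
first, which is equivalent. The reported "top predictors" view filters to
clinical tokens (diagnoses, procedures, medications, observations/values),
since age and demographic tokens otherwise dominate by sheer frequency.
`audit_suspect_features` flags top-ranked tokens from the cohort's
exclusion medication classes — the programmatic analogue of a clinician
noticing disease-typical prescriptions among top predictors, which usually
indicates missed diagnosis codes upstream.

## Synthetic data generator

The generator emulates the structure the pipeline assumes, not real
epidemiology. Per patient: Poisson(3) visits per year over 2010–2020
(1–8 events per visit, so within-date ordering ambiguity actually occurs),
background events over toy SNOMED/NDC/LOINC-style vocabularies with
Zipf-like code frequencies, insurance changes (25% of patients), habit
records, demographics with five regions, and geometric right-truncation
(2%/year). Disease onset is a single logistic draw per patient per
disease — matching the binary three-year label rather than a full
time-to-event model: counts of five planted drivers per disease (extreme
observation values, risk-factor diagnoses, smoking) are Poisson with a
shared per-patient gamma frailty (shape 2) multiplying every driver rate,
so risk factors co-occur within patients the way metabolic-syndrome
components do; the intercept is calibrated by bisection so the population
mean onset equals the configured prevalence. Driver observation events
draw values from the top (or bottom) decile of their code's distribution,
so the *binned token*, not the raw code, carries the signal, and a
patient's repeat measurements of one code share a persistent offset
(correlation 0.6), so they land in nearby bins. The frailty and the value
consistency are what give pre-cutoff corpora co-occurrence structure at
all — without them, skip-gram has nothing to learn beyond frequency and
age adjacency, and the embedding-locality properties cannot hold. Onset emits a disease diagnosis
(root or toy descendant, exercising hierarchy expansion) followed by
disease-consistent medications; truncation before onset produces the
realistic mislabeled negative.

Deliberate scale-downs, chosen once as the package's study conditions:
populations in the tens of thousands rather than tens of millions; onset
prevalence 8–10% rather than sub-1% three-year rates, so desk-scale cohorts
and 500-positive transfer samples exist; records averaging ~130 tokens
rather than ~500. Driver effect sizes were set at design time so the
analytic ceiling (AUC of the latent linear predictor against simulated
onset) leaves clear headroom for a sequence model that observes only noisy
tokens; with the shared frailty the ceiling is ≈ 0.98 per disease. One generator seeded by `config.seed` drives
all draws in a fixed order, so populations are byte-reproducible; this is
a single-stream design rather than per-patient hash substreams, trading
parallel generation for vectorized speed.

What passing tests show: the pipeline recovers planted signal end to end —
classifier AUC well above chance and near the latent ceiling, planted
drivers at the top of the attribution ranking, pre-training benefit at
small sample sizes. What they do not show: performance on real EHR data,
whose code distributions, visit dynamics, missingness and label noise are
far richer; absolute metric values here are properties of the simulator's
conditions, not clinical claims.

## Known limitations

* The GRU is one bidirectional layer with modest hidden size; no attention,
  no hierarchical visit structure.
* The synthetic vocabulary is small (~2,500 token types), so informative
  tokens are frequent even in 1,250-patient samples and the measured
  benefit of embedding pre-training is far smaller than on real data,
  where most of a 150k-token vocabulary is unseen at that sample size.
* Integrated gradients is exact in the limit of the quadrature but inherits
  max-pooling's piecewise structure; the recorded gap is the honest bound.
* The simulator shares drivers across diseases but has no deeper
  comorbidity network, no seasonality, and no coding-practice drift.
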