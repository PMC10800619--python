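# ehrseq

Sequence modeling of longitudinal electronic health records for
population-health risk stratification: token timelines with decile-binned
observation values, skip-gram concept embeddings, BiGRU onset classifiers,
transfer learning with scarce labels, and additive per-token
explainability — exercised end to end on a built-in synthetic EHR
generator with planted risk drivers.

## The problem

Population health management teams want to find, inside a large covered
population, the patients most likely to receive a first diagnosis of a
chronic condition (type 2 diabetes, hypertension, COPD) or an acute event
(myocardial infarction) within the next three years, early enough for
preventative intervention — and they need the model's reasons to be
reviewable by clinicians. `ehrseq` is a toolkit for building and auditing
such models from long-format event tables (diagnoses, procedures,
medications, lab observations with values, admissions, habits, insurance
changes, demographics).

## The method

A patient's record over an observation window becomes one token sequence:
codes ordered by date (within-date order randomized), lab values winsorized
at the 1st/99th percentile, min-max scaled per code, and binned into
deciles (`8480-6_9` = systolic blood pressure in the top decile), one
`age_N` token per calendar year, and terminal race/gender tokens. The
label is first target diagnosis (hierarchy descendants included) inside the
prediction window; a fixed exclusion cascade with an auditable attrition
table defines the cohort.

Skip-gram embeddings (negative sampling, window 5) are pre-trained on
pre-cutoff timelines; the risk model is a bidirectional GRU with global max
pooling and a sigmoid output,

    p(onset) = sigmoid( w . maxpool_t [ GRU_fwd(e_1..e_T); GRU_bwd(e_T..e_1) ]_t + b ),

trained on a 60:40 control:case downsample and evaluated on an untouched
test split at the real class distribution (ROC AUC plus precision/recall
of the top 1/5/10% risk population). Predictions decompose into additive
per-token Shapley-style attributions (exact enumeration for short records,
adaptive integrated gradients otherwise), summed across a class-balanced
sample into a population feature ranking with bins de-normalized back to
original units. A transfer harness measures the value of the pre-trained
embeddings when only 500–6,000 labeled positives are available, within a
population or across a held-out region.

All neural components (skip-gram, BiGRU with exact hand-written gradients,
attribution) are implemented in numpy; see `docs/methods.md` for model
details, parameter choices, and what the synthetic experiments do and do
not show.

## Worked example

```bash
python examples/05_risk_model.py
```

runs the whole pipeline on a 5,000-patient synthetic population (seed 0)
and prints:

```
attrition:
                       step  excluded  remaining
                    initial         0       5000
               age_under_18       410       4590
               short_record        51       4539
        exclusion_diagnosis        57       4482
       pre_existing_disease         0       4482
exclusion_medication_or_lab       126       4356

test n=218, incidence 9.6%
test ROC AUC: 0.822
top  1% risk population: precision 100.0%  recall  14.3%
top  5% risk population: precision  54.5%  recall  28.6%
top 10% risk population: precision  40.9%  recall  42.9%
```

Reading: the cohort keeps 4,356 of 5,000 simulated patients after the
exclusion cascade; on the held-out test split this deliberately quick,
small-scale model already ranks future diabetes cases well above controls
(AUC 0.82; the full-size 20,000-patient study reaches ~0.94), and a care
team contacting the top 10% of the ranked list would reach ~43% of the
patients who actually develop the disease — at a 9.6% background rate.
The other scripts in `examples/` walk through each capability separately
(simulation, tokenization, cohorts, embeddings, explainability, transfer);
a thin `ehrseq` command-line interface wraps the same functions for shell
use (`ehrseq --help`).

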