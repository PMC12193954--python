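# Methods

This note documents the models, conventions and defaults behind `pdsocial`,
what the synthetic data do and do not emulate, and the choices made where
the design was genuinely open.

## Problem setting

The pipeline quantifies Parkinson's-disease-related discourse in donated
personal Facebook archives from a movement-disorder cohort: people with PD,
essential tremor (ET), atypical parkinsonism (AP), and caregivers (CG).
Every participant contributes a directory of JSON export files and a
metadata row (group, gender, age at interview, interview date, diagnosis
date — possibly missing for caregivers). The quantity of interest per
participant and timeframe is the share of PD-related posts among all posts,
compared within subject across the diagnosis boundary and between groups.

## Ingestion and deduplication

Facebook exports spread one author's text across several JSON files that
are not mutually exclusive. Harvesting walks every JSON value and emits one
entry per text-bearing key (`post`, `comment`, `description`, `title`)
stamped with the nearest enclosing `timestamp`; untimestamped text is
discarded because every downstream analysis is time-indexed.

Cleaning is three idempotent steps: encoding repair (re-encode as
Latin-1/cp1252 and re-decode as UTF-8, iterated to a fixpoint, NFC
normalization; ASCII text is invariant and unrepairable text passes
through), removal of quantified relative-time stamps (`digit-or-number-word
+ year/month/day + "ago"` plus trailing punctuation — unquantified phrases
like "years ago" are left alone), and whitespace collapse.

Deduplication operates per participant on cleaned text, case-sensitively:

1. identical (timestamp, text) pairs collapse to one;
2. in time order, a repeated text is retained only if at least **180 s**
   have elapsed since the most recently **retained** occurrence of that
   text.

Anchoring the window to retained occurrences (rather than the immediately
preceding occurrence) makes chains deterministic: in a burst of re-saves
every copy inside the window is dropped, and the first copy outside it is
kept as a deliberate reshare. The suite checks the fast implementation
against a brute-force restatement of the rule on thousands of random
inputs.

## Lexicon

The term dictionary is a flat UTF-8 file, one lowercase term per line with
an optional tag in {symptom, medication, advocacy, exercise, other}. The
bundled `data/pd_terms.tsv` is a **reconstructed starter dictionary**
(~190 terms) assembled from clinical PD vocabulary, common drug names,
advocacy phrases, PD-community exercise programs and deliberately ambiguous
everyday words; any larger dictionary in the same format can be supplied at
run time. Terms and posts are preprocessed identically — lowercase,
punctuation stripped, stop words removed (fixed bundled list), Porter
stemming — and a post is flagged if any term matches on either the raw or
the stemmed token stream; multi-word terms match as consecutive
stopword-filtered tokens. Matching is over-inclusive by design; precision
is the classifier's job.

Explicit-mention rules run on raw text and bypass everything else: a
case-insensitive `parkinson` substring, and `\bPD\b` applied
**case-sensitively** (case-insensitivity would hit casual "pd" and the
rule's purpose is avoiding false matches such as "updated").

The exercise-excluded sensitivity analysis is tag-based: a post is
`exercise_only` when it is PD-related, all its matched terms carry the
`exercise` tag, and it has no explicit mention; the variant percentages
drop exactly those posts. Explicit mentions are never excluded.

## Features

Four blocks, all fitted on training data and applied frozen to test data:

| block | content | default |
|---|---|---|
| lemma TF-IDF | noun-default lemma 1–3-grams | min document frequency 2 |
| cluster TF-IDF | token→cluster unigrams, OOV id for unknown tokens | min document frequency 2 |
| age | age at posting, min–max scaled by training bounds, clipped to [0, 1] | — |
| one-hot | gender and diagnosis-group levels seen in training | unseen level → all-zero |

The TF-IDF variant is raw term count × smoothed idf, `ln((1+N)/(1+df)) + 1`,
with L2 row normalization within each text block; the suite pins this
variant with hand-computed toy matrices. Age at posting is derived as
`age_at_interview − (interview − post)/365.25 d`, floored at 0, because
birth dates are not collected; min–max scaling (not z-scoring) keeps the
matrix nonnegative so a multinomial Naive Bayes applies. Model-side text
cleaning removes URLs, @-tags, #-hashtags, punctuation and stop words;
lemmatization assumes noun forms by default (a rule-based singularizer with
an irregular-plural table), so gerunds like "trembling" deliberately stay
unchanged. The bundled cluster table is a small synthetic fixture grouping
lexical variants; it is an exchangeable input, not a dependency.

## Classifier

Families: multinomial Naive Bayes, linear SVM (probability-calibrated so it
can join the soft-voting ensemble), decision tree, random forest, AdaBoost,
XGBoost, KNN, plus an unweighted soft-voting ensemble over all tuned
members. Tuning is grid search with stratified 5-fold CV scoring
macro-averaged recall; the grids are small documented defaults (NB
smoothing {0.1, 0.5, 1}; SVM C {0.1, 1, 10}; tree depth {4, 8, ∞}; forest
depth {8, ∞}; XGBoost depth {3, 6}; k {3, 5, 11}; AdaBoost 50 estimators)
and are config-overridable. The 80/20 split is stratified — a documented
strengthening of a plain random split that guarantees both classes in the
test set. Evaluation reports macro recall/precision/F1 with percentile
bootstrap CIs (B = 1000 resamples of the test set over fixed predictions;
models are not refit) and trapezoid AUC. Selection maximizes macro recall,
ties broken by macro F1 and then a fixed family order; decisions use the
0.5 threshold with the boundary classified positive.

## Longitudinal summaries

`percentage = 100 · n_PD / n_posts` per participant and timeframe
(overall / pre / post), normalizing engagement by post volume rather than
account age. Conventions: the diagnosis day itself counts as
post-diagnosis; year-only diagnosis dates are coerced to July 1 (logged);
a timeframe with zero posts has an undefined percentage (NaN, never 0),
and such participants drop out of that cell of the cohort table and of
paired tests — so pre/post Ns can differ from overall Ns, as with
caregivers lacking diagnosis dates who contribute to "overall" only.
Keyword-frequency tables per group and phase use the model cleaning
pipeline with lexicographic tie-breaks; rendering word-cloud images is
deliberately out of scope.

## Statistics

All p-values two-sided, no multiple-testing correction.

* **Welch's t** from summary statistics, Welch–Satterthwaite df, Cohen's d
  with the (n−1)-weighted pooled SD.
* **Fisher's exact**: sum of hypergeometric probabilities ≤ the observed
  table's.
* **Wilcoxon signed-rank**: missing and zero-difference pairs dropped;
  midranks; W = smaller of the positive/negative rank sums (the convention
  consistent with a printed significant W of 105 at n = 27, where the
  maximum possible sum is 378); exact sign-flip enumeration for n ≤ 12,
  otherwise normal approximation with tie and continuity corrections.
* **Mann–Whitney U**: U = smaller of the two statistics; exact enumeration
  of group assignments when n₁·n₂ ≤ 100 (midranks handled), otherwise the
  tie- and continuity-corrected normal approximation.
* **Shapiro–Wilk** for 3 ≤ n ≤ 5000; a constant vector is an error.
* **Cohen's κ** with marginal-product expected agreement; κ defined as 1
  when both raters are constant and identical.

The exact-path results are verified against independent enumeration oracles
in the suite, and each test's null rejection rate is calibrated to
α = 0.05 ± 0.02 over 1000 simulations.

## Synthetic cohorts

The generator's defaults are the study conditions: 30 PD / 3 ET / 1 AP /
12 CG participants; account spans 14 ± 3 years; 4018 ± 5570 posts per
participant (lognormal, moment-matched); diagnosis 5 ± 6 years after
account creation with 90% of accounts predating diagnosis; caregiver
diagnosis dates present for 75%; phase-specific PD-content rates per group
(PD 1.7% pre / 4.0% post; ET 1.0/0.7; AP 9.3/4.9; CG 1.1/1.0); 45% of
PD-related posts exercise-themed; 15% of irrelevant posts carrying
ambiguous dictionary terms; duplicate-injection rates of 8% exact / 4%
near / 3% reshare; 5% memory posts; 2% mojibake; 20% cross-file overlap.

Texts are template renderings: PD templates embed symptom/medication/
advocacy vocabulary, exercise templates embed only exercise-tagged terms,
ambiguous templates embed dictionary terms in clearly non-PD contexts, and
plain templates carry no dictionary terms. Same-text events are spaced
≥ 180 s apart at generation, so the ground truth equals exactly what the
deduplicator must recover; injected exact/near copies carry no label
because they must disappear, while reshares are labeled retained events.
The labeled-corpus generator mirrors the annotated-set construction: 6750
posts by 14 PwPD and 5 caregivers, 35.6% PD-related, every post
dictionary-bearing (negatives drawn from ambiguous templates only, since
annotation was applied to dictionary-flagged posts).

**What passing tests show — and don't.** Template language is far more
separable than real posts: the classifier reaches near-perfect recall on
synthetic corpora, so harness results validate the machinery (feature
fitting without leakage, seeded CV/tuning, selection, bootstrap, threshold
semantics), not real-world accuracy. Per-post Bernoulli rates mean
participants share one rate per phase; real cohorts are heavily
overdispersed (SDs of the printed percentages exceed their means), so
cohort-level SDs here are much smaller than real ones. Topic drift,
code-switching, images, reactions and follower dynamics are not modeled.

## Problem sizes and determinism

Everything is seeded: the generator from `SynthConfig.seed`, splits/CV/
bootstrap from explicit seeds, and a rerun of the same configuration is
byte-identical. The default test suite and the acceptance script use
scaled problem sizes chosen as a deliberate compromise: the labeled-corpus
harness runs at the full 6750 posts; the parameter-recovery study uses 27
participants × 1600 posts (≥ 500 per phase) × 100 replicate cohorts; the
end-to-end cohort run in the acceptance script uses 1200 ± 1000 posts per
participant (percentages are volume-normalized, so means are unaffected by
this scaling); oracle and calibration suites use 1000 replicates.

## Known limitations

* The bundled dictionary is a ~190-term reconstruction, not the full
  >1000-term instrument; recall on real text depends on the dictionary
  supplied.
* The noun lemmatizer and the bundled stop-word list are compact fixed
  resources; they are versioned for reproducibility, not completeness.
* Memory posts are recognized only by the in-text relative-time pattern;
  exports that flag memories out-of-band are not distinguished.
* Caregivers without diagnosis dates cannot enter pre/post comparisons at
  all; no imputation is attempted.
* The encoding repair is heuristic: text that legitimately looks like
  double-encoded UTF-8 would be "repaired".
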