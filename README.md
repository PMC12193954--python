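# pdsocial

Mining longitudinal personal social-media archives for Parkinson's-disease
(PD) discourse.

People with PD often carry a decade or more of Facebook history — everyday
posts written both before and after their diagnosis. Because the prodromal
phase of PD is hard to study prospectively, that archive is a rare
retrospective window: did health-related language surface before the
clinical diagnosis, and how does PD-related posting change after it?
`pdsocial` implements a reusable, tested pipeline for exactly this analysis
on donated Facebook-export archives from a movement-disorder cohort —
people with PD, essential tremor (ET), atypical parkinsonism (AP), and
caregivers (CG). Real donated archives cannot be redistributed, so the
package ships a synthetic-cohort generator with known ground truth that
emulates every awkward property of real exports (overlapping JSON files,
near-duplicate entries, reshared "memories", broken encodings), making the
whole pipeline verifiable end to end.

## The method

1. **Ingest.** Harvest every timestamped author text from the JSON files of
   an export. Repair UTF-8-read-as-Latin-1 mojibake, strip relative
   "N years ago" stamps from reshared memories, then deduplicate: entries
   with identical timestamp and text collapse, and a repeated text is kept
   only if ≥ 180 s have elapsed since the most recently retained occurrence
   — deliberate reshares survive, export artifacts do not.
2. **Lexicon.** Flag candidate posts with an over-inclusive PD term
   dictionary (symptoms, medications, advocacy, exercise vocabulary),
   matched on stopword-filtered tokens both raw and Porter-stemmed
   ("trembling" → "trembl"). Over-inclusiveness is intentional: "I fell in
   love" hits just like "I fell down".
3. **Classify.** Separate genuinely PD-related posts from incidental
   matches. Features: TF-IDF over noun-default lemma 1–3-grams (document
   frequency ≥ 2), TF-IDF over word-cluster unigrams, normalized age at
   posting, one-hot gender/diagnosis-group — all fitted on training data
   only. Seven model families (KNN, SVM, random forest, AdaBoost,
   multinomial Naive Bayes, decision tree, XGBoost) plus a soft-voting
   ensemble are tuned by grid search with stratified 5-fold CV optimizing
   **macro-averaged recall**; the best-recall family is selected and applied
   at the fixed 0.5 threshold.
4. **Flag.** Final verdict per post:
   `pd_related = (dict_hit AND classifier positive) OR "parkinson" OR \bPD\b`,
   where the explicit-mention rules are applied to raw text ("PD" only as a
   standalone case-sensitive word, so "updated" never matches) and always
   dominate the classifier.
5. **Quantify.** Normalize by post volume, not account age:
   `percentage = 100 · (PD-related posts) / (total posts)`, computed
   overall, pre-diagnosis and post-diagnosis, with a sensitivity variant
   excluding posts whose PD-relatedness rests only on exercise vocabulary.
6. **Test.** Welch's *t* (with pooled-SD Cohen's *d*) and Fisher's exact
   test for cohort comparisons; Wilcoxon signed-rank for within-subject
   pre/post change (identical pairs dropped, W = smaller rank sum);
   Mann–Whitney U between groups (U = smaller statistic); Shapiro–Wilk for
   normality; Cohen's κ for annotator agreement.

## Worked example

Simulate 27 people with PD who post PD-related content at 1.7% of posts
before diagnosis and 4.0% after, then recover those rates and test the
change (`python examples/05_longitudinal_stats.py`):

```
pre-diagnosis  PD-related %: 1.63 +/- 0.58 (configured 1.7)
post-diagnosis PD-related %: 3.83 +/- 0.58 (configured 4.0)
Wilcoxon signed-rank: W = 0.0, p = 5.9e-06 (n = 27 usable pairs)
```

The per-participant percentages recover the configured generation rates,
and the signed-rank test (W = smaller rank sum; here every participant
increased, so W = 0) detects the post-diagnosis rise.

The other scripts in `examples/` walk the remaining stages one at a time:
archive simulation, ingestion/deduplication (recovered post ids match the
generator's ground truth exactly), dictionary and explicit-mention rules,
and classifier training with bootstrap CIs. The `pdsocial` command exposes
the same pipeline from the shell (`pdsocial simulate`, `pdsocial run
--config config.yaml`, ...).

## Layout

- `src/pdsocial/` — `synth` (cohort generator), `ingest`, `lexicon`,
  `features`, `classify`, `flagging`, `longitudinal`, `stats`, `pipeline`,
  `cli`, `textproc`, plus bundled data (`data/pd_terms.tsv` — a
  reconstructed starter dictionary, `data/clusters.tsv` — a synthetic
  token→cluster fixture, `data/stopwords.txt`).
- `docs/methods.md` — model, conventions, parameter defaults, limitations.
- `examples/` — one narrative script per capability.
- `tests/` — unit, property and acceptance suites.
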