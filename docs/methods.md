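# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
study conditions do and do not establish.

## Transcript model and preprocessing regimes

A transcript is an ordered list of turns; provider turns are the lines
wrapped in `#`. Patient turns are sequences of clauses (`|...|`), minor
utterances (`<...>`), disfluency spans (`{...}`) and bare sentence
punctuation. The parser trusts the annotation: it does not verify that a
clause contains a conjugated verb, and it does not attempt clause detection
on unannotated text. Disfluency spans carry an explicit category tag
(`fp`, `rep`, `fs`, `ac`, `ai`, `ab`, `tc`); untagged spans are resolved
against a configurable filled-pause lexicon (default `euh, heu, hum, ben,
bah`) and otherwise default to `abandonment` with a logged warning, so real
annotated files with bare `{...}` remain loadable. A span counts as one
disfluency element regardless of its word count.

Three preprocessing regimes feed the feature levels:

* **lexical** — patient speech, disfluency removed, lemmatized by the
  pluggable annotator (type–token ratio, lexical density, pronoun measures);
* **syntactic** — patient speech, disfluency removed, surface forms
  (words per clause, short answers, truncated clauses);
* **semantic** — both speakers, disfluency *kept*, stop words removed, no
  lemmatization (the coherence features);
* disfluency proportions use the verbatim patient word count (spans
  included) as denominator — the verbatim flow is what disfluency rates
  describe. The truncated-clause percentage uses total patient clauses
  (full clauses plus truncated-clause spans) as its base, the natural
  denominator for a clause-level event.

Tokenization is deterministic and language-neutral: whitespace split,
terminal punctuation stripped, lowercased. Sentence boundaries are `.?!` and
ellipsis, plus line end. Undefined ratios (no subject pronoun, no
first-person object pronoun, no clause) are NaN, never silently zero;
imputation happens only inside model-stage training partitions.

## Latent semantic space

The space is a rank-`k` truncated SVD of the weighted term–document matrix,
fitted on the pooled sentence segments of all transcripts in a run (both
speakers). Pooling gives a stable shared space at the ~70-document scale of
a typical cohort; the fit-corpus digest is stored so feature tables are
traceable to the space that produced them.

* **Weighting**: log-entropy by default (local `log(1+tf)`, global
  `1 − H(term)/log n`), with raw counts and tf-idf selectable.
* **k**: default `min(100, n_documents − 1, |vocab| − 1)`, clipped to the
  rank bound with a warning. For the synthetic language the study uses
  `k = 8`, one dimension per latent topic — with topic membership the only
  semantic structure in the generated text, a near-full-rank space leaves no
  room for latent smoothing and similarity degenerates toward exact lexical
  co-occurrence.
* **Embedding**: a segment embeds as the sum of its terms' rows of `U·Σ`;
  cosine similarity between consecutive segments forms the coherence series.
  Segments embedding to the zero vector (all tokens out-of-vocabulary or
  stopped) are skipped with a log message rather than scored 0 — a zero
  vector has no direction, and scoring it would fabricate incoherence.
* **Determinism**: dense `numpy.linalg.svd` (the corpora here are small)
  plus a sign convention — the largest-magnitude entry of each right
  singular vector is made positive — so refits are bit-stable across runs
  and backends.

Per transcript and mode the series is summarized by median, minimum,
IQR (linear-interpolation quartiles) and the percentage of values beyond
the Tukey fences at 1.5·IQR on each side.

## Synthetic cohort generator

The generator emulates two-speaker consultations in an artificial
pseudo-language so that every statistic keeps its definition without a
language-specific tagger: designated pronoun tokens (`je`, `me`/`moi`,
`tu`/`il`), a function-word pool, filled-pause tokens, discourse particles,
and per-topic content vocabularies.

**Topic geometry.** Topics lie on a line; each topic's vocabulary is a
sliding window over a global word list (adjacent windows overlap by 65 %),
plus a small globally shared set drawn at a fixed rate (12.5 % of content
draws) and Zipf-weighted window words (`s = 1`). Conversational *drift*
moves to a neighboring topic, so drifted pairs stay fairly similar;
a *derailment* jumps to a topic at distance ≥ 3 — beyond any window
overlap — producing a near-orthogonal pair. Two structural choices matter
and were arrived at by construction, not tuning-to-test: shared words must
not occupy the top frequency ranks (otherwise they dominate every segment
and glue all topics together), and discourse particles, pronouns and minor
answers belong on the stop-word list (under log-entropy weighting such
ubiquitous words carry near-zero weight, so minor-utterance segments would
otherwise embed as pure noise and pin every transcript's coherence minimum
at a common floor).

**Dialogue process.** The provider pursues their own slowly drifting agenda
(persistence ρ per turn) and asks six-word questions from it; the patient
answers from the agenda topic with 1–3 clauses, drifting per sentence with
probability 1 − ρ, and with probability π a derailment strikes mid-turn:
from a random clause onward the answer continues on a distant topic. Because
the provider does not follow the derailment, a derailed answer breaks
question–answer (intersubjective) coherence as well as sentence-to-sentence
coherence. Minor-utterance ("short answer") turns occur with a configured
probability.

**Rates.** Pronoun rates are per disfluency-stripped patient word, matching
the lexical features' denominator; disfluency-span insertion rates are per
verbatim patient word (the fluency features' denominator), with the
insertion probability scaled by 1/(1 − Σ rates·span lengths) so the
configured value is recovered despite spans adding words. Recovery of all
configured rates within three binomial standard errors is part of the test
suite.

**Defaults.** The default cohort is 15 NAR / 45 AR / 8 FEP. All groups share
ρ = 0.88 and differ only where the study injects contrasts: derailment
π = 0.002 / 0.008 / 0.12 (NAR/AR/FEP) — rare but deep, so FEP's deficit
appears in the coherence *minimum* while medians stay close; first-person
subject rate 0.04 / 0.085 / 0.05 per word; filled-pause rate
0.028 / 0.012 / 0.022. Interviews average 80 turns (~700 patient words) —
long enough that per-transcript binomial noise does not swamp the rate
deltas, while staying cheap to simulate. Randomness derives from one root
seed; transcript *i* uses `numpy.random.default_rng([root_seed, i])`, so
cohorts are reproducible and any transcript independently regenerable.

**What the generator does not emulate.** Linguistic realism of any kind:
morphology, syntax beyond clause segmentation, pragmatics, clinician
interviewing style, acoustic features, or the heavy-tailed word-frequency
and topic structure of real French interviews. Passing tests show the
*pipeline* recovers structure it is pointed at; they say nothing about
effect sizes in real clinical speech.

## Statistical screen

Kruskal–Wallis uses scipy's tie-corrected H with a chi-square reference
(df = groups − 1); the rank effect size is ε² = H/(n − 1), the definition
that reproduces, to four decimals, every published effect size recomputable
from its H and n. When all pooled observations are identical the tie
correction degenerates; the screen returns H = 0, p = 1 with a warning
rather than an error. Dunn post-hocs use pooled tie-corrected ranks with the
variance term N(N+1)/12 − Σ(t³−t)/(12(N−1)) and Bonferroni factor 3, capped
at 1. The normality check is a one-sample Kolmogorov–Smirnov test of the
*raw* values against the standard normal — for non-negative-valued features
this yields D ≥ 0.5, the regime the screen reports; a Lilliefors-style
standardized variant is available behind a flag. Levene is mean-centered.
No correction is applied across the feature screen (post-hoc adjustment
lives inside Dunn); Benjamini–Hochberg q-values are available as an
off-by-default column.

## Classification pipeline

A single stratified 30 % hold-out produces the final report; 3-fold
stratified cross-validation with in-fold SMOTE runs inside the training side
for hyperparameter tuning and feature-count scanning. The two protocol knobs
(`test_fraction`, `k_folds`) are independent and configurable.

* **SMOTE** balances every class to the majority count; each synthetic
  sample is `x_i + u·(x_nn − x_i)` with `u ~ U[0,1]` between a minority
  sample and one of its k nearest minority neighbors (k auto-clipped to
  minority − 1 with a logged warning; a singleton class is an error).
  Oversampling and imputation statistics are always fitted on training
  partitions only.
* **Tuning** is Gaussian-process Bayesian optimization (Matern 5/2 kernel,
  expected improvement over a random candidate pool) of mean CV accuracy
  over max_depth ∈ [2,6], learning_rate ∈ [0.03,0.3] (log), n_estimators ∈
  [50,300], subsample ∈ [0.6,1], colsample_bytree ∈ [0.5,1],
  min_child_weight ∈ [1,5]. These ranges and the iteration budget are this
  package's declared defaults, configurable in `ModelConfig`.
* **Importances** are mean absolute SHAP values from XGBoost's native
  TreeSHAP, averaged over samples and classes, computed from a model trained
  on the original (non-oversampled) training data; the final model trains on
  the SMOTE-balanced selected features.
* **Selection** offers the fixed-threshold rule (importance > 0.3, falling
  back to top-1 with a warning) and a scan that evaluates CV accuracy for
  the top-m features, m = 1..10, keeping the best (ties to the smaller m).
  The scan is the study default on synthetic cohorts: the mean-|SHAP| scale
  depends on the data, so a fixed absolute cutoff does not transfer across
  corpora, whereas the scan re-derives the cutoff each run.
* **Report**: per-class precision, recall (= sensitivity), one-vs-rest
  specificity, F1 and Fβ (β = 2 by default; both reported), supports,
  accuracy, macro (NaN-skipping) and support-weighted averages, macro
  one-vs-rest ROC–AUC on predicted probabilities, and a percentile bootstrap
  95 % CI for accuracy resampling within each true class (1000 replicates by
  default). Signed per-sample SHAP attributions per class are tabulated, and
  a direction summary gives, per (class, feature), the sign of the mean
  attribution among samples above the feature median.

**Null behaviour.** With identical group profiles the pipeline scores well
*below* the majority-class rate (~0.40 vs 0.67 on the default cohort
shape): balanced training deliberately removes the majority prior, so a
no-signal classifier spreads predictions across classes instead of voting
majority. The calibration tests therefore assert the one-sided property —
no spurious signal above the majority rate — and the informative-cohort
tests require accuracy above that band.

## Numerical and degenerate-input conventions

* All-tied Kruskal–Wallis → H = 0, p = 1, warning.
* Zero-vector segments → skipped and logged, never scored.
* k exceeding the SVD rank bound → clipped with a warning.
* Missing feature values → NaN throughout; median imputation fitted on
  training partitions only at the model stage.
* SHAP additivity holds to float32 precision (residuals ~1e-6–1e-5);
  tests assert 1e-4.
* All estimator stages are deterministic given their seeds; XGBoost runs
  single-threaded with `tree_method="hist"`.

## Known limitations

* The annotator lexicon ships no real morphology; for real French
  transcripts a POS tagger/lemmatizer must be plugged in via
  `AnnotatorLexicon`'s resolver callables.
* The coherence minimum is an extreme statistic: its sampling variance
  grows with series length differences, and cross-transcript comparability
  assumes similar interview lengths.
* With eight FEP interviews in the default cohort, hold-out FEP supports
  are 2–3; per-class FEP metrics are correspondingly unstable, and the
  bootstrap CI for accuracy is wide.
* The three coherence minima (turn, sentence, patient-sentence) respond to
  the same derailment mechanism in the generator and are largely
  exchangeable; which one tops a given screen is sampling noise.
* Dunn–Bonferroni with very small groups is conservative by construction:
  at n = 5 per group the adjacent-pair z statistic cannot exceed ~1.77
  regardless of separation.
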