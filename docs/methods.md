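# Methods

## Model and procedure

`toonet` treats tissue-of-origin prediction as supervised multi-class
classification of bulk expression profiles. The pipeline assumes
non-negative expression values per sample and gene, a single class label per
sample, and that class-discriminative information is carried by genes
*upregulated* in their class — the selection statistic is the signed Pearson
correlation between a gene's expression vector and the one-vs-rest 0/1 class
indicator, sorted in decreasing order. Downregulation-based markers are
deliberately not captured by the default (an absolute-value ranking would
change the contract and is not provided as a default; the ranking function
returns the full signed list, from which callers can implement variants).

Per-class top-N lists are merged in class order, first occurrence wins, and
every contributing class is recorded per gene (`GenePanel.provenance`). With
disjoint markers the panel size is exactly C·N; overlap shrinks it — both
are legitimate outcomes and the panel reports which.

The classifier is a scikit-learn `MLPClassifier` with one hidden layer of 50
rectifier units and a softmax output per class, L2 penalty 1e-4, behind a
wrapper that enforces the exact training panel (gene identity *and* order)
at prediction time. The baseline is multinomial `LogisticRegression` with
C = 10,000. For two-class problems scikit-learn parametrizes the output as a
single logistic unit; this is mathematically equivalent to a two-unit
softmax and is left as is.

Cross-validation is the leakage-free protocol: per repeat, a stratified
k-fold partition; per fold, gene ranking and panel construction from the
k−1 training folds only, model training on those folds restricted to that
panel, prediction of the held-out fold. Each sample is predicted exactly
once per repeat. Two accuracy summaries are exposed because they answer
slightly different questions: `mean_accuracy` (mean of repeat-level
merged-prediction accuracies) and `pooled_accuracy` (trace/total of the
confusion matrix pooled over all repeats); for balanced repeats they
coincide to Monte-Carlo error.

## Parameters that matter

| parameter | default | meaning / why |
|---|---|---|
| `PreprocessConfig.scale` | 1.0 | row-sum target after library-size division; 1.0 gives proportions, 1e6 CPM-style values. Proportions are the literal reading of "divide by the per-sample sum". |
| `PreprocessConfig.zero_replacement_factor` | 0.1 | zeros become (global positive minimum × 0.1) before log₂, keeping the replacement below every observed positive value. "Global" is the whole-matrix minimum over strictly positive entries, not per-gene. |
| `n_per_class` (N) | 10 | per-class gene number; 15 classes × 10 = the 150-gene reference panel. |
| `MLPConfig.hidden_units` | 50 | hidden-layer width of the reference network. |
| `MLPConfig.l2_penalty` | 1e-4 | L2 regularization of the reference network. |
| `MLPConfig.learning_rate_init` | 0.01 | adam's initial step. Inputs are unstandardized by design (no normalization after feature selection), so proportion-scale features (~1e-4) produce tiny gradients; at the stock 1e-3 step the optimizer stalls at the class-prior solution and small classes are never predicted. One order larger restores convergence at every input scale used here. |
| `LogisticConfig.inverse_reg_C` | 10000 | near-unregularized multinomial baseline. |
| `CVConfig.k`, `repeats` | 10, 10 | the repeated 10-fold protocol. Stratified folds are the default so small classes appear in every training portion; plain random folds (`stratified=False`) are available. |

## Synthetic cohorts

`simulate` draws per-gene baseline log-means from
Normal(`background_log_mean`=1, `background_log_sd`=1), per-sample
expression log-normally around them (`noise_log_sd`=0.7), multiplies each
class's disjoint marker genes' means by `marker_effect` (8×) within that
class only, and scales each sample by a log-normal library factor
(CV 0.2, mean 1). Defaults: 15 classes named as the reference cohort's
merged tokens, class sizes proportional to that cohort scaled to 750 samples
(14–107 per class), 2,000 genes, 10 markers per class. A negative-binomial
count mode (`count_mode=True`, dispersion 0.3) generates integer counts with
the library factor inside the NB mean.

`simulate_metastatic` reuses the primary cohort's gene baselines and marker
assignments but raises markers by `marker_effect ** attenuation`
(default attenuation 0.5): the attenuation acts on the log-fold-change, so
attenuation → 0 removes the class signal entirely (fold-change → 1) and
accuracy degrades toward chance, while attenuation 1 reproduces the primary
signal. Attenuating the raw fold-change multiplicatively would instead turn
markers into *down*-regulated features below 1/effect, which is a different
biological statement. The default class composition mirrors the reference
20-sample metastatic set (7/2/1/2/8 across five classes) when those classes
exist.

What the generator does **not** emulate: gene–gene correlation structure,
batch effects, tumor purity, platform-specific zero inflation. Passing tests
therefore demonstrate that the pipeline recovers planted univariate
class-mean structure under library-size noise and class imbalance — not
performance on real TCGA data.

## Numerical choices

- Pearson correlation of a zero-variance vector is undefined; both the
  scalar and the vectorized path return 0 with a warning, which keeps
  constant genes out of the top ranks.
- Ranking ties in r break by ascending gene id, making panels deterministic.
- Exact prediction-probability ties resolve to the earlier class in the
  model's class order.
- Precision of a class never predicted is defined as 0 (with a warning)
  rather than NaN, so macro averages stay total.
- The permuted-label chance band used in testing is
  1/C ± 3·sqrt((1/C)(1−1/C)/n): the binomial Monte-Carlo error of an
  accuracy estimated from n held-out predictions under the null. The
  repeat-level spread is not used as the error estimate because with few
  repeats it is itself too noisy. This 1/C null is only meaningful for
  balanced cohorts; for unequal class sizes the correct null is the
  class-prior matching rate (e.g. 0.143 for the default cohort, whose
  largest class holds 14.3% of samples), and the chance-level test is
  therefore run on a balanced 15 × 50 cohort.
- All randomness flows from explicit integer seeds; repeat-level partition
  and model seeds are drawn from one `numpy` generator seeded by
  `CVConfig.seed`, so a CV run is a pure function of (data, config).

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run at desk scale, chosen so the
full suite completes in a couple of minutes: the headline synthetic check
uses 15 classes × 50 samples × 2,000 genes with 2 CV repeats; the
feature-number sweep uses 8 classes × 40 samples × 800 genes with 5 markers
per class at 3× effect and the logistic model. The sweep uses the logistic
baseline deliberately: it is convex and deterministic, so the
accuracy-vs-N curve isolates the information content of the panel from
neural-network optimization noise. The generator accepts full-cohort sizes
(e.g. 20,501 genes) for stress runs.

## Known limitations

- Signed-correlation selection misses markers defined by absence of
  expression.
- The published per-class cohort counts sum to 7,397 while the printed total
  is 7,460; the bundled cohort table reproduces the printed numbers as-is
  and percentage arithmetic uses the printed totals as denominators.
- Model persistence uses pickle for the estimator weights; bundles are not
  portable across incompatible scikit-learn versions (the JSON metadata is).
- No probability calibration, ROC analysis, or significance testing between
  the two models is provided.
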