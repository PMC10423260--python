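# Methods

## Problem and pipeline

The package estimates the apnea–hypopnea index (AHI, events per hour of
sleep) from a single overnight SpO₂ channel sampled at 1 Hz, plus a 30-s
epoch hypnogram and two demographic covariates (age, sex). The pipeline
mirrors how such a study is run end to end: a synthetic cohort with exact
ground truth, signal cleaning and exclusion, a rule-based desaturation
detector and engineered biomarkers as benchmarks, a dual-branch deep
regressor, occlusion-based explainability, and agreement statistics.

## Synthetic oximetry generator

Real overnight oximetry cohorts are access-restricted, so the generator is a
first-class component: it defines the study conditions under which every
claim in the test suite holds.

Per record: a personal baseline saturation is drawn from
N(96.5, 0.8) %. A sleep/wake hypnogram is built from a target sleep
efficiency (default 0.85); the implied wake budget is spent ~60% as initial
sleep latency, ~15% as a terminal awakening, and the remainder as scattered
single-epoch arousals, which keeps the intra-sleep wake fraction small — a
deliberate choice so that the TST̂ estimate (onset-to-offset span) stays
within a few percent of true sleep time. The target AHI is lognormal
(μ=2.3, σ=0.9 on the log scale; median ≈10 events/h), truncated at 60 and
with a 5% point mass at zero, roughly matching the right-skewed severity
mix of community sleep cohorts. The integer event count is
round(AHI × sleep-hours) and the recorded `true_ahi` is recomputed from the
events actually planted, so ground truth is exact by construction.

Desaturations are trapezoids — linear descent over the first third of the
duration, a plateau at (baseline − depth), linear recovery — with depth
truncated-normal (mean 5.5%, sd 1.5, min 3, max 12) and duration
truncated-normal (mean 38 s, sd 12, range 10–120 s), consistent with severe
desaturations typically lasting 30–45 s. With probability 0.25 an event
seeds a burst of 3–8 back-to-back events with 20–60-s recovery gaps,
emulating the event clustering characteristic of severe apnea. Bursts are
assigned to sleep segments by free capacity (largest first) and spread
within a segment by Dirichlet-distributed gaps, which conditions a
Poisson-like process on the drawn count; if an extreme draw cannot be
placed into fragmented sleep, events are shed until it fits and the ground
truth reflects what was planted. Gaussian sensor noise (default sd 0.5%)
is added everywhere; the physiological signal is clipped to [50, 100]%, and
1–5-sample artifacts at 20–45% are injected afterwards (about 1/hour) to
exercise the delta filter.

What the generator does **not** emulate: baseline drift and position-
dependent baselines, Cheyne–Stokes or COPD-type sustained hypoxemia,
autocorrelated (pink) sensor noise, oximeter averaging-window distortion,
and desaturations without a recovery to baseline. Tests passing on this
simulator therefore demonstrate the internal correctness of the pipeline
and the learnability of the dip-counting signal, not clinical performance
on real cohorts.

## Preprocessing

Stages in order: (1) resampling to 1 Hz by 1-s block means; (2) a delta
filter marking samples invalid when outside [50, 100]% or when changing
faster than 4 percentage points per second relative to the previous valid
sample — the classic motion-artifact thresholds, both configurable;
(3) invalid runs of 1–2 samples are linearly interpolated and revalidated,
longer runs are filled by carry-forward but stay masked (interpolation is
trusted only where it cannot invent structure); a run of exactly 3 is
treated as long. (4) Sleep onset is the start of the first run of ≥10
consecutive sleep-labeled epochs (5 min), offset the end of the last such
run; TST̂ is the span between them, and any non-wake stage counts as sleep.
(5) Records are excluded for technical faults (empty or fully
non-physiological signal), TST̂ < 4 h, or age < 18 y, with one reason
recorded in that precedence; the boundaries TST̂ = 4.0 h and age = 18 are
retained. (6) The signal is cropped to [onset, offset] and fitted into a
fixed 7-h frame (25200 samples): shorter spans are right-padded with the
per-record mean SpO₂ (masked invalid), longer spans keep their first 7 h.
The padding value equals the occlusion baseline used by the explainer,
making padding neutral to the model by construction.

## Desaturation detection and ODI

The detector's local baseline at time t is the maximum valid SpO₂ over the
preceding 100 s. An event opens when the signal falls ≥3% (configurable)
below that baseline, closes on recovery to within 1% of the baseline in
force at opening or at 120 s, and is then extended along its monotone
descent/recovery flanks so the reported extent covers the full dip rather
than only the ≥3%-deep core. Events shorter than 10 s, or mostly inside
invalid/padding samples, are discarded. ODI = events / TST̂. The specific
baseline and recovery rules follow the common published operationalisation;
nothing downstream depends on this exact variant, only on there being *a*
reasonable rule-based detector to benchmark against.

## Engineered biomarkers (OBM)

About 25 named features in five families are computed from valid samples
only (hence invariant to padding): general statistics (mean, sd, median,
5th percentile, zero-crossings about the mean, delta index = mean absolute
difference of consecutive 12-s block means); complexity (ApEn with m=1,
r=0.25·sd; DFA exponent over dyadic box sizes 10…n/4); periodicity (PRSA
capacity with ±10-s windows at decreasing anchors; Welch band powers, with
0.014–0.033 Hz as the apnea-cycling band); desaturation morphology (count,
rate, mean/max depth, mean length, mean area, mean slope); hypoxic burden
(seconds and integrated area below 90%). Age and sex are appended. ApEn is
O(n²), so record-level extraction averages it over 10-min windows; the
standalone function is exact and is validated to 1e-8 against a literal
brute-force implementation. This is a representative subset of the
published oximetry-biomarker families — category coverage, not cardinality,
is what the baseline contrast requires — and it makes no claim of bit
parity with any toolbox.

mRMR selection is the Pearson variant: greedily add the feature maximising
|corr(f, target)| − mean |corr(f, selected)|, constant features scoring
zero, ties broken by column order for determinism.

## Baseline models

Two benchmarks: ODI + age + sex, and the OBM vector. The regressor backend
is sklearn's gradient-boosted trees (deterministic at this scale; a ridge
backend exists for degenerate problems). The OBM fit runs mRMR inside each
of 5 shuffled folds, scores a small documented hyperparameter grid
(150 trees/depth 2/lr 0.1 vs 300 trees/depth 3/lr 0.05) by out-of-fold MSE,
and refits on all rows; a full Bayesian search is out of scope at desk
scale but the grid is pluggable. Predictions are clipped at zero.

## Dual-branch deep regressor

The model is implemented on the package's own reverse-mode autodiff engine
(`autodiff.py`: tape of numpy tensors with conv1d/maxpool/LSTM/batch-norm
building blocks and Adam), since the architecture itself is the point of
the package. Input scaling is fixed: (SpO₂ − 96)/4.

* **CNN branch** — the 25200-sample frame is cut into overlapping windows
  (defaults: 1200 s, 50% overlap); each window passes through n_B=3 blocks
  of [n_L × (conv k=3 → batch-norm → LeakyReLU)] → maxpool, with additive
  skip connections (1×1 projection when widths change). Per-window features
  are concatenated along time and processed by n_DB=3 dilated conv blocks
  (kernel 7; dilation 2·2^i, doubling per block) with LeakyReLU; global
  average pooling yields V_CNN of width n_C.
* **CRNN branch** — two conv/batch-norm/LeakyReLU/maxpool blocks reduce the
  temporal resolution (stride 2 each by default), then two stacked
  bidirectional LSTMs (n_LSTM=64 units); the concatenated final hidden
  states of both directions form V_CRNN of width 2·n_LSTM.
* **Metadata branch** — (z-scored age, sex) through one fully connected
  layer with LeakyReLU, width N_META=8.
* **Head** — V_final = [V_CNN, V_CRNN, V_META] through n_classifier=2
  blocks of (linear width-halving → batch-norm → LeakyReLU → dropout 0.3)
  and a final linear unit. Two auxiliary linear regressors read V_CNN and
  V_CRNN directly; they share gradients with their branch but are detached
  from the main head.

The published architecture was tuned by a hyperparameter search whose
values were not reported; these defaults were chosen for desk-scale
trainability and no particular parameter count is targeted.

## Training

Loss: L = L_agg + λ_CNN·L_CNN + λ_CRNN·L_CRNN + l2·Σw², each term an MSE
against the target; λ starts at 1 and is multiplied by 0.8 every 4 epochs
(closed form 0.8^⌊e/4⌋ — multiplying iteratively from the current value is
identical). Optimiser: Adam at lr 0.005. Targets are internally z-scored by
training-split statistics and predictions un-scaled and clipped at 0.
Splits: 90/10 cohort-level train/test where an experiment needs a held-out
set, and 70/30 train/validation inside `train_model`; the checkpoint with
the lowest validation loss is kept. Augmentation per batch: a moving-window
shift (the real span is re-placed at a uniform offset inside the 7-h frame;
label-preserving by construction) and Gaussian jitter (σ=0.5%) over valid
samples, clipped back to [50, 100]%. l2 = 1e-5 and batch size 16 are
desk-scale defaults. Non-finite losses abort with a diagnostic rather than
silently continuing.

### Reduced configuration

`reduced_config()` is the documented small model used by the benchmark
study and the tests: windows of 3600 s without overlap, channels (8, 16,
16) with pool stride 4, two dilated blocks of 16 filters (kernel 5), CRNN
pooling strides (16, 8) so the BiLSTMs see ~196 steps of 8 channels with 16
units, N_META=4, two classifier blocks, dropout 0.2 — about 16k parameters.
The benchmark study trains it for 12 epochs on 250 records (4.5–6.5-h
records), which takes ~4 minutes on one CPU and reaches held-out ICC ≈ 0.95
on the simulator. Because training at this scale is stochastic, the study
retries with a derived seed (at most twice) if the held-out ICC misses
0.70.

## Explainability

Feature occlusion: each 120-s region (stride 60 s) is replaced by the mean
of the record's valid samples and the importance score is
f(x) − f(x_occluded), in AHI units. The sign is kept — for a regression
target a negative score (occlusion *raises* the prediction) is
informative. Traces carry an optional min–max normalised column; a constant
trace normalises to zero. Padding regions score exactly zero because they
already equal the baseline.

## Agreement statistics

ICC is the two-way random-effects, single-rater, absolute-agreement form
computed from the ANOVA mean squares (instances, observers, residual) with
O=2 observers; systematic offsets between truth and estimate are penalised
through the observer mean square. It is validated to 1e-10 against an
independent OLS-ANOVA computation. Severity bins are half-open: non (<5),
mild [5, 15), moderate [15, 30), severe (≥30). Macro sensitivity and PPV
average the per-class ratios over the four bins, with an empty class
contributing 0 (not NaN) and a warning; macro-F1 is their harmonic mean.
Bland–Altman reports the median difference with its 5th/95th percentiles
and the mean ± 1.96·sd limits. Bootstrap CIs resample 80% of the pairs with
replacement 1000 times and report point ± 1.96·se_boot (the two-sided 95%
normal critical value); degenerate resamples are redrawn with a cap and
counted. Model comparisons use the Wilcoxon rank-sum test; feature
screening across severity groups uses Kruskal–Wallis (α = 0.05 in both
cases, with all-tied data returning p = 1 and a warning).

## Numerical and design choices

* The autodiff engine is float32 by default; float64 inputs stay float64,
  which the numerical-gradient tests use. Batch norm keeps running
  statistics (momentum 0.1, eps 1e-5) for eval-mode determinism.
* Conv padding is symmetric ("same"); maxpool truncates a non-divisible
  tail. LSTM forget-gate biases initialise to 1.
* `pool_stride` and `crnn_pool_strides` are configurable; the defaults keep
  the contract of stride-2 pooling (×4 CRNN reduction), the reduced config
  pools harder purely for speed.
* One seed drives everything: cohort generation spawns per-record
  generators from a SeedSequence; pipeline stages receive fixed seeds fanned
  out from the global one; fitting, training, bootstrap and splits all take
  explicit seeds.
* EDF input/output is not implemented; the on-disk interchange formats are
  plain CSV (signal, hypnogram, events, manifest). The CLI `run` demo uses
  the ODI baseline path because the deep trainer requires ≥50 records.

## Known limitations

Simulator realism as listed above; the desaturation detector's depth
estimates are biased high by ~2·noise-sd under noise (baseline is a running
max); the ODI inherits a small negative bias from intra-sleep wake inside
TST̂; the deep model is trained and validated on simulated physiology only,
and its near-ceiling simulator performance (all events detectable by
construction) says nothing about the clinical gap between rule-based and
learned estimators on real recordings.
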