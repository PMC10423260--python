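# oxidiag

Estimation of the apnea–hypopnea index (AHI) from a single channel of
overnight pulse oximetry (SpO₂ at 1 Hz).

Obstructive sleep apnea is diagnosed from the AHI — apneas plus hypopneas
per hour of sleep — which normally requires full polysomnography. Because
most respiratory events end in a transient oxygen desaturation, the overnight
SpO₂ trace alone carries much of the needed information. `oxidiag`
implements a complete estimation pipeline for that signal, together with a
synthetic oximetry simulator that provides exact ground truth, so every
stage can be developed and validated without access-restricted clinical
recordings:

* **simulate** — overnight SpO₂ cohorts with planted desaturations (≥3%
  deep, 10–120 s, optionally clustered into bursts), sleep/wake hypnograms,
  Gaussian sensor noise and sub-50% motion artifacts. The true AHI of each
  record is exact: planted events divided by hours asleep.
* **preprocess** — resampling to 1 Hz, a delta filter for non-physiological
  values (outside [50, 100]% or changing faster than 4 %/s), linear
  interpolation of 1–2-sample gaps, sleep-bounds estimation
  (TST̂ = span between the first and last 5-minute runs of sleep epochs),
  exclusion of records with technical faults, TST̂ < 4 h or age < 18 y, and
  padding/truncation to a fixed 7-h frame (25200 samples).
* **desat / obm** — a rule-based desaturation detector (local-baseline
  drop ≥3%), the oxygen desaturation index (ODI), and ~25 engineered
  oximetry biomarkers in five families (general statistics, complexity,
  periodicity, desaturation morphology, hypoxic burden) with mRMR feature
  selection.
* **baselines** — two benchmark regressors: ODI + age + sex, and the full
  biomarker vector, both through a gradient-boosted tree backend with
  cross-validated fitting.
* **oxinet / train** — a dual-branch deep regressor written on the package's
  own numpy autodiff engine: a windowed CNN with a dilated temporal stack,
  a conv-reduced stacked bidirectional LSTM, and a metadata branch, merged
  by width-halving classifier blocks. Training minimises

  `L = L_aggregated + λ_CNN·L_CNN + λ_CRNN·L_CRNN + l2·‖w‖²`

  where the two auxiliary heads regress the AHI from each branch alone and
  λ decays as `0.8^(epoch // 4)` from 1. Augmentation: Gaussian jitter and a
  moving-window shift of the real signal inside the 7-h frame.
* **explain** — feature-occlusion importance traces (120-s regions, 60-s
  stride, record-mean baseline).
* **metrics** — the two-observer intraclass correlation
  `ICC = (MS_I − MS_E) / (MS_I + (O−1)MS_E + O(MS_O − MS_E)/n)`,
  severity binning (non <5, mild 5–15, moderate 15–30, severe ≥30),
  macro-averaged sensitivity/PPV/F1, Bland–Altman statistics, bootstrap
  confidence intervals (1000 resamples of 80% with replacement), and
  Wilcoxon/Kruskal–Wallis tests.

## Worked example

```python
import numpy as np
from oxidiag import SimConfig, simulate_cohort, icc
from oxidiag.preprocess import preprocess_cohort, sim_to_raw
from oxidiag.desat import detect_desaturations, compute_odi

records, manifest = simulate_cohort(SimConfig(seed=1, n_records=3,
                                              record_hours=(4.5, 6.0)))
cleans, log = preprocess_cohort([sim_to_raw(r) for r in records],
                                [r.true_ahi for r in records])
c, r = cleans[0], records[0]
events = detect_desaturations(c.spo2, c.validity_mask)
print(len(r.events), len(events), round(compute_odi(events, c.tst_hat), 2),
      round(r.true_ahi, 2))
```

prints

```
65 70 14.21 13.78
```

— all 65 planted desaturations were recovered (the extra detections are
noise-split events under the default 0.5% sensor noise), and the ODI
(14.21 events/h over the estimated sleep span) sits within about 3% of the
exact planted AHI of 13.78.

The full model comparison (both baselines plus the trained network on a
300-record cohort) is available as one call:

```python
from oxidiag.experiments import benchmark_study
res = benchmark_study(seed=1)        # ~7 minutes on one CPU
print(res["icc_oxinet"], res["f1_macro_obm_oof"], res["f1_macro_odi_oof"])
```

A thin CLI wraps the stages (`oxidiag simulate | preprocess | desat |
features | fit-baseline | train | predict | explain | evaluate | run`);
`oxidiag run --out dir/ --seed 5` executes the whole pipeline from a YAML
config and writes `report.json`.

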