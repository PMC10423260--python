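"""Agreement and diagnostic-accuracy statistics for AHI estimation.

The reference and estimated apnea–hypopnea index (AHI) are treated as two
"observers" rating the same set of recordings.  Agreement on the continuous
scale is summarised by a two-way ANOVA intraclass correlation coefficient
(single-rater, absolute agreement); diagnostic accuracy is summarised by the
macro-averaged F1 over the four clinical severity classes; bias is displayed
with Bland–Altman statistics; uncertainty with a bootstrap normal-theory CI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

SEVERITY_CLASSES = ("non", "mild", "moderate", "severe")
# class edges: non < 5 <= mild < 15 <= moderate < 30 <= severe
SEVERITY_EDGES = (5.0, 15.0, 30.0)


# ---------------------------------------------------------------------------
# severity binning
# ---------------------------------------------------------------------------

def severity_bin(ahi):
    """Map AHI (events/h) to OSA severity class indices 0..3.

    Bins are half-open as used clinically: non (<5), mild [5, 15),
    moderate [15, 30), severe (>= 30).

    Accepts a scalar or array; returns an int or int array.
    """
    arr = np.asarray(ahi, dtype=float)
    if np.any(arr < 0):
        raise ValueError("AHI must be nonnegative")
    idx = np.digitize(arr, SEVERITY_EDGES, right=False)
    if np.isscalar(ahi) or arr.ndim == 0:
        return int(idx)
    return idx.astype(int)


def severity_label(ahi):
    """Severity class name(s) for the given AHI value(s)."""
    idx = severity_bin(ahi)
    if isinstance(idx, int):
        return SEVERITY_CLASSES[idx]
    return np.array([SEVERITY_CLASSES[i] for i in idx])


# ---------------------------------------------------------------------------
# intraclass correlation (two-way, single rater, absolute agreement)
# ---------------------------------------------------------------------------

@dataclass
class ICCComponents:
    """Mean squares of the two-way ANOVA underlying the ICC."""

    ms_i: float  # instances (rows) mean square
    ms_e: float  # residual mean square
    ms_o: float  # observers (columns) mean square
    observers: int
    n: int


def icc(y_true, y_pred) -> tuple[float, ICCComponents]:
    """Two-way random-effects ICC for absolute agreement between two observers.

        ICC = (MS_I - MS_E) / (MS_I + (O-1) MS_E + O (MS_O - MS_E) / n)

    with O = 2 observers (the reference and the estimate).  Systematic offsets
    between the observers enter through MS_O and are penalised.

    Returns (icc_value, ICCComponents).
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be 1-D and of equal length")
    n = y_true.size
    if n < 2:
        raise ValueError("need at least 2 paired observations")

    x = np.stack([y_true, y_pred], axis=1)  # n instances x O observers
    O = 2
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)

    ss_rows = O * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    ss_err = np.sum(resid**2)

    ms_i = ss_rows / (n - 1)
    ms_o = ss_cols / (O - 1)
    ms_e = ss_err / ((n - 1) * (O - 1))

    denom = ms_i + (O - 1) * ms_e + O * (ms_o - ms_e) / n
    value = 0.0 if denom == 0 else (ms_i - ms_e) / denom
    return float(value), ICCComponents(ms_i=float(ms_i), ms_e=float(ms_e),
                                       ms_o=float(ms_o), observers=O, n=n)


# ---------------------------------------------------------------------------
# severity confusion matrix and macro F1
# ---------------------------------------------------------------------------

def confusion_matrix4(y_true_ahi, y_pred_ahi) -> np.ndarray:
    """4x4 severity confusion matrix; rows = true class, columns = predicted."""
    t = severity_bin(np.asarray(y_true_ahi, dtype=float))
    p = severity_bin(np.asarray(y_pred_ahi, dtype=float))
    cm = np.zeros((4, 4), dtype=int)
    np.add.at(cm, (t, p), 1)
    return cm


def macro_f1(cm: np.ndarray) -> tuple[float, float, float]:
    """Macro sensitivity, macro PPV and their harmonic mean (macro F1).

    Each of the 4 severity classes contributes TP/(TP+FN) to Se_M and
    TP/(TP+FP) to PPV_M with equal weight; a class absent from both the truth
    and the predictions contributes 0 to its term (logged via a warning)
    rather than propagating NaN.
    """
    cm = np.asarray(cm)
    if cm.shape != (4, 4):
        raise ValueError("confusion matrix must be 4x4")
    if cm.sum() == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(cm).astype(float)
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp

    with np.errstate(invalid="ignore", divide="ignore"):
        se_k = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1e-300), 0.0)
        ppv_k = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1e-300), 0.0)
    if np.any((tp + fn) == 0) or np.any((tp + fp) == 0):
        warnings.warn("empty severity class; its Se/PPV term counted as 0",
                      stacklevel=2)
    se_m = float(se_k.mean())
    ppv_m = float(ppv_k.mean())
    f1_m = 0.0 if se_m + ppv_m == 0 else 2 * se_m * ppv_m / (se_m + ppv_m)
    return se_m, ppv_m, float(f1_m)


# ---------------------------------------------------------------------------
# Bland–Altman
# ---------------------------------------------------------------------------

@dataclass
class BlandAltman:
    mean_diff: float
    sd_diff: float
    median_diff: float
    p5: float
    p95: float
    loa_lower: float  # mean - 1.96 sd
    loa_upper: float  # mean + 1.96 sd


def bland_altman(y_true, y_pred) -> BlandAltman:
    """Bland–Altman statistics of (estimate - reference) differences."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("need >= 2 paired values")
    d = y_pred - y_true
    m, s = float(d.mean()), float(d.std(ddof=1))
    p5, p95 = np.percentile(d, [5, 95])
    return BlandAltman(mean_diff=m, sd_diff=s, median_diff=float(np.median(d)),
                       p5=float(p5), p95=float(p95),
                       loa_lower=m - 1.96 * s, loa_upper=m + 1.96 * s)


# ---------------------------------------------------------------------------
# bootstrap confidence intervals
# ---------------------------------------------------------------------------

@dataclass
class BootstrapCI:
    point: float
    se_boot: float
    z: float
    lower: float
    upper: float
    n_boot: int
    n_skipped: int = 0


_STATISTICS = {
    "icc": lambda t, p: icc(t, p)[0],
    "macro_f1": lambda t, p: macro_f1(confusion_matrix4(t, p))[2],
}


def bootstrap_ci(y_true, y_pred, statistic="icc", n_boot=1000, frac=0.8,
                 seed=0, z=1.96) -> BootstrapCI:
    """Normal-theory bootstrap CI: point +/- z * se_boot.

    Each replicate recomputes the statistic on floor(frac*n) pairs sampled
    with replacement.  Degenerate resamples (zero-variance pairs for which the
    statistic is undefined) are redrawn, up to a cap, and counted.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    n = y_true.size
    if n < 10:
        raise ValueError("bootstrap needs at least 10 pairs")
    if statistic not in _STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")
    fn = _STATISTICS[statistic]
    rng = np.random.default_rng(seed)
    m = int(np.floor(frac * n))
    point = fn(y_true, y_pred)

    vals = np.empty(n_boot)
    n_skipped = 0
    for b in range(n_boot):
        for _attempt in range(20):
            idx = rng.integers(0, n, size=m)
            t, p = y_true[idx], y_pred[idx]
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    v = fn(t, p)
            except ValueError:
                n_skipped += 1
                continue
            if np.isfinite(v):
                vals[b] = v
                break
            n_skipped += 1
        else:  # pragma: no cover - pathological input
            vals[b] = point
    if n_skipped:
        warnings.warn(f"{n_skipped} degenerate bootstrap resamples redrawn",
                      stacklevel=2)
    se = float(vals.std(ddof=1))
    return BootstrapCI(point=float(point), se_boot=se, z=z,
                       lower=float(point - z * se), upper=float(point + z * se),
                       n_boot=n_boot, n_skipped=n_skipped)


# ---------------------------------------------------------------------------
# hypothesis tests
# ---------------------------------------------------------------------------

def compare_models(errors_a, errors_b) -> float:
    """Wilcoxon rank-sum p-value comparing two models' absolute errors."""
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        warnings.warn("all observations tied; p = 1", stacklevel=2)
        return 1.0
    return float(stats.ranksums(a, b).pvalue)


def kruskal_screen(feature, severity_labels) -> float:
    """Kruskal–Wallis p-value: does a feature differ across severity groups?"""
    feature = np.asarray(feature, dtype=float)
    severity_labels = np.asarray(severity_labels)
    groups = [feature[severity_labels == g] for g in np.unique(severity_labels)]
    groups = [g for g in groups if g.size > 0]
    if len(groups) < 2:
        raise ValueError("need at least two severity groups")
    flat = np.concatenate(groups)
    if np.all(flat == flat[0]):
        warnings.warn("all observations tied; p = 1", stacklevel=2)
        return 1.0
    return float(stats.kruskal(*groups).pvalue)


# ---------------------------------------------------------------------------
# cohort-level report
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    n: int
    icc: float
    icc_components: ICCComponents
    se_macro: float
    ppv_macro: float
    f1_macro: float
    confusion: np.ndarray
    bland_altman: BlandAltman
    icc_ci: BootstrapCI | None = None
    f1_ci: BootstrapCI | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "n": self.n,
            "icc": self.icc,
            "se_macro": self.se_macro,
            "ppv_macro": self.ppv_macro,
            "f1_macro": self.f1_macro,
            "confusion": self.confusion.tolist(),
            "bland_altman": vars(self.bland_altman),
        }
        if self.icc_ci is not None:
            d["icc_ci"] = [self.icc_ci.lower, self.icc_ci.upper]
        if self.f1_ci is not None:
            d["f1_ci"] = [self.f1_ci.lower, self.f1_ci.upper]
        d.update(self.extras)
        return d


def evaluate_cohort(y_true, y_pred, bootstrap=True, n_boot=1000,
                    seed=0) -> EvaluationReport:
    """Full agreement report for a cohort of (reference AHI, estimated AHI)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    value, comps = icc(y_true, y_pred)
    cm = confusion_matrix4(y_true, y_pred)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        se_m, ppv_m, f1_m = macro_f1(cm)
    ba = bland_altman(y_true, y_pred)
    icc_ci = f1_ci = None
    if bootstrap and y_true.size >= 10:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            icc_ci = bootstrap_ci(y_true, y_pred, "icc", n_boot=n_boot, seed=seed)
            f1_ci = bootstrap_ci(y_true, y_pred, "macro_f1", n_boot=n_boot,
                                 seed=seed + 1)
    return EvaluationReport(n=y_true.size, icc=value, icc_components=comps,
                            se_macro=se_m, ppv_macro=ppv_m, f1_macro=f1_m,
                            confusion=cm, bland_altman=ba,
                            icc_ci=icc_ci, f1_ci=f1_ci)
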