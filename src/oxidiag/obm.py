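"""Engineered oximetry biomarkers (OBM) and mRMR feature selection.

Five feature families computed from the valid (non-padding) part of a
cleaned 1-Hz SpO2 record:

1. general statistics — mean, spread, zero-crossings about the mean, delta
   index (mean absolute difference of consecutive 12-s block means);
2. complexity — approximate entropy and the detrended-fluctuation-analysis
   (DFA) scaling exponent;
3. periodicity — phase-rectified signal averaging (PRSA) capacity and Welch
   band powers (the 0.014-0.033 Hz band captures apnea-cycle periodicity);
4. desaturation morphology — count and mean/max depth, length, area, slope
   of detected desaturations;
5. hypoxic burden — cumulative time and integrated area below 90%.

Age and sex join the vector as demographic covariates.  This is a
representative named subset of the published oximetry-biomarker families,
not a bit-parity reimplementation of any toolbox.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .desat import DesaturationEvent, detect_desaturations
from .preprocess import CleanRecord

DELTA_BLOCK_S = 12
APEN_WINDOW_S = 600      # ApEn is O(n^2); long records are averaged over
                         # 10-min windows
PSD_BANDS = {
    "psd_apnea": (0.014, 0.033),   # ~30-70 s apnea cycling
    "psd_low": (0.0, 0.014),
    "psd_high": (0.033, 0.1),
}
HYPOXIC_THRESHOLD = 90.0


# ---------------------------------------------------------------------------
# (1) general statistics
# ---------------------------------------------------------------------------

def general_statistics(series: np.ndarray) -> dict[str, float]:
    """Mean/spread, zero-crossings about the mean, and the delta index."""
    x = np.asarray(series, dtype=float)
    if x.size < 2 * DELTA_BLOCK_S:
        raise ValueError("series too short for the delta index "
                         f"(need >= {2 * DELTA_BLOCK_S} samples)")
    mu = x.mean()
    centered = np.sign(x - mu)
    nz = centered[centered != 0]
    zero_crossings = int(np.count_nonzero(np.diff(nz) != 0))

    nblk = x.size // DELTA_BLOCK_S
    block_means = x[: nblk * DELTA_BLOCK_S].reshape(nblk, DELTA_BLOCK_S).mean(axis=1)
    delta_index = float(np.abs(np.diff(block_means)).mean()) if nblk >= 2 else 0.0
    return {
        "mean_spo2": float(mu),
        "std_spo2": float(x.std()),
        "median_spo2": float(np.median(x)),
        "p5_spo2": float(np.percentile(x, 5)),
        "zero_crossings": float(zero_crossings),
        "delta_index": delta_index,
    }


# ---------------------------------------------------------------------------
# (2) complexity
# ---------------------------------------------------------------------------

def approximate_entropy(series: np.ndarray, m: int = 1,
                        r: float | None = None) -> float:
    """ApEn(m, r): phi(m) - phi(m+1) with Chebyshev distance and
    self-matches included.  r defaults to 0.25 * sd; a zero-variance series
    returns 0 by convention."""
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < m + 2:
        raise ValueError("series too short for ApEn")
    sd = x.std()
    if sd == 0:
        return 0.0
    if r is None:
        r = 0.25 * sd

    # one pairwise within-r matrix serves both template lengths: a pair of
    # length-(k+1) templates matches iff its length-k prefixes match and the
    # trailing samples are within r
    within = np.abs(x[:, None] - x[None, :]) <= r
    w_m = within.copy()
    for k in range(1, m):
        w_m = w_m[:-1, :-1] & within[k:, k:]
    c_m = w_m.mean(axis=1)                      # n - m + 1 templates
    phi_m = float(np.mean(np.log(c_m)))
    w_m1 = w_m[:-1, :-1] & within[m:, m:]
    c_m1 = w_m1.sum(axis=1) / (n - m)           # n - m templates
    phi_m1 = float(np.mean(np.log(c_m1)))
    return phi_m - phi_m1


def dfa_alpha(series: np.ndarray, box_sizes: np.ndarray | None = None) -> float:
    """DFA scaling exponent: slope of log F(s) vs log s, with linear
    detrending in each box of the integrated series."""
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 100:
        raise ValueError("series too short for DFA")
    if x.std() == 0:
        raise ValueError("zero-variance series has no DFA exponent")
    if box_sizes is None:
        smax = n // 4
        box_sizes = np.unique(np.round(
            10 * 2 ** np.arange(0, np.log2(smax / 10) + 0.01, 0.5)).astype(int))
        box_sizes = box_sizes[box_sizes >= 10]
    y = np.cumsum(x - x.mean())
    fluct = []
    for s in box_sizes:
        nbox = n // s
        if nbox < 2:
            continue
        segs = y[: nbox * s].reshape(nbox, s)
        t = np.arange(s)
        # per-box linear detrend via least squares
        tm = t - t.mean()
        beta = segs @ tm / (tm @ tm)
        resid = segs - segs.mean(axis=1, keepdims=True) - beta[:, None] * tm
        fluct.append(np.sqrt(np.mean(resid**2)))
    sizes = np.array([s for s in box_sizes if n // s >= 2], dtype=float)
    fluct = np.asarray(fluct)
    keep = fluct > 0
    if keep.sum() < 2:
        raise ValueError("not enough scales for DFA fit")
    slope = np.polyfit(np.log(sizes[keep]), np.log(fluct[keep]), 1)[0]
    return float(slope)


# ---------------------------------------------------------------------------
# (3) periodicity
# ---------------------------------------------------------------------------

def prsa_capacity(series: np.ndarray, L_prsa: int = 10, s: int = 2) -> float:
    """Phase-rectified signal averaging capacity.

    Anchors are samples that decrease relative to their predecessor; windows
    of +/- L_prsa samples around each anchor are averaged and the capacity is
    a central difference of the averaged curve at the anchor point
    (Bauer-style with smoothing width s).  No anchors -> 0.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2 * L_prsa + 2:
        raise ValueError("series too short for PRSA")
    anchors = np.flatnonzero(x[1:] < x[:-1]) + 1
    anchors = anchors[(anchors >= L_prsa) & (anchors < x.size - L_prsa)]
    if anchors.size == 0:
        return 0.0
    offs = np.arange(-L_prsa, L_prsa + 1)
    windows = x[anchors[:, None] + offs[None, :]]
    avg = windows.mean(axis=0)
    c = L_prsa  # index of the anchor in the averaged curve
    cap = (np.sum(avg[c + 1:c + 1 + s]) - np.sum(avg[c - s:c])) / (2.0 * s)
    return float(cap)


def psd_bands(series: np.ndarray, bands: dict | None = None,
              fs: float = 1.0) -> dict[str, float]:
    """Welch band powers in the given frequency bands (Hz)."""
    x = np.asarray(series, dtype=float)
    if bands is None:
        bands = PSD_BANDS
    nper = min(x.size, 2048)
    f, pxx = sp_signal.welch(x - x.mean(), fs=fs, nperseg=nper)
    out = {}
    for name, (lo, hi) in bands.items():
        sel = (f >= lo) & (f < hi)
        out[name] = float(np.trapezoid(pxx[sel], f[sel])) if sel.any() else 0.0
    return out


# ---------------------------------------------------------------------------
# (4) desaturation aggregates / (5) hypoxic burden
# ---------------------------------------------------------------------------

def desaturation_features(events: list[DesaturationEvent],
                          tst_hat: float) -> dict[str, float]:
    if not events:
        return {"desat_count": 0.0, "desat_per_hour": 0.0,
                "desat_depth_mean": 0.0, "desat_depth_max": 0.0,
                "desat_length_mean": 0.0, "desat_area_mean": 0.0,
                "desat_slope_mean": 0.0}
    depths = np.array([e.depth for e in events])
    lengths = np.array([e.length for e in events], dtype=float)
    areas = np.array([e.area for e in events])
    slopes = np.array([e.slope_desc for e in events])
    return {
        "desat_count": float(len(events)),
        "desat_per_hour": float(len(events) / tst_hat) if tst_hat > 0 else 0.0,
        "desat_depth_mean": float(depths.mean()),
        "desat_depth_max": float(depths.max()),
        "desat_length_mean": float(lengths.mean()),
        "desat_area_mean": float(areas.mean()),
        "desat_slope_mean": float(slopes.mean()),
    }


def hypoxic_burden(series: np.ndarray,
                   threshold: float = HYPOXIC_THRESHOLD) -> dict[str, float]:
    """Cumulative seconds below threshold and the integrated %*s deficit."""
    x = np.asarray(series, dtype=float)
    below = x < threshold
    return {
        "ct_below": float(np.count_nonzero(below)),
        "area_below": float(np.sum(np.clip(threshold - x, 0.0, None))),
        "pct_time_below": float(below.mean() * 100.0) if x.size else 0.0,
    }


# ---------------------------------------------------------------------------
# full feature vector
# ---------------------------------------------------------------------------

def _windowed_apen(x: np.ndarray, window: int = APEN_WINDOW_S) -> float:
    """Mean ApEn over disjoint windows (exact on inputs <= one window)."""
    if x.size <= window:
        return approximate_entropy(x)
    vals = []
    for start in range(0, x.size - window + 1, window):
        seg = x[start:start + window]
        if seg.std() > 0:
            vals.append(approximate_entropy(seg))
    return float(np.mean(vals)) if vals else 0.0


def extract_features(record: CleanRecord,
                     events: list[DesaturationEvent] | None = None,
                     ) -> pd.Series:
    """The named OBM feature vector of one cleaned record.

    Only valid (non-padding) samples enter the computations, so features are
    invariant to the amount of padding.  Desaturations are detected on the
    framed signal unless supplied.
    """
    if record.excluded:
        raise ValueError(f"record {record.record_id} was excluded "
                         f"({record.exclusion_reason})")
    if events is None:
        events = detect_desaturations(record.spo2, record.validity_mask)
    x = record.spo2[record.validity_mask]
    feats: dict[str, float] = {}
    feats.update(general_statistics(x))
    feats["apen"] = _windowed_apen(x)
    try:
        feats["dfa_alpha"] = dfa_alpha(x)
    except ValueError:
        feats["dfa_alpha"] = 0.0
    feats["prsa_capacity"] = prsa_capacity(x)
    feats.update(psd_bands(x))
    feats.update(desaturation_features(events, record.tst_hat))
    feats.update(hypoxic_burden(x))
    feats["age"] = float(record.age)
    feats["sex"] = 1.0 if record.sex == "male" else 0.0
    return pd.Series(feats, name=record.record_id)


def feature_table(records: list[CleanRecord]) -> pd.DataFrame:
    """Records x features matrix for the non-excluded records."""
    rows = [extract_features(r) for r in records if not r.excluded]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mRMR feature selection
# ---------------------------------------------------------------------------

def mrmr_select(matrix: pd.DataFrame, target: np.ndarray, k: int) -> list[str]:
    """Greedy maximum-relevance minimum-redundancy feature selection.

    Relevance and redundancy are absolute Pearson correlations; at each step
    the feature maximising |corr(f, target)| - mean |corr(f, selected)| is
    added.  Constant features have zero relevance.  Ties break on column
    order, so the result is deterministic.
    """
    if k > matrix.shape[1]:
        raise ValueError("k exceeds the number of features")
    if matrix.isna().any().any():
        raise ValueError("feature matrix contains missing values")
    X = matrix.to_numpy(dtype=float)
    y = np.asarray(target, dtype=float)

    def _abs_corr(a: np.ndarray, b: np.ndarray) -> float:
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            return 0.0
        return abs(float(np.corrcoef(a, b)[0, 1]))

    cols = list(matrix.columns)
    relevance = np.array([_abs_corr(X[:, j], y) for j in range(len(cols))])
    selected: list[int] = []
    remaining = list(range(len(cols)))
    while len(selected) < k:
        best_j, best_score = None, -np.inf
        for j in remaining:
            red = (np.mean([_abs_corr(X[:, j], X[:, s]) for s in selected])
                   if selected else 0.0)
            score = relevance[j] - red
            if score > best_score + 1e-12:
                best_j, best_score = j, score
        selected.append(best_j)
        remaining.remove(best_j)
    return [cols[j] for j in selected]
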