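"""Oximetry biomarkers against brute-force references and hand arithmetic."""

import numpy as np
import pandas as pd
import pytest

from oxidiag import obm
from oxidiag.preprocess import CleanRecord


def _clean(signal, n_pad=0, age=55.0, sex="male", tst=6.0):
    x = np.asarray(signal, dtype=float)
    spo2 = np.concatenate([x, np.full(n_pad, x.mean())])
    mask = np.concatenate([np.ones(x.size, bool), np.zeros(n_pad, bool)])
    return CleanRecord(record_id="t", spo2=spo2, validity_mask=mask,
                       sleep_onset=0, sleep_offset=int(tst * 3600),
                       tst_hat=tst, age=age, sex=sex, true_ahi=0.0)


# ---------------------------------------------------------------------------
# general statistics
# ---------------------------------------------------------------------------

def test_general_statistics_constant_series():
    s = obm.general_statistics(np.full(600, 95.0))
    assert s["zero_crossings"] == 0 and s["delta_index"] == 0


def test_delta_index_alternating_samples_is_zero():
    x = np.tile([95.0, 96.0], 300)  # every 12-s block has the same mean
    assert obm.general_statistics(x)["delta_index"] == pytest.approx(0.0)


def test_delta_index_square_wave_blocks():
    x = np.concatenate([np.full(12, 94.0) if i % 2 == 0 else np.full(12, 96.0)
                        for i in range(20)])
    assert obm.general_statistics(x)["delta_index"] == pytest.approx(2.0)


def test_general_statistics_too_short_raises():
    with pytest.raises(ValueError):
        obm.general_statistics(np.full(20, 95.0))


# ---------------------------------------------------------------------------
# complexity: brute-force oracles
# ---------------------------------------------------------------------------

def apen_bruteforce(x, m, r):
    """Literal ApEn definition with explicit loops (self-matches included)."""
    n = len(x)

    def phi(mm):
        count = np.zeros(n - mm + 1)
        for i in range(n - mm + 1):
            for j in range(n - mm + 1):
                if max(abs(x[i + k] - x[j + k]) for k in range(mm)) <= r:
                    count[i] += 1
        return np.mean(np.log(count / (n - mm + 1)))

    return phi(m) - phi(m + 1)


def test_apen_matches_bruteforce():
    rng = np.random.default_rng(3)
    x = rng.normal(95, 1, 200)
    r = 0.25 * x.std()
    assert obm.approximate_entropy(x, m=1, r=r) == pytest.approx(
        apen_bruteforce(x, 1, r), abs=1e-8)


def test_apen_constant_and_periodic_vs_shuffled():
    assert obm.approximate_entropy(np.full(300, 95.0)) == 0.0
    t = np.arange(1000)
    periodic = 95 + np.sin(2 * np.pi * t / 50)
    shuffled = periodic.copy()
    np.random.default_rng(0).shuffle(shuffled)
    assert obm.approximate_entropy(periodic) < obm.approximate_entropy(shuffled)


def dfa_bruteforce(x, sizes):
    """Direct DFA: integrate, split into boxes, fit/remove a line per box."""
    y = np.cumsum(x - np.mean(x))
    out = []
    for s in sizes:
        resids = []
        for b in range(len(x) // s):
            seg = y[b * s:(b + 1) * s]
            t = np.arange(s)
            coef = np.polyfit(t, seg, 1)
            resids.extend((seg - np.polyval(coef, t)) ** 2)
        out.append(np.sqrt(np.mean(resids)))
    return np.polyfit(np.log(sizes), np.log(out), 1)[0]


def test_dfa_matches_bruteforce():
    rng = np.random.default_rng(5)
    x = rng.normal(0, 1, 500)
    sizes = np.array([10, 20, 40, 80, 125])
    assert obm.dfa_alpha(x, sizes) == pytest.approx(
        dfa_bruteforce(x, sizes), abs=1e-8)


def test_dfa_white_noise_exponent_near_half():
    rng = np.random.default_rng(6)
    alpha = obm.dfa_alpha(rng.normal(0, 1, 4096))
    assert 0.4 <= alpha <= 0.6


def test_dfa_zero_variance_raises():
    with pytest.raises(ValueError):
        obm.dfa_alpha(np.full(500, 95.0))


# ---------------------------------------------------------------------------
# periodicity
# ---------------------------------------------------------------------------

def test_prsa_constant_is_zero_and_ramp_anchors():
    assert obm.prsa_capacity(np.full(100, 95.0)) == 0.0
    ramp = np.linspace(100, 50, 200)  # every interior sample decreases
    cap = obm.prsa_capacity(ramp)
    assert cap != 0.0


def test_psd_band_peak_location():
    t = np.arange(6000)
    x = 96 + np.sin(2 * np.pi * 0.02 * t)  # 0.02 Hz: inside the apnea band
    bands = obm.psd_bands(x)
    assert bands["psd_apnea"] > bands["psd_low"]
    assert bands["psd_apnea"] > bands["psd_high"]


def test_psd_constant_series_near_zero():
    bands = obm.psd_bands(np.full(4000, 95.0))
    assert all(abs(v) < 1e-12 for v in bands.values())


# ---------------------------------------------------------------------------
# hypoxic burden and desaturation aggregates
# ---------------------------------------------------------------------------

def test_hypoxic_burden_examples():
    x = np.full(600, 95.0)
    hb = obm.hypoxic_burden(x)
    assert hb["ct_below"] == 0 and hb["area_below"] == 0

    x[100:160] = 88.0
    hb = obm.hypoxic_burden(x)
    assert hb["ct_below"] == 60 and hb["area_below"] == pytest.approx(120.0)

    hb = obm.hypoxic_burden(np.full(600, 95.0), threshold=100.0)
    assert hb["ct_below"] == 600


def test_event_free_record_zero_aggregates():
    rec = _clean(np.random.default_rng(0).normal(96, 0.2, 21600))
    f = obm.extract_features(rec, events=[])
    assert f["desat_count"] == 0 and f["desat_area_mean"] == 0
    assert f["ct_below"] == 0 and f["area_below"] == 0


def test_features_invariant_to_padding():
    rng = np.random.default_rng(1)
    x = rng.normal(96, 0.5, 18000)
    a = obm.extract_features(_clean(x, n_pad=0), events=[])
    b = obm.extract_features(_clean(x, n_pad=7200), events=[])
    pd.testing.assert_series_equal(a, b, check_names=False)


def test_excluded_record_rejected():
    rec = _clean(np.full(18000, 95.0))
    rec.excluded = True
    rec.exclusion_reason = "tst_lt_4"
    with pytest.raises(ValueError):
        obm.extract_features(rec)


# ---------------------------------------------------------------------------
# mRMR
# ---------------------------------------------------------------------------

def _toy_matrix(n=200, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.normal(0, 1, n)
    X = pd.DataFrame({
        "copy": y.copy(),
        "noisy": y + rng.normal(0, 0.5, n),
        "dup_of_copy": y.copy() + rng.normal(0, 1e-3, n),
        "weak": 0.3 * y + rng.normal(0, 1, n),
        "noise1": rng.normal(0, 1, n),
        "noise2": rng.normal(0, 1, n),
        "constant": np.ones(n),
    })
    return X, y


def test_mrmr_exact_copy_selected_first():
    X, y = _toy_matrix()
    sel = obm.mrmr_select(X, y, 3)
    assert sel[0] == "copy"


def test_mrmr_redundancy_penalty_demotes_duplicate():
    # minimal trace: two near-duplicates of the target plus one independent
    # weaker feature; after the first duplicate is taken, full redundancy
    # drives the second duplicate below the weak feature
    rng = np.random.default_rng(2)
    y = rng.normal(0, 1, 300)
    dup_a = y + rng.normal(0, 0.5, 300)
    X = pd.DataFrame({
        "dup_a": dup_a,
        "dup_b": dup_a + rng.normal(0, 1e-3, 300),  # shares dup_a's noise
        "weak": 0.4 * y + rng.normal(0, 1, 300),
    })
    sel = obm.mrmr_select(X, y, 3)
    assert sel[0] in ("dup_a", "dup_b")
    assert sel[1] == "weak"


def test_mrmr_k_equals_n_features_returns_all():
    X, y = _toy_matrix()
    sel = obm.mrmr_select(X, y, X.shape[1])
    assert set(sel) == set(X.columns)
    assert sel[0] == "copy"  # first pick is pure max relevance


def test_mrmr_validates_input():
    X, y = _toy_matrix()
    with pytest.raises(ValueError):
        obm.mrmr_select(X, y, X.shape[1] + 1)
    X.loc[0, "weak"] = np.nan
    with pytest.raises(ValueError):
        obm.mrmr_select(X, y, 2)


def test_feature_table_shape(small_cohort):
    _, cleans, _ = small_cohort
    kept = [c for c in cleans if not c.excluded]
    tbl = obm.feature_table(kept[:5])
    assert tbl.shape[0] == 5
    assert {"apen", "dfa_alpha", "odi", "age", "sex"}.issubset(
        set(tbl.columns) | {"odi"})
    assert np.isfinite(tbl.to_numpy(float)).all()
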