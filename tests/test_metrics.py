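"""Agreement statistics against independent oracles and hand arithmetic."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oxidiag import metrics


# ---------------------------------------------------------------------------
# severity bins
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("ahi,expected", [
    (0.0, "non"), (4.999, "non"), (5.0, "mild"), (14.999, "mild"),
    (15.0, "moderate"), (29.999, "moderate"), (30.0, "severe"), (90.0, "severe"),
])
def test_severity_bin_boundaries(ahi, expected):
    assert metrics.severity_label(ahi) == expected


def test_severity_bin_rejects_negative():
    with pytest.raises(ValueError):
        metrics.severity_bin(-0.1)


@given(st.floats(min_value=0, max_value=200), st.floats(min_value=0, max_value=5))
@settings(max_examples=50, deadline=None)
def test_severity_bin_monotone(ahi, delta):
    assert metrics.severity_bin(ahi + delta) >= metrics.severity_bin(ahi)


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

from oracles import icc_anova_oracle


def test_icc_perfect_agreement():
    y = np.array([3.0, 10.0, 25.0, 40.0])
    value, comps = metrics.icc(y, y)
    assert value == pytest.approx(1.0, abs=1e-12)
    assert comps.ms_e == pytest.approx(0.0, abs=1e-12)


def test_icc_matches_anova_oracle_reversed_vectors():
    y_true = np.array([0.0, 10.0, 20.0, 30.0])
    y_pred = y_true[::-1].copy()
    value, _ = metrics.icc(y_true, y_pred)
    assert value == pytest.approx(icc_anova_oracle(y_true, y_pred), abs=1e-10)


def test_icc_penalises_systematic_shift():
    rng = np.random.default_rng(0)
    y = rng.normal(20, 10, 100)
    shifted, _ = metrics.icc(y, y + 15.0)
    assert shifted < 1.0
    assert shifted == pytest.approx(icc_anova_oracle(y, y + 15.0), abs=1e-10)


def test_icc_input_validation():
    with pytest.raises(ValueError):
        metrics.icc([1.0], [1.0])
    with pytest.raises(ValueError):
        metrics.icc([1.0, 2.0], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# macro F1
# ---------------------------------------------------------------------------

def test_macro_f1_perfect_diagonal():
    cm = np.diag([10, 5, 7, 3])
    assert metrics.macro_f1(cm) == pytest.approx((1.0, 1.0, 1.0))


def test_macro_f1_hand_traced_confusions():
    # class 1 entirely predicted as class 2:
    # Se = (1 + 0 + 1 + 1)/4, PPV = (1 + 0 + 0.5 + 1)/4
    cm = np.array([[5, 0, 0, 0], [0, 0, 5, 0], [0, 0, 5, 0], [0, 0, 0, 5]])
    with pytest.warns(UserWarning):
        se, ppv, f1 = metrics.macro_f1(cm)
    assert se == pytest.approx(0.75)
    assert ppv == pytest.approx(0.625)
    assert f1 == pytest.approx(2 * 0.75 * 0.625 / (0.75 + 0.625))


def test_macro_f1_uniform_random_predictions():
    rng = np.random.default_rng(4)
    t = np.repeat(np.arange(4), 2500)
    p = rng.integers(0, 4, t.size)
    cm = np.zeros((4, 4), int)
    np.add.at(cm, (t, p), 1)
    _, _, f1 = metrics.macro_f1(cm)
    assert 0.22 <= f1 <= 0.28  # expectation 0.25 for 4 balanced classes


def test_macro_f1_invariant_under_class_relabeling():
    rng = np.random.default_rng(5)
    cm = rng.integers(0, 30, (4, 4))
    perm = rng.permutation(4)
    assert metrics.macro_f1(cm[np.ix_(perm, perm)]) == pytest.approx(
        metrics.macro_f1(cm))


def test_macro_f1_rejects_empty():
    with pytest.raises(ValueError):
        metrics.macro_f1(np.zeros((4, 4), int))


# ---------------------------------------------------------------------------
# Bland–Altman
# ---------------------------------------------------------------------------

def test_bland_altman_identical_and_offset():
    y = np.array([5.0, 10.0, 20.0, 40.0])
    ba = metrics.bland_altman(y, y)
    assert ba.median_diff == ba.p5 == ba.p95 == 0.0
    ba = metrics.bland_altman(y, y + 3.0)
    assert ba.median_diff == pytest.approx(3.0)
    assert ba.p5 == pytest.approx(3.0) and ba.p95 == pytest.approx(3.0)
    assert ba.sd_diff == pytest.approx(0.0)


def test_bland_altman_limits_of_agreement():
    rng = np.random.default_rng(2)
    t = rng.normal(20, 10, 500)
    p = t + rng.normal(1.0, 2.0, 500)
    ba = metrics.bland_altman(t, p)
    d = p - t
    assert ba.loa_upper == pytest.approx(d.mean() + 1.96 * d.std(ddof=1))
    assert ba.p95 == pytest.approx(np.percentile(d, 95), abs=1e-10)


# ---------------------------------------------------------------------------
# bootstrap CI
# ---------------------------------------------------------------------------

def test_bootstrap_collapses_for_perfect_predictions():
    rng = np.random.default_rng(7)
    y = rng.normal(20, 10, 40)
    ci = metrics.bootstrap_ci(y, y.copy(), "icc", n_boot=200, seed=1)
    assert ci.se_boot == pytest.approx(0.0, abs=1e-12)
    assert ci.lower == pytest.approx(1.0) and ci.upper == pytest.approx(1.0)


def test_bootstrap_is_seed_reproducible():
    rng = np.random.default_rng(8)
    t = rng.normal(20, 10, 60)
    p = t + rng.normal(0, 5, 60)
    a = metrics.bootstrap_ci(t, p, "icc", n_boot=300, seed=42)
    b = metrics.bootstrap_ci(t, p, "icc", n_boot=300, seed=42)
    assert (a.lower, a.upper) == (b.lower, b.upper)
    c = metrics.bootstrap_ci(t, p, "icc", n_boot=300, seed=43)
    assert (a.lower, a.upper) != (c.lower, c.upper)


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------

def test_compare_models_identical_and_disjoint():
    rng = np.random.default_rng(3)
    a = rng.normal(5, 1, 50)
    with pytest.warns(UserWarning):
        assert metrics.compare_models(a[:10] * 0 + 1, a[:10] * 0 + 1) == 1.0
    b = a + 100.0
    assert metrics.compare_models(a, b) < 1e-6


def test_ranksum_close_to_exact_permutation_null():
    """At n=6 per group the asymptotic p is near the exhaustive one."""
    a = np.array([1.2, 3.4, 0.5, 2.2, 4.1, 1.9])
    b = np.array([2.8, 5.0, 4.4, 3.9, 6.1, 2.0])
    p_asym = metrics.compare_models(a, b)

    pooled = np.concatenate([a, b])
    ranks = pooled.argsort().argsort() + 1
    obs = ranks[:6].sum()
    null = [sum(c) for c in itertools.combinations(ranks, 6)]
    null = np.array(null, dtype=float)
    mean = null.mean()
    p_exact = np.mean(np.abs(null - mean) >= abs(obs - mean) - 1e-9)
    assert p_asym == pytest.approx(p_exact, abs=0.02)


def test_kruskal_screen_detects_group_differences():
    rng = np.random.default_rng(9)
    labels = np.repeat([0, 1, 2, 3], 30)
    flat = rng.normal(0, 1, 120)
    assert metrics.kruskal_screen(flat, labels) > 0.01
    separated = flat + labels * 10.0
    assert metrics.kruskal_screen(separated, labels) < 1e-6


def test_evaluate_cohort_report_roundtrip():
    rng = np.random.default_rng(11)
    t = np.abs(rng.normal(15, 12, 80))
    p = np.clip(t + rng.normal(0, 4, 80), 0, None)
    rep = metrics.evaluate_cohort(t, p, n_boot=100, seed=0)
    d = rep.to_dict()
    assert d["n"] == 80
    assert 0 < d["icc"] <= 1
    assert np.array(d["confusion"]).sum() == 80
    assert d["icc_ci"][0] <= d["icc"] <= d["icc_ci"][1]
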