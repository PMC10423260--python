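"""Architecture contracts: windowing, shapes, parameter counts, gradients."""

import numpy as np
import pytest

from oxidiag import nn
from oxidiag.oxinet import (OxiNet, OxiNetConfig, build_windows,
                            count_parameters, dilated_receptive_field,
                            load_checkpoint, reduced_config, save_checkpoint)
from oxidiag.train import composite_loss


def tiny_config(**over) -> OxiNetConfig:
    """A deliberately small config for fast structural tests."""
    base = dict(input_len=4800, L_window=1200, overlap=0.0, n_B=2, n_L=1,
                cnn_channels=(4, 8), pool_stride=4, n_DB=2, n_C=8,
                K_dilated=3, rate_dilation=2, k_CRNN=5, crnn_channels=4,
                crnn_pool_strides=(16, 8), n_LSTM=6, N_META=4,
                n_classifier=2, d_classifier=0.2)
    base.update(over)
    return OxiNetConfig(**base)


def _inputs(cfg, n=3, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(96, 2, (n, cfg.input_len))
    meta = np.stack([rng.normal(0, 1, n), rng.integers(0, 2, n)], axis=1)
    return x, meta


# ---------------------------------------------------------------------------
# windowing
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("T,L,overlap,expected", [
    (25200, 3600, 0.0, 7),
    (25200, 3600, 0.5, 13),   # (25200-3600)/1800 + 1
    (25200, 25200, 0.0, 1),
])
def test_build_windows_counts(T, L, overlap, expected):
    w = build_windows(np.zeros((2, T)), L, overlap)
    assert w.shape == (2, expected, L)


def test_build_windows_tile_content():
    x = np.arange(100.0)[None, :]
    w = build_windows(x, 20, 0.5)
    assert np.array_equal(w[0, 0], np.arange(20.0))
    assert np.array_equal(w[0, 1], np.arange(10.0, 30.0))


def test_build_windows_errors():
    with pytest.raises(ValueError):
        build_windows(np.zeros((1, 10)), 20, 0.0)
    with pytest.raises(ValueError):
        OxiNetConfig(L_window=100, overlap=0.999).validate()


# ---------------------------------------------------------------------------
# forward contracts
# ---------------------------------------------------------------------------

def test_forward_returns_three_finite_scalars_per_record():
    cfg = tiny_config()
    m = OxiNet(cfg, seed=0)
    x, meta = _inputs(cfg)
    main, aux_c, aux_r = m(x, meta)
    for out in (main, aux_c, aux_r):
        assert out.data.shape == (3,)
        assert np.isfinite(out.data).all()


def test_branch_widths_match_config():
    cfg = tiny_config()
    m = OxiNet(cfg, seed=0)
    x, meta = _inputs(cfg)
    v_cnn, v_crnn, v_meta = m.branch_features(x, meta)
    assert v_cnn.data.shape == (3, cfg.n_cnn)
    assert v_crnn.data.shape == (3, 2 * cfg.n_LSTM)
    assert v_meta.data.shape == (3, cfg.N_META)


def test_classifier_widths_halve():
    cfg = tiny_config(n_classifier=3)
    m = OxiNet(cfg, seed=0)
    w0 = cfg.n_cnn + 2 * cfg.n_LSTM + cfg.N_META
    assert m.head_widths == [w0, w0 // 2, w0 // 4, w0 // 8]


def test_eval_mode_forward_is_deterministic():
    cfg = tiny_config(d_classifier=0.5)
    m = OxiNet(cfg, seed=0)
    x, meta = _inputs(cfg)
    a = m.predict(x, meta)
    b = m.predict(x, meta)
    assert np.array_equal(a, b)
    # train mode with dropout is stochastic
    m.train()
    t1, _, _ = m(x, meta)
    t2, _, _ = m(x, meta)
    assert not np.array_equal(t1.data, t2.data)


def test_palindromic_input_equals_its_reverse():
    cfg = tiny_config()
    m = OxiNet(cfg, seed=0)
    rng = np.random.default_rng(3)
    half = rng.normal(96, 2, cfg.input_len // 2)
    x = np.concatenate([half, half[::-1]])[None, :]
    assert np.array_equal(x, x[:, ::-1])
    meta = np.array([[0.0, 1.0]])
    assert np.allclose(m.predict(x, meta), m.predict(x[:, ::-1].copy(), meta))


def test_wrong_input_length_raises():
    cfg = tiny_config()
    m = OxiNet(cfg, seed=0)
    with pytest.raises(ValueError):
        m(np.zeros((2, cfg.input_len + 1)), np.zeros((2, 2)))


def test_meta_branch_distinguishes_sexes():
    cfg = tiny_config()
    m = OxiNet(cfg, seed=0)
    a = m.meta(nnt(np.array([[0.0, 0.0]])))
    b = m.meta(nnt(np.array([[0.0, 1.0]])))
    assert not np.allclose(a.data, b.data)


def nnt(x):
    from oxidiag.autodiff import Tensor
    return Tensor(np.asarray(x, np.float32))


# ---------------------------------------------------------------------------
# parameter counting
# ---------------------------------------------------------------------------

def test_count_parameters_head_only_degenerate():
    cfg_a = tiny_config(n_classifier=0)
    cfg_b = tiny_config(n_classifier=1)
    m_a = OxiNet(cfg_a, seed=0)
    w0 = cfg_a.n_cnn + 2 * cfg_a.n_LSTM + cfg_a.N_META
    head_params = sum(p.size for name, p in m_a.named_parameters()
                      if name.startswith(("head", "out")))
    assert head_params == w0 + 1  # single linear unit
    assert count_parameters(cfg_b) > count_parameters(cfg_a)


def test_count_parameters_matches_layer_arithmetic():
    """Hand sum for a minimal config with known layer shapes."""
    cfg = tiny_config(n_B=1, n_L=1, cnn_channels=(4,), n_DB=1, n_C=8,
                      K_dilated=3, n_LSTM=6, N_META=4, n_classifier=1)
    # CNN: conv1(1->4,k3) 16, bn 8, proj(1->4,k1) 8; dilated conv(4->8,k3) 104
    cnn = (1 * 4 * 3 + 4) + (4 + 4) + (1 * 4 * 1 + 4) + (4 * 8 * 3 + 8)
    # CRNN convs: (1->4,k5)+bn, (4->4,k5)+bn
    crnn_conv = (1 * 4 * 5 + 4) + 8 + (4 * 4 * 5 + 4) + 8
    # BiLSTM1: 2 dirs x (4*6*(4+6) + 4*6); BiLSTM2: input 12
    lstm1 = 2 * (4 * 6 * (4 + 6) + 24)
    lstm2 = 2 * (4 * 6 * (12 + 6) + 24)
    meta = 2 * 4 + 4
    w0 = 8 + 12 + 4
    head = (w0 * (w0 // 2) + w0 // 2) + (w0 // 2 + w0 // 2)  # linear + bn
    out = (w0 // 2) + 1
    aux = (8 + 1) + (12 + 1)
    expected = cnn + crnn_conv + lstm1 + lstm2 + meta + head + out + aux
    assert count_parameters(cfg) == expected


def test_doubling_lstm_units_more_than_doubles_lstm_params():
    def lstm_params(n):
        m = OxiNet(tiny_config(n_LSTM=n), seed=0)
        return sum(p.size for name, p in m.named_parameters()
                   if "lstm" in name)
    assert lstm_params(12) > 2 * lstm_params(6)


def test_dilated_receptive_field_grows_geometrically():
    cfg = tiny_config()
    rf2 = dilated_receptive_field(tiny_config(n_DB=2))
    rf3 = dilated_receptive_field(tiny_config(n_DB=3))
    # adding a block adds (K-1) * rate * 2^i, i.e. more than doubling growth
    assert rf3 - rf2 >= (rf2 - 1)


# ---------------------------------------------------------------------------
# learning sanity and gradient isolation
# ---------------------------------------------------------------------------

def test_one_adam_step_reduces_all_three_losses():
    cfg = tiny_config(d_classifier=0.0)
    m = OxiNet(cfg, seed=1)
    x, meta = _inputs(cfg, n=8, seed=2)
    y = np.random.default_rng(3).normal(0, 1, 8)
    opt = nn.Adam(m.parameters(), lr=0.001)

    def losses():
        main, ac, ar = m(x, meta)
        return (composite_loss(main, ac, ar, y, 0, 0).item(),
                composite_loss(ac, ac, ac, y, 0, 0).item(),
                composite_loss(ar, ar, ar, y, 0, 0).item())

    before = losses()
    main, ac, ar = m(x, meta)
    loss = composite_loss(main, ac, ar, y, 1.0, 1.0)
    opt.zero_grad()
    loss.backward()
    opt.step()
    after = losses()
    assert all(a < b for a, b in zip(after, before))


def test_aux_heads_do_not_touch_main_head_parameters():
    cfg = tiny_config(d_classifier=0.0)
    m = OxiNet(cfg, seed=0)
    x, meta = _inputs(cfg, n=4)
    y = np.zeros(4)
    _, aux_c, aux_r = m(x, meta)
    loss = composite_loss(aux_c, aux_c, aux_r, y, 1.0, 1.0)
    m.zero_grad()
    loss.backward()
    for name, p in m.named_parameters():
        if name.startswith(("head", "out", "meta")):
            assert p.grad is None or np.allclose(p.grad, 0), name
        if name.startswith("aux_cnn"):
            assert p.grad is not None and not np.allclose(p.grad, 0), name
    # the CNN-branch aux loss must not reach the CRNN branch
    m.zero_grad()
    _, aux_c, _ = m(x, meta)
    composite_loss(aux_c, aux_c, aux_c, y, 0.0, 0.0).backward()
    for name, p in m.named_parameters():
        if name.startswith("crnn"):
            assert p.grad is None or np.allclose(p.grad, 0), name


def test_checkpoint_roundtrip(tmp_path):
    cfg = tiny_config()
    m = OxiNet(cfg, seed=4)
    x, meta = _inputs(cfg)
    before = m.predict(x, meta)
    save_checkpoint(m, tmp_path / "ckpt.npz", extra={"note": "test"})
    loaded, sidecar = load_checkpoint(tmp_path / "ckpt.npz")
    assert sidecar["note"] == "test"
    assert np.allclose(loaded.predict(x, meta), before)


def test_config_validation_errors():
    with pytest.raises(ValueError):
        tiny_config(n_DB=0).validate()
    with pytest.raises(ValueError):
        tiny_config(d_classifier=1.0).validate()
    with pytest.raises(ValueError):
        tiny_config(pool_stride=40, n_B=2, cnn_channels=(4, 8),
                    L_window=100).validate()
    reduced_config().validate()  # the documented small config is valid
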