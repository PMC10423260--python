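"""The dual-branch deep AHI regressor.

A 7-h 1-Hz SpO2 record (25200 samples) is processed by two complementary
branches:

* a CNN branch: the signal is cut into overlapping windows; each window
  passes through a stack of conv/batch-norm/LeakyReLU/maxpool blocks with
  additive skip connections; the per-window features are concatenated along
  time and a stack of dilated convolutions (dilation doubling per block)
  widens the receptive field over the whole night; global average pooling
  yields V_CNN;
* a CRNN branch: two conv/pool blocks reduce the temporal resolution, then
  two stacked bidirectional LSTMs summarise long-range structure; the final
  hidden states of both directions form V_CRNN;
* a metadata branch embeds (standardised age, sex) into V_META.

V_final = [V_CNN, V_CRNN, V_META] feeds a stack of classifier blocks (fully
connected + batch norm + LeakyReLU + dropout, width halving per block) and a
final linear unit that outputs the AHI.  Two auxiliary linear regressors
predict the AHI from V_CNN and V_CRNN alone; they are not part of the final
prediction but keep each branch independently discriminative during
training.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concat, mse  # noqa: F401  (mse re-exported)
from . import nn

FRAME_SAMPLES = 25200


@dataclass
class OxiNetConfig:
    """Architecture hyperparameters.

    The published architecture left the searched values unreported; these
    defaults are chosen for desk-scale trainability and are not tuned to any
    particular parameter count.
    """

    input_len: int = FRAME_SAMPLES
    # CNN branch
    L_window: int = 1200          # seconds per window
    overlap: float = 0.5          # fraction of window overlap
    n_B: int = 3                  # conv blocks per window
    n_L: int = 2                  # conv layers per block
    cnn_channels: tuple[int, ...] = (8, 16, 32)
    pool_stride: int = 2
    n_DB: int = 3                 # dilated blocks
    n_C: int = 32                 # filters per dilated block
    K_dilated: int = 7
    rate_dilation: int = 2        # initial dilation; doubles per block
    # CRNN branch
    k_CRNN: int = 7
    crnn_channels: int = 16
    crnn_pool_strides: tuple[int, ...] = (2, 2)
    n_LSTM: int = 64
    # metadata branch
    N_META: int = 8
    # aggregation head
    n_classifier: int = 2
    d_classifier: float = 0.3
    leaky_alpha: float = 0.1
    dtype: str = "float32"
    # input scaling: (spo2 - input_center) / input_scale
    input_center: float = 96.0
    input_scale: float = 4.0

    @property
    def window_stride(self) -> int:
        return int(round(self.L_window * (1.0 - self.overlap)))

    @property
    def n_windows(self) -> int:
        return (self.input_len - self.L_window) // self.window_stride + 1

    @property
    def n_cnn(self) -> int:
        return self.n_C

    @property
    def n_crnn(self) -> int:
        return 2 * self.n_LSTM

    def validate(self) -> None:
        for name in ("n_B", "n_L", "n_DB", "n_C", "K_dilated", "n_LSTM",
                     "N_META"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_classifier < 0:
            raise ValueError("n_classifier must be >= 0")
        if not 0.0 <= self.d_classifier < 1.0:
            raise ValueError("d_classifier must be in [0, 1)")
        if self.L_window > self.input_len:
            raise ValueError("L_window exceeds the input length")
        if self.window_stride < 1:
            raise ValueError("window stride below 1 sample; lower the overlap")
        if len(self.cnn_channels) != self.n_B:
            raise ValueError("cnn_channels must list one width per block")
        if self.L_window // self.pool_stride ** self.n_B < 1:
            raise ValueError("too many maxpool stages for the window length")
        t = self.input_len
        for s in self.crnn_pool_strides:
            t //= s
        if t < 4:
            raise ValueError("CRNN pooling collapses the sequence")


def build_windows(signal: np.ndarray, L_window: int,
                  overlap: float) -> np.ndarray:
    """Cut (N, T) signals into overlapping windows -> (N, n_win, L_window).

    n_win = floor((T - L) / stride) + 1 with stride = L * (1 - overlap).
    """
    x = np.atleast_2d(np.asarray(signal))
    T = x.shape[1]
    if L_window > T:
        raise ValueError("window longer than the signal")
    stride = int(round(L_window * (1.0 - overlap)))
    if stride < 1:
        raise ValueError("window stride below 1 sample")
    n_win = (T - L_window) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, L_window, axis=1)
    return win[:, ::stride][:, :n_win].copy()


def dilated_receptive_field(cfg: OxiNetConfig) -> int:
    """Receptive field (in feature steps) of the dilated stack."""
    rf = 1
    for i in range(cfg.n_DB):
        rf += (cfg.K_dilated - 1) * cfg.rate_dilation * 2 ** i
    return rf


class _ConvBlock(nn.Module):
    """n_L x (conv k3 / BN / LeakyReLU) then maxpool, with an additive skip
    (1x1 projection when the channel widths differ)."""

    def __init__(self, c_in, c_out, n_L, pool, alpha, rng, dtype):
        super().__init__()
        convs = []
        c = c_in
        for _ in range(n_L):
            convs.append(nn.Conv1d(c, c_out, 3, rng, padding="same", dtype=dtype))
            convs.append(nn.BatchNorm(c_out, dtype=dtype))
            c = c_out
        self.layers = convs
        self.proj = (nn.Conv1d(c_in, c_out, 1, rng, dtype=dtype)
                     if c_in != c_out else None)
        self.pool = pool
        self.alpha = alpha

    def __call__(self, x: Tensor) -> Tensor:
        h = x
        for i in range(0, len(self.layers), 2):
            h = self.layers[i + 1](self.layers[i](h)).leaky_relu(self.alpha)
        skip = self.proj(x) if self.proj is not None else x
        return nn.maxpool1d(h + skip, self.pool)


class CNNBranch(nn.Module):
    def __init__(self, cfg: OxiNetConfig, rng, dtype):
        super().__init__()
        blocks = []
        c = 1
        for b in range(cfg.n_B):
            blocks.append(_ConvBlock(c, cfg.cnn_channels[b], cfg.n_L,
                                     cfg.pool_stride, cfg.leaky_alpha, rng,
                                     dtype))
            c = cfg.cnn_channels[b]
        self.blocks = blocks
        dil = []
        for i in range(cfg.n_DB):
            dil.append(nn.Conv1d(c if i == 0 else cfg.n_C, cfg.n_C,
                                 cfg.K_dilated, rng,
                                 dilation=cfg.rate_dilation * 2 ** i,
                                 padding="same", dtype=dtype))
        self.dilated = dil
        self.cfg = cfg

    def __call__(self, windows: Tensor) -> Tensor:
        # windows: (N, n_win, L) -> per-window features -> concat along time
        N, n_win, L = windows.data.shape
        h = windows.reshape(N * n_win, 1, L)
        for blk in self.blocks:
            h = blk(h)
        c, lp = h.data.shape[1], h.data.shape[2]
        h = h.reshape(N, n_win, c, lp).transpose(0, 2, 1, 3).reshape(N, c, n_win * lp)
        for conv in self.dilated:
            h = conv(h).leaky_relu(self.cfg.leaky_alpha)
        return h.mean(axis=2)  # global average pool -> (N, n_C)


class CRNNBranch(nn.Module):
    def __init__(self, cfg: OxiNetConfig, rng, dtype):
        super().__init__()
        c = cfg.crnn_channels
        convs = []
        c_in = 1
        for s in cfg.crnn_pool_strides:
            convs.append(nn.Conv1d(c_in, c, cfg.k_CRNN, rng, padding="same",
                                   dtype=dtype))
            convs.append(nn.BatchNorm(c, dtype=dtype))
            c_in = c
        self.convs = convs
        self.pools = list(cfg.crnn_pool_strides)
        self.lstm1 = nn.BiLSTM(c, cfg.n_LSTM, rng, dtype)
        self.lstm2 = nn.BiLSTM(2 * cfg.n_LSTM, cfg.n_LSTM, rng, dtype)
        self.cfg = cfg

    def conv_features(self, x: Tensor) -> Tensor:
        for i, pool in enumerate(self.pools):
            x = self.convs[2 * i + 1](self.convs[2 * i](x)).leaky_relu(
                self.cfg.leaky_alpha)
            x = nn.maxpool1d(x, pool)
        return x

    def __call__(self, x: Tensor) -> Tensor:
        h = self.conv_features(x)          # (N, C, T')
        T = h.data.shape[2]
        steps = [h[:, :, t] for t in range(T)]
        steps, _ = self.lstm1(steps)
        _, final = self.lstm2(steps)
        return final                       # (N, 2 * n_LSTM)


class MetaBranch(nn.Module):
    def __init__(self, cfg: OxiNetConfig, rng, dtype):
        super().__init__()
        self.fc = nn.Linear(2, cfg.N_META, rng, dtype)
        self.alpha = cfg.leaky_alpha

    def __call__(self, meta: Tensor) -> Tensor:
        return self.fc(meta).leaky_relu(self.alpha)


class OxiNet(nn.Module):
    """The full dual-branch model.  forward() returns the main prediction and
    the two auxiliary branch predictions, each of shape (N,)."""

    def __init__(self, cfg: OxiNetConfig, seed: int = 0):
        super().__init__()
        cfg.validate()
        dtype = np.dtype(cfg.dtype).type
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.cnn = CNNBranch(cfg, rng, dtype)
        self.crnn = CRNNBranch(cfg, rng, dtype)
        self.meta = MetaBranch(cfg, rng, dtype)

        w = cfg.n_cnn + cfg.n_crnn + cfg.N_META
        head = []
        self.head_widths = [w]
        for _ in range(cfg.n_classifier):
            head.append(nn.Linear(w, w // 2, rng, dtype))
            head.append(nn.BatchNorm(w // 2, axis=(0,), dtype=dtype))
            head.append(nn.Dropout(cfg.d_classifier, rng))
            w //= 2
            self.head_widths.append(w)
        self.head = head
        self.out = nn.Linear(w, 1, rng, dtype)
        self.aux_cnn = nn.Linear(cfg.n_cnn, 1, rng, dtype)
        self.aux_crnn = nn.Linear(cfg.n_crnn, 1, rng, dtype)
        self.dtype = dtype

    def branch_features(self, x: np.ndarray, meta: np.ndarray):
        cfg = self.cfg
        x = np.atleast_2d(np.asarray(x, self.dtype))
        if x.shape[1] != cfg.input_len:
            raise ValueError(f"expected {cfg.input_len}-sample input, "
                             f"got {x.shape[1]}")
        xs = (x - cfg.input_center) / cfg.input_scale
        windows = Tensor(build_windows(xs, cfg.L_window, cfg.overlap))
        v_cnn = self.cnn(windows)
        v_crnn = self.crnn(Tensor(xs[:, None, :]))
        v_meta = self.meta(Tensor(np.asarray(meta, self.dtype)))
        return v_cnn, v_crnn, v_meta

    def __call__(self, x: np.ndarray, meta: np.ndarray):
        v_cnn, v_crnn, v_meta = self.branch_features(x, meta)
        v_final = concat([v_cnn, v_crnn, v_meta], axis=1)
        h = v_final
        for i in range(0, len(self.head), 3):
            h = self.head[i + 1](self.head[i](h)).leaky_relu(self.cfg.leaky_alpha)
            h = self.head[i + 2](h)
        main = self.out(h).reshape(-1)
        aux_c = self.aux_cnn(v_cnn).reshape(-1)
        aux_r = self.aux_crnn(v_crnn).reshape(-1)
        return main, aux_c, aux_r

    def predict(self, x: np.ndarray, meta: np.ndarray) -> np.ndarray:
        """Deterministic eval-mode main-head prediction (unscaled)."""
        was_training = self.training
        self.eval()
        try:
            main, _, _ = self(x, meta)
        finally:
            self.train(was_training)
        return main.data.copy()


def count_parameters(cfg: OxiNetConfig) -> int:
    """Exact trainable-parameter count of a model built from cfg."""
    return OxiNet(cfg, seed=0).n_parameters()


# ---------------------------------------------------------------------------
# documented small configuration for desk-scale experiments
# ---------------------------------------------------------------------------

def reduced_config() -> OxiNetConfig:
    """A small configuration that trains in minutes on one CPU.

    Window and channel counts are shrunk and the pooling is more aggressive
    than the defaults (the CRNN front end reduces 25200 samples to ~200
    BiLSTM steps); the architecture is otherwise identical.
    """
    return OxiNetConfig(
        L_window=3600, overlap=0.0, n_B=3, n_L=1, cnn_channels=(8, 16, 16),
        pool_stride=4, n_DB=2, n_C=16, K_dilated=5, rate_dilation=2,
        k_CRNN=7, crnn_channels=8, crnn_pool_strides=(16, 8), n_LSTM=16,
        N_META=4, n_classifier=2, d_classifier=0.2,
    )


def save_checkpoint(model: OxiNet, path: str | Path, extra: dict | None = None):
    """Weights as .npz plus a JSON config sidecar."""
    path = Path(path)
    np.savez(path, **model.state_dict())
    sidecar = {"config": asdict(model.cfg)}
    if extra:
        sidecar.update(extra)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2,
                                                    default=list))


def load_checkpoint(path: str | Path) -> tuple[OxiNet, dict]:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg_d = dict(sidecar["config"])
    for key in ("cnn_channels", "crnn_pool_strides"):
        cfg_d[key] = tuple(cfg_d[key])
    model = OxiNet(OxiNetConfig(**cfg_d), seed=0)
    with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as z:
        model.load_state_dict(dict(z))
    return model, sidecar
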