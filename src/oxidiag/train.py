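"""Training of the dual-branch AHI regressor.

The loss is a composite of three mean-squared errors — the aggregated head
and the two auxiliary branch regressors — plus L2 weight regularisation:

    L = L_aggregated + lambda_CNN * L_CNN + lambda_CRNN * L_CRNN + l2 ||w||^2

Both lambda weights start at 1 and are multiplied by 0.8 every four epochs
(equivalently lambda(e) = 0.8 ** floor(e / 4)), so the auxiliary heads guide
early training and fade out.  Two label-preserving augmentations are
applied per batch: jitter (additive white noise over the valid samples,
clipped back to [50, 100]%) and a moving window (the real-signal span is
re-placed at a random offset inside the 7-h frame, redistributing the
padding).  Optimisation uses Adam; the checkpoint with the lowest
validation loss is retained.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .nn import Adam
from .oxinet import OxiNet, OxiNetConfig
from .preprocess import CleanRecord


@dataclass
class TrainConfig:
    lambda_cnn_init: float = 1.0
    lambda_crnn_init: float = 1.0
    decay_every_epochs: int = 4
    decay_factor: float = 0.8
    sigma_noise: float = 0.5    # jitter noise sd, %
    lr: float = 0.005
    epochs: int = 100
    l2_weight: float = 1e-5
    batch_size: int = 16
    seed: int = 0
    test_frac: float = 0.1      # cohort-level test split
    val_frac: float = 0.3       # of the remaining training set
    use_jitter: bool = True
    use_moving_window: bool = True

    def validate(self) -> None:
        if not 0.0 < self.decay_factor <= 1.0:
            raise ValueError("decay_factor must be in (0, 1]")
        if self.sigma_noise < 0:
            raise ValueError("sigma_noise must be nonnegative")


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def _as_tensor(v) -> Tensor:
    return v if isinstance(v, Tensor) else Tensor(np.asarray(v, dtype=float))


def composite_loss(pred_main, pred_cnn, pred_crnn, target, lam_cnn: float,
                   lam_crnn: float, l2_weight: float = 0.0,
                   params: list[Tensor] | None = None) -> Tensor:
    """The three-term MSE loss plus optional L2 penalty (a Tensor scalar)."""
    target = np.asarray(target, dtype=float)

    def _mse(p):
        p = _as_tensor(p)
        d = p - Tensor(target.astype(p.data.dtype))
        return (d * d).mean()

    loss = _mse(pred_main) + lam_cnn * _mse(pred_cnn) + lam_crnn * _mse(pred_crnn)
    if l2_weight and params:
        reg = None
        for p in params:
            term = (p * p).sum()
            reg = term if reg is None else reg + term
        loss = loss + l2_weight * reg
    return loss


def decay_aux_weights(epoch: int, cfg: TrainConfig) -> tuple[float, float]:
    """lambda(e) = init * decay_factor ** floor(e / decay_every_epochs)."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    f = cfg.decay_factor ** (epoch // cfg.decay_every_epochs)
    return cfg.lambda_cnn_init * f, cfg.lambda_crnn_init * f


# ---------------------------------------------------------------------------
# augmentations
# ---------------------------------------------------------------------------

def jitter_augment(spo2: np.ndarray, mask: np.ndarray, sigma_noise: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Additive i.i.d. Gaussian noise over the valid samples, clipped to
    [50, 100]%.  Padding samples are untouched."""
    if sigma_noise < 0:
        raise ValueError("sigma_noise must be nonnegative")
    x = np.array(spo2, dtype=float, copy=True)
    if sigma_noise == 0:
        return x
    noise = rng.normal(0.0, sigma_noise, x.shape)
    x[mask] = np.clip(x[mask] + noise[mask], 50.0, 100.0)
    return x


def moving_window_augment(spo2: np.ndarray, mask: np.ndarray,
                          rng: np.random.Generator,
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Place the real-signal span at a random offset inside the frame.

    The real span is everything up to the last valid sample (padding is the
    all-invalid tail).  With zero padding slack this is the identity.  The
    record's AHI is untouched by construction.
    """
    valid_idx = np.flatnonzero(mask)
    if valid_idx.size == 0:
        return spo2.copy(), mask.copy()
    n_real = int(valid_idx[-1]) + 1
    slack = spo2.size - n_real
    if slack == 0:
        return spo2.copy(), mask.copy()
    off = int(rng.integers(0, slack + 1))
    pad_value = spo2[n_real:].mean() if slack else spo2[mask].mean()
    x = np.full_like(spo2, pad_value)
    m = np.zeros_like(mask)
    x[off:off + n_real] = spo2[:n_real]
    m[off:off + n_real] = mask[:n_real]
    return x, m


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------

def cohort_arrays(records: list[CleanRecord]):
    """Stack non-excluded records into (X, masks, meta_raw, y)."""
    recs = [r for r in records if not r.excluded]
    if any(r.true_ahi is None for r in recs):
        raise ValueError("records need a target AHI")
    X = np.stack([r.spo2 for r in recs]).astype(np.float32)
    M = np.stack([r.validity_mask for r in recs])
    meta = np.stack([[r.age, 1.0 if r.sex == "male" else 0.0] for r in recs])
    y = np.array([r.true_ahi for r in recs], dtype=float)
    return X, M, meta, y


def split_cohort(n: int, test_frac: float, seed: int):
    """Deterministic shuffled (train_idx, test_idx) cohort split."""
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    n_test = int(round(test_frac * n))
    return np.sort(idx[n_test:]), np.sort(idx[:n_test])


@dataclass
class TrainedOxiNet:
    """A trained model plus the normalisation constants it was fit with."""

    model: OxiNet
    y_mean: float
    y_std: float
    age_mean: float
    age_std: float
    history: pd.DataFrame = field(repr=False, default=None)
    best_epoch: int = -1

    def _meta(self, meta_raw: np.ndarray) -> np.ndarray:
        m = np.array(meta_raw, dtype=float, copy=True)
        m[:, 0] = (m[:, 0] - self.age_mean) / max(self.age_std, 1e-9)
        return m

    def predict(self, X: np.ndarray, meta_raw: np.ndarray,
                batch_size: int = 32) -> np.ndarray:
        """Eval-mode AHI estimates (nonnegative) for (N, 25200) signals."""
        X = np.atleast_2d(X)
        meta = self._meta(np.atleast_2d(meta_raw))
        out = []
        for i in range(0, X.shape[0], batch_size):
            z = self.model.predict(X[i:i + batch_size], meta[i:i + batch_size])
            out.append(z * self.y_std + self.y_mean)
        return np.clip(np.concatenate(out), 0.0, None)

    def predict_records(self, records: list[CleanRecord]) -> np.ndarray:
        X, _, meta, _ = cohort_arrays(records)
        return self.predict(X, meta)


def train_model(records: list[CleanRecord], oxinet_cfg: OxiNetConfig,
                train_cfg: TrainConfig, verbose: bool = False,
                ) -> TrainedOxiNet:
    """Train on a cohort of CleanRecords (70/30 train/validation split).

    Returns the model restored to its best-validation-loss checkpoint plus
    the per-epoch loss history.  Raises on divergence (non-finite loss).
    """
    train_cfg.validate()
    X, M, meta_raw, y = cohort_arrays(records)
    n = X.shape[0]
    if n < 50:
        raise ValueError("need at least 50 non-excluded records to train")

    rng = np.random.default_rng(train_cfg.seed)
    perm = rng.permutation(n)
    n_val = int(round(train_cfg.val_frac * n))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]

    y_mean, y_std = float(y[tr_idx].mean()), float(y[tr_idx].std() + 1e-9)
    age_mean = float(meta_raw[tr_idx, 0].mean())
    age_std = float(meta_raw[tr_idx, 0].std() + 1e-9)
    meta = meta_raw.copy()
    meta[:, 0] = (meta[:, 0] - age_mean) / max(age_std, 1e-9)
    yz = (y - y_mean) / y_std

    model = OxiNet(oxinet_cfg, seed=train_cfg.seed)
    opt = Adam(model.parameters(), lr=train_cfg.lr)
    history = []
    best = (np.inf, None, -1)

    for epoch in range(train_cfg.epochs):
        lam_cnn, lam_crnn = decay_aux_weights(epoch, train_cfg)
        model.train()
        order = rng.permutation(tr_idx)
        ep_losses = []
        for start in range(0, order.size, train_cfg.batch_size):
            bidx = order[start:start + train_cfg.batch_size]
            if bidx.size < 2:
                continue  # batch norm needs more than one row
            xb = np.empty((bidx.size, X.shape[1]), dtype=np.float32)
            for j, i in enumerate(bidx):
                x_i, m_i = X[i], M[i]
                if train_cfg.use_moving_window:
                    x_i, m_i = moving_window_augment(x_i, m_i, rng)
                if train_cfg.use_jitter and train_cfg.sigma_noise > 0:
                    x_i = jitter_augment(x_i, m_i, train_cfg.sigma_noise, rng)
                xb[j] = x_i
            main, aux_c, aux_r = model(xb, meta[bidx])
            loss = composite_loss(main, aux_c, aux_r, yz[bidx], lam_cnn,
                                  lam_crnn, train_cfg.l2_weight,
                                  model.parameters())
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"training diverged at epoch {epoch} (loss "
                    f"{loss.item()}); lower the learning rate")
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_losses.append(loss.item())

        # validation on the main head only, eval mode
        model.eval()
        val_pred = []
        for start in range(0, val_idx.size, 32):
            vi = val_idx[start:start + 32]
            val_pred.append(model.predict(X[vi], meta[vi]))
        val_pred = np.concatenate(val_pred) if val_pred else np.zeros(0)
        val_loss = float(np.mean((val_pred - yz[val_idx]) ** 2)) if val_idx.size else np.nan
        train_loss = float(np.mean(ep_losses)) if ep_losses else np.nan
        history.append({"epoch": epoch, "train_loss": train_loss,
                        "val_loss": val_loss, "lambda": lam_cnn})
        if verbose:
            print(f"epoch {epoch:3d}  train {train_loss:.4f}  "
                  f"val {val_loss:.4f}  lambda {lam_cnn:.3f}")
        if np.isfinite(val_loss) and val_loss < best[0]:
            best = (val_loss, copy.deepcopy(model.state_dict()), epoch)

    if best[1] is not None:
        model.load_state_dict(best[1])
    model.eval()
    return TrainedOxiNet(model=model, y_mean=y_mean, y_std=y_std,
                         age_mean=age_mean, age_std=age_std,
                         history=pd.DataFrame(history), best_epoch=best[2])
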