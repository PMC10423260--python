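"""Feature-occlusion explainability for the overnight AHI regressor.

Each contiguous region of the signal (a window of ``L_region`` seconds,
slid with a stride of ``L_region / 2`` by default) is replaced by a baseline
value — the overall mean of the signal over its valid samples — and the
importance score of the region is the drop in predicted AHI:

    score_i = f(x) - f(x with window_i <- mean(x))

A positive score means the region pushed the prediction up (the model saw
apnea-like structure there); scores near zero mean the region was
uninformative.  The sign is retained: for a regression target it carries
information.  L_region defaults to 120 s, the scale of one to a few apnea
events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .desat import DesaturationEvent


@dataclass
class ExplainConfig:
    L_region: int = 120          # seconds
    stride: int | None = None    # defaults to L_region // 2
    baseline_mode: str = "record_mean"
    batch_size: int = 16

    def resolved_stride(self) -> int:
        s = self.stride if self.stride is not None else self.L_region // 2
        if s < 1 or s > self.L_region:
            raise ValueError("stride must be in [1, L_region]")
        if self.L_region < 2:
            raise ValueError("L_region must be >= 2 s")
        return s


def occlusion_windows(n_samples: int, cfg: ExplainConfig) -> np.ndarray:
    """Window start indices; trace length = floor((T - L)/stride) + 1."""
    stride = cfg.resolved_stride()
    if cfg.L_region > n_samples:
        raise ValueError("L_region exceeds the signal length")
    n_win = (n_samples - cfg.L_region) // stride + 1
    return np.arange(n_win) * stride


def feature_occlusion(predict_fn, spo2: np.ndarray,
                      mask: np.ndarray | None = None,
                      cfg: ExplainConfig | None = None) -> pd.DataFrame:
    """Importance trace of one record under any predictor.

    Parameters
    ----------
    predict_fn : callable mapping an (N, T) signal batch to (N,) predictions
        (e.g. a trained model's prediction closure, or a surrogate).
    spo2, mask : the preprocessed record; the occlusion baseline is the mean
        over valid samples (the padding already carries that value).

    Returns a DataFrame with columns start_s, score and score_norm (min-max
    normalised per record, constant traces normalising to 0).
    """
    cfg = cfg or ExplainConfig()
    spo2 = np.asarray(spo2, dtype=float)
    if mask is None:
        mask = np.ones(spo2.size, dtype=bool)
    starts = occlusion_windows(spo2.size, cfg)
    baseline = float(spo2[mask].mean()) if mask.any() else float(spo2.mean())

    f_x = float(np.asarray(predict_fn(spo2[None, :])).reshape(-1)[0])
    scores = np.empty(starts.size)
    bs = cfg.batch_size
    for i in range(0, starts.size, bs):
        chunk = starts[i:i + bs]
        batch = np.repeat(spo2[None, :], chunk.size, axis=0)
        for j, s in enumerate(chunk):
            batch[j, s:s + cfg.L_region] = baseline
        scores[i:i + bs] = f_x - np.asarray(predict_fn(batch)).reshape(-1)

    span = scores.max() - scores.min()
    norm = (scores - scores.min()) / span if span > 0 else np.zeros_like(scores)
    return pd.DataFrame({"start_s": starts, "score": scores,
                         "score_norm": norm})


def overlay_report(trace: pd.DataFrame, events: list[DesaturationEvent],
                   cfg: ExplainConfig | None = None,
                   plot_path=None) -> pd.DataFrame:
    """Join the importance trace with detected desaturations.

    Adds n_overlapping_desats: how many events intersect each window.
    Optionally writes a two-panel figure (signal scores + event overlay).
    """
    cfg = cfg or ExplainConfig()
    L = cfg.L_region
    counts = []
    for s in trace["start_s"].to_numpy():
        e0, e1 = s, s + L
        counts.append(sum(1 for ev in events
                          if ev.start_s < e1 and e0 < ev.end_s))
    out = trace.copy()
    out["n_overlapping_desats"] = counts
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(10, 3))
        ax.plot(out["start_s"] / 3600.0, out["score"], lw=0.8,
                label="occlusion score")
        for ev in events:
            ax.axvspan(ev.start_s / 3600.0, ev.end_s / 3600.0, alpha=0.15,
                       color="tab:red", lw=0)
        ax.set_xlabel("time (h)")
        ax.set_ylabel("importance (AHI units)")
        ax.legend(loc="upper right", fontsize=8)
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return out


def model_predict_fn(trained, meta_row: np.ndarray):
    """Closure over a TrainedOxiNet for one record's metadata."""
    meta_row = np.asarray(meta_row, dtype=float)

    def _fn(batch: np.ndarray) -> np.ndarray:
        meta = np.repeat(meta_row[None, :], batch.shape[0], axis=0)
        return trained.predict(batch, meta)
    return _fn
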