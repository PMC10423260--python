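"""Synthetic overnight oximetry with exact ground-truth AHI.

The generator produces 1-Hz SpO2 records that carry the features the
estimation pipeline has to cope with: a personal baseline saturation near
96-97%, transient desaturation events of known depth and duration (>=3% and
10-120 s, with severe events typically in the 30-45 s range), clustering of
events into bursts, a sleep/wake hypnogram with initial and terminal wake and
intra-sleep fragments, additive Gaussian sensor noise, and short
non-physiological artifact excursions below 50%.

Because every event is planted, the true AHI of a record is exact:
(number of planted events) / (hours actually asleep).  This lets every
downstream stage — the delta filter, the desaturation detector, the feature
baselines, and the deep regressor — be tested against known ground truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .desat import DesaturationEvent

EPOCH_S = 30           # hypnogram epoch length, seconds
MIN_EVENT_GAP_S = 5    # minimum spacing between placed events


class GenerationError(RuntimeError):
    """Raised when a record's drawn event load cannot be placed."""


@dataclass
class SimConfig:
    """Study conditions of the synthetic cohort.

    Rates are per hour, durations in seconds, SpO2 quantities in %.
    """

    seed: int = 0
    n_records: int = 50
    record_hours: float | tuple[float, float] = 6.0  # scalar or uniform range
    baseline_spo2_mean: float = 96.5
    baseline_spo2_sd: float = 0.8
    # AHI drawn from a lognormal (median ~ exp(mu)), truncated at ahi_max,
    # with a point mass at 0 for event-free sleepers
    ahi_log_mu: float = 2.3
    ahi_log_sigma: float = 0.9
    ahi_max: float = 60.0
    zero_ahi_prob: float = 0.05
    # desaturation morphology: depth >= 3%, duration in [10, 120] s;
    # severe desaturations typically last 30-45 s
    desat_depth_mean: float = 5.5
    desat_depth_sd: float = 1.5
    desat_depth_min: float = 3.0
    desat_depth_max: float = 12.0
    desat_duration_mean: float = 38.0
    desat_duration_sd: float = 12.0
    desat_duration_min: float = 10.0
    desat_duration_max: float = 120.0
    cluster_prob: float = 0.25      # an event seeds a burst of 3-8
    burst_size: tuple[int, int] = (3, 8)
    burst_gap_s: tuple[float, float] = (20.0, 60.0)
    noise_sd: float = 0.5           # Gaussian sensor noise, % per sample
    artifact_rate: float = 1.0      # artifacts per hour, 1-5 samples < 50%
    sleep_efficiency: float = 0.85
    age_range: tuple[float, float] = (40.0, 80.0)
    sex_ratio: float = 0.5          # fraction male

    def validate(self) -> None:
        hours = self.record_hours
        lo = hours[0] if isinstance(hours, (tuple, list)) else hours
        if lo <= 0:
            raise ValueError("record_hours must be positive")
        if self.desat_depth_min < 3.0:
            raise ValueError("desaturation depth threshold is >= 3%")
        if not (0.0 <= self.sleep_efficiency <= 1.0):
            raise ValueError("sleep_efficiency must be in [0, 1]")
        for name in ("noise_sd", "artifact_rate", "desat_duration_min",
                     "desat_duration_max", "ahi_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class SimRecord:
    """One synthetic overnight recording with exact ground truth."""

    record_id: str
    spo2: np.ndarray            # 1-Hz, %
    hypnogram: np.ndarray       # per-30-s epoch, 1 = sleep, 0 = wake
    events: list[DesaturationEvent]
    true_ahi: float             # events per hour of actual sleep, exact
    age: float
    sex: str                    # "male" | "female"
    baseline_spo2: float
    sampling_rate: float = 1.0

    @property
    def sleep_hours(self) -> float:
        return float(self.hypnogram.sum()) * EPOCH_S / 3600.0


# ---------------------------------------------------------------------------
# hypnogram
# ---------------------------------------------------------------------------

def simulate_hypnogram(cfg: SimConfig, rng: np.random.Generator,
                       record_hours: float | None = None) -> np.ndarray:
    """Sleep/wake epoch labels with realistic wake placement.

    The wake budget implied by ``sleep_efficiency`` is spent mostly at the
    record edges (sleep latency and final awakening) with the remainder
    scattered as single-epoch intra-sleep arousals; the realized sleep
    fraction is exact by construction.
    """
    hours = record_hours
    if hours is None:
        hours = (cfg.record_hours if not isinstance(cfg.record_hours, (tuple, list))
                 else float(rng.uniform(*cfg.record_hours)))
    if hours <= 0:
        raise ValueError("record duration must be positive")
    n = int(round(hours * 3600 / EPOCH_S))
    eff = cfg.sleep_efficiency
    if eff >= 1.0:
        return np.ones(n, dtype=np.int8)
    if eff <= 0.0:
        return np.zeros(n, dtype=np.int8)

    labels = np.ones(n, dtype=np.int8)
    wake_total = int(round((1.0 - eff) * n))
    wake_total = min(wake_total, n - 1)
    w0 = max(1, int(round(0.6 * wake_total)))
    w1 = max(1, int(round(0.15 * wake_total)))
    if w0 + w1 > wake_total:
        w0, w1 = wake_total, 0
    ws = wake_total - w0 - w1
    labels[:w0] = 0
    if w1:
        labels[n - w1:] = 0
    # scatter single-epoch arousals, keeping the first and last 10 sleep
    # epochs intact so the 5-min-run onset/offset rule anchors at the edges
    interior = np.arange(w0 + 10, n - w1 - 10)
    if ws > 0 and interior.size > 0:
        ws = min(ws, interior.size)
        picks = rng.choice(interior, size=ws, replace=False)
        labels[picks] = 0
    return labels


def _sleep_segments(hypnogram: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous sleep runs as (start_s, end_s) in record seconds."""
    segs = []
    padded = np.concatenate([[0], hypnogram, [0]])
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    for s, e in zip(starts, ends):
        segs.append((int(s) * EPOCH_S, int(e) * EPOCH_S))
    return segs


# ---------------------------------------------------------------------------
# event placement
# ---------------------------------------------------------------------------

def _draw_events(cfg: SimConfig, n_events: int,
                 rng: np.random.Generator) -> list[tuple[float, float]]:
    """(duration_s, depth_pct) pairs for n_events desaturations."""
    dur = rng.normal(cfg.desat_duration_mean, cfg.desat_duration_sd, n_events)
    dur = np.clip(dur, cfg.desat_duration_min, cfg.desat_duration_max)
    depth = rng.normal(cfg.desat_depth_mean, cfg.desat_depth_sd, n_events)
    depth = np.clip(depth, cfg.desat_depth_min, cfg.desat_depth_max)
    return list(zip(np.round(dur).astype(int).tolist(), depth.tolist()))


def place_events(cfg: SimConfig, hypnogram: np.ndarray, n_events: int,
                 rng: np.random.Generator,
                 record_id: str = "?") -> list[DesaturationEvent]:
    """Place n_events desaturations inside sleep, without overlap.

    Events are first grouped into bursts (with probability ``cluster_prob``
    an event seeds a run of 3-8 back-to-back events separated by 20-60 s
    recovery gaps); bursts are assigned to sleep segments by free capacity
    and spread within a segment by Dirichlet-distributed gaps, which yields
    Poisson-process-like spacing conditioned on the count.
    """
    if n_events == 0:
        return []
    specs = _draw_events(cfg, n_events, rng)

    # group into bursts
    bursts: list[list[tuple[float, float]]] = []
    gaps_within: list[list[int]] = []
    i = 0
    while i < n_events:
        if rng.random() < cfg.cluster_prob and n_events - i >= cfg.burst_size[0]:
            b = int(rng.integers(cfg.burst_size[0], cfg.burst_size[1] + 1))
            b = min(b, n_events - i)
        else:
            b = 1
        bursts.append(specs[i:i + b])
        gaps_within.append([int(rng.uniform(*cfg.burst_gap_s))
                            for _ in range(b - 1)])
        i += b

    burst_len = [sum(d for d, _ in bl) + sum(g)
                 for bl, g in zip(bursts, gaps_within)]
    segments = _sleep_segments(hypnogram)
    if not segments:
        raise GenerationError(f"record {record_id}: no sleep to place events in")
    free = [e - s for s, e in segments]
    assign: list[list[int]] = [[] for _ in segments]
    # largest bursts first so fragmentation does not strand them
    order = sorted(range(len(bursts)), key=lambda bi: -burst_len[bi])
    for bi in order:
        need = burst_len[bi] + 2 * MIN_EVENT_GAP_S
        capacity = np.array([f - need for f in free], dtype=float)
        ok = capacity >= 0
        if not ok.any():
            raise GenerationError(
                f"record {record_id}: cannot place {n_events} events "
                f"({sum(burst_len)} s of events) into "
                f"{sum(e - s for s, e in segments)} s of sleep")
        w = np.where(ok, np.maximum(capacity, 1.0), 0.0)
        si = int(rng.choice(len(segments), p=w / w.sum()))
        assign[si].append(bi)
        free[si] -= burst_len[bi] + MIN_EVENT_GAP_S

    events = _layout(bursts, gaps_within, burst_len, segments, assign, rng,
                     record_id)
    events.sort(key=lambda e: e.start_s)
    return events


def _layout(bursts, gaps_within, burst_len, segments, assign, rng, record_id):

    events: list[DesaturationEvent] = []
    for (seg_start, seg_end), bis in zip(segments, assign):
        if not bis:
            continue
        total = sum(burst_len[bi] for bi in bis)
        slack = (seg_end - seg_start) - total - MIN_EVENT_GAP_S * (len(bis) + 1)
        if slack < 0:
            raise GenerationError(f"record {record_id}: segment overflow")
        w = rng.exponential(1.0, len(bis) + 1)
        gaps = slack * w / w.sum()
        t = seg_start
        for k, bi in enumerate(bis):
            t += MIN_EVENT_GAP_S + gaps[k]
            pos = int(t)
            for j, (dur, depth) in enumerate(bursts[bi]):
                dur = int(dur)
                events.append(_planted_event(pos, dur, depth))
                pos += dur
                if j < len(gaps_within[bi]):
                    pos += gaps_within[bi][j]
            t = pos
    return events


def _planted_event(start: int, dur: int, depth: float) -> DesaturationEvent:
    # trapezoidal dip: 1/3 descent, 1/3 plateau, 1/3 recovery
    return DesaturationEvent(start_s=start, end_s=start + dur, depth=depth,
                             length=dur, area=depth * dur * 2.0 / 3.0,
                             slope_desc=depth / max(dur / 3.0, 1.0))


# ---------------------------------------------------------------------------
# signal rendering
# ---------------------------------------------------------------------------

def render_spo2(events: list[DesaturationEvent], hypnogram: np.ndarray,
                cfg: SimConfig, rng: np.random.Generator,
                baseline: float | None = None) -> np.ndarray:
    """Render the 1-Hz SpO2 series: baseline + dips + noise + artifacts.

    Each event is a trapezoid: linear descent over the first third of its
    duration, a plateau at (baseline - depth), and a linear recovery.  The
    physiological signal is clipped to [50, 100]; artifact samples are then
    injected below 50% so the delta filter has something to remove.
    """
    n = hypnogram.size * EPOCH_S
    if baseline is None:
        baseline = float(rng.normal(cfg.baseline_spo2_mean, cfg.baseline_spo2_sd))
    x = np.full(n, baseline, dtype=float)
    for ev in events:
        dur = ev.end_s - ev.start_s
        third = max(dur // 3, 1)
        t0, t1 = ev.start_s, min(ev.end_s, n)
        shape = np.zeros(t1 - t0)
        down = np.linspace(0, ev.depth, third + 1)[1:]
        up = np.linspace(ev.depth, 0, (dur - 2 * third) + 1)[1:]
        prof = np.concatenate([down, np.full(dur - third - up.size, ev.depth), up])
        shape[:] = prof[: t1 - t0]
        x[t0:t1] -= shape
    if cfg.noise_sd > 0:
        x += rng.normal(0.0, cfg.noise_sd, n)
    x = np.clip(x, 50.0, 100.0)
    # non-physiological artifacts: 1-5 sample excursions below 50%
    hours = n / 3600.0
    n_art = rng.poisson(cfg.artifact_rate * hours)
    for _ in range(n_art):
        a0 = int(rng.integers(0, max(n - 5, 1)))
        alen = int(rng.integers(1, 6))
        x[a0:a0 + alen] = rng.uniform(20.0, 45.0, min(alen, n - a0))
    return x


# ---------------------------------------------------------------------------
# records and cohorts
# ---------------------------------------------------------------------------

def simulate_record(cfg: SimConfig, rng: np.random.Generator,
                    record_id: str = "rec") -> SimRecord:
    """One synthetic record; true_ahi = planted events / sleep hours, exact."""
    cfg.validate()
    hypnogram = simulate_hypnogram(cfg, rng)
    sleep_hours = float(hypnogram.sum()) * EPOCH_S / 3600.0

    if sleep_hours > 0 and rng.random() >= cfg.zero_ahi_prob:
        ahi_drawn = float(np.exp(rng.normal(cfg.ahi_log_mu, cfg.ahi_log_sigma)))
        ahi_drawn = min(ahi_drawn, cfg.ahi_max)
    else:
        ahi_drawn = 0.0
    n_events = int(round(ahi_drawn * sleep_hours))
    # a very dense draw may not fit into fragmented sleep; shed events until
    # it places (true_ahi is recomputed from what was actually planted)
    events = None
    for _ in range(40):
        try:
            events = place_events(cfg, hypnogram, n_events, rng, record_id)
            break
        except GenerationError:
            if n_events == 0:
                raise
            n_events = max(0, int(n_events * 0.9) - 1)
    if events is None:
        raise GenerationError(f"record {record_id}: event placement failed")
    true_ahi = (len(events) / sleep_hours) if sleep_hours > 0 else 0.0

    spo2 = render_spo2(events, hypnogram, cfg, rng)
    age = float(rng.uniform(*cfg.age_range))
    sex = "male" if rng.random() < cfg.sex_ratio else "female"
    return SimRecord(record_id=record_id, spo2=spo2, hypnogram=hypnogram,
                     events=events, true_ahi=true_ahi, age=age, sex=sex,
                     baseline_spo2=float(np.median(spo2)))


def simulate_cohort(cfg: SimConfig) -> tuple[list[SimRecord], pd.DataFrame]:
    """Generate cfg.n_records records; returns (records, manifest).

    Per-record generators are spawned from a single SeedSequence, so the
    whole cohort is bit-identical for a given cfg.seed.
    """
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.n_records)
    records = []
    rows = []
    for i, child in enumerate(children):
        rid = f"rec{i:04d}"
        rec = simulate_record(cfg, np.random.default_rng(child), record_id=rid)
        records.append(rec)
        rows.append({"record_id": rid, "true_ahi": rec.true_ahi,
                     "n_events": len(rec.events),
                     "sleep_hours": rec.sleep_hours,
                     "age": rec.age, "sex": rec.sex, "seed": cfg.seed})
    return records, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# on-disk layout
# ---------------------------------------------------------------------------

def write_cohort(records: list[SimRecord], manifest: pd.DataFrame,
                 out_dir: str | Path) -> None:
    """CSV layout: <id>_spo2.csv (time_s,spo2), <id>_hypnogram.csv
    (epoch,label), <id>_events.csv, and manifest.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rec in records:
        n = rec.spo2.size
        pd.DataFrame({"time_s": np.arange(n), "spo2": rec.spo2}).to_csv(
            out / f"{rec.record_id}_spo2.csv", index=False)
        pd.DataFrame({"epoch": np.arange(rec.hypnogram.size),
                      "label": rec.hypnogram}).to_csv(
            out / f"{rec.record_id}_hypnogram.csv", index=False)
        from .desat import events_to_frame
        events_to_frame(rec.events, rec.record_id).to_csv(
            out / f"{rec.record_id}_events.csv", index=False)
    manifest.to_csv(out / "manifest.csv", index=False)


def read_record(data_dir: str | Path, record_id: str,
                manifest_row: dict | None = None):
    """Read one record back from the CSV layout written by write_cohort."""
    d = Path(data_dir)
    spo2 = pd.read_csv(d / f"{record_id}_spo2.csv")["spo2"].to_numpy(float)
    hyp = pd.read_csv(d / f"{record_id}_hypnogram.csv")["label"].to_numpy(np.int8)
    age = sex = None
    if manifest_row is not None:
        age, sex = manifest_row.get("age"), manifest_row.get("sex")
    return spo2, hyp, age, sex


def config_to_json(cfg: SimConfig) -> str:
    return json.dumps(asdict(cfg), default=list, sort_keys=True)
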