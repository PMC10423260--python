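"""Preprocessing and exclusion of overnight oximetry records.

Stages, in order:

1. resample to 1 Hz (block means for higher rates),
2. delta filter: mark non-physiological samples invalid (out of [50, 100]%
   or changing faster than 4 percentage points per second),
3. interpolate short invalid gaps (1-2 samples) linearly; longer gaps are
   filled by carrying the last valid value forward but stay masked invalid,
4. estimate sleep bounds from the hypnogram: onset is the start of the first
   run of >= 10 consecutive sleep-labeled 30-s epochs (5 min), offset the end
   of the last such run; TST-hat is the span between them,
5. exclude records with technical faults, TST-hat < 4 h, or age < 18 y
   (boundaries inclusive for retention: TST-hat = 4.0 h and age = 18 stay),
6. crop to [onset, offset] and pad or truncate to a fixed 7-h frame (25200
   samples); padding uses the per-record mean SpO2 and is masked invalid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

FRAME_SAMPLES = 25200       # 7 h at 1 Hz
EPOCH_S = 30
MIN_SLEEP_RUN_EPOCHS = 10   # 5 minutes of consecutive sleep
SPO2_RANGE = (50.0, 100.0)
DELTA_MAX_PCT_PER_S = 4.0   # classic delta-filter motion threshold
MIN_TST_HOURS = 4.0
MIN_AGE_YEARS = 18.0

EXCLUSION_REASONS = ("technical_fault", "tst_lt_4", "age_lt_18")


@dataclass
class RawRecord:
    """An as-recorded oximetry record prior to cleaning."""

    record_id: str
    spo2: np.ndarray
    sampling_rate: float
    hypnogram: np.ndarray       # 30-s epochs; 0 = wake, nonzero = sleep
    age: float
    sex: str


@dataclass
class CleanRecord:
    """A preprocessed record in the fixed 7-h frame."""

    record_id: str
    spo2: np.ndarray            # length FRAME_SAMPLES when not excluded
    validity_mask: np.ndarray   # False over padding / unrecoverable samples
    sleep_onset: int            # seconds from original record start
    sleep_offset: int
    tst_hat: float              # hours
    age: float
    sex: str
    excluded: bool = False
    exclusion_reason: str | None = None
    true_ahi: float | None = None   # carried through for synthetic records
    is_clean: bool = True

    @property
    def real_samples(self) -> int:
        return int(self.validity_mask.sum())


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def resample_to_1hz(spo2: np.ndarray, sampling_rate: float) -> np.ndarray:
    """Resample to 1 Hz by averaging each 1-s block.

    1-Hz input is returned unchanged.  Rates other than 1 or 16 Hz are
    accepted with a warning; a trailing partial block is dropped.
    """
    spo2 = np.asarray(spo2, dtype=float)
    if spo2.size == 0:
        return spo2
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    if sampling_rate == 1:
        return spo2
    if sampling_rate not in (1, 16):
        warnings.warn(f"unusual sampling rate {sampling_rate} Hz; "
                      "resampling by 1-s block means", stacklevel=2)
    block = int(round(sampling_rate))
    n = (spo2.size // block) * block
    return spo2[:n].reshape(-1, block).mean(axis=1)


def delta_filter(spo2: np.ndarray,
                 valid_range: tuple[float, float] = SPO2_RANGE,
                 max_delta: float = DELTA_MAX_PCT_PER_S,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Mark non-physiological samples invalid.

    A sample is invalid if outside ``valid_range`` or if its rate of change
    relative to the previous *valid* sample exceeds ``max_delta`` %/s.
    Returns (spo2, validity_mask); the signal itself is not modified here.
    """
    spo2 = np.asarray(spo2, dtype=float)
    n = spo2.size
    mask = np.ones(n, dtype=bool)
    lo, hi = valid_range
    last_val = None
    last_idx = -1
    for i in range(n):
        v = spo2[i]
        ok = (lo <= v <= hi) and np.isfinite(v)
        if ok and last_val is not None:
            rate = abs(v - last_val) / (i - last_idx)
            ok = rate <= max_delta
        mask[i] = ok
        if ok:
            last_val, last_idx = v, i
    return spo2, mask


def interpolate_short_gaps(spo2: np.ndarray, mask: np.ndarray,
                           max_gap: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Fill invalid runs: linear interpolation for runs of 1-2 samples
    (which then become valid), carry-forward for longer runs (still masked).

    A leading invalid run is filled with the first valid value and a trailing
    run with the last valid value; both stay masked unless short and flanked.
    """
    spo2 = np.asarray(spo2, dtype=float).copy()
    mask = np.asarray(mask, dtype=bool).copy()
    n = spo2.size
    if mask.all():
        return spo2, mask
    if not mask.any():
        raise TechnicalFault("all samples non-physiological")

    valid_idx = np.flatnonzero(mask)
    # leading / trailing fills
    first, last = valid_idx[0], valid_idx[-1]
    spo2[:first] = spo2[first]
    spo2[last + 1:] = spo2[last]

    # interior runs
    i = first
    while i <= last:
        if mask[i]:
            i += 1
            continue
        j = i
        while j <= last and not mask[j]:
            j += 1
        run = j - i
        a, b = spo2[i - 1], spo2[j]  # flanking valid samples
        if run <= max_gap:
            spo2[i:j] = np.linspace(a, b, run + 2)[1:-1]
            mask[i:j] = True
        else:
            spo2[i:j] = a  # carry-forward; mask stays False
        i = j
    return spo2, mask


def estimate_sleep_bounds(hypnogram: np.ndarray,
                          min_run: int = MIN_SLEEP_RUN_EPOCHS,
                          ) -> tuple[int, int, float]:
    """(sleep_onset_s, sleep_offset_s, tst_hat_hours) from epoch labels.

    Onset is the start of the first run of >= min_run consecutive sleep
    epochs; offset the end of the last such run.  Any non-wake label counts
    as sleep.  With no qualifying run, returns (0, 0, 0.0): the record is
    excluded downstream, not an error here.
    """
    hyp = np.asarray(hypnogram)
    if hyp.size == 0:
        return 0, 0, 0.0
    sleep = (hyp != 0).astype(int)
    padded = np.concatenate([[0], sleep, [0]])
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    runs = [(s, e) for s, e in zip(starts, ends) if e - s >= min_run]
    if not runs:
        return 0, 0, 0.0
    onset = int(runs[0][0]) * EPOCH_S
    offset = int(runs[-1][1]) * EPOCH_S
    return onset, offset, (offset - onset) / 3600.0


class TechnicalFault(RuntimeError):
    """Unusable signal (empty or entirely non-physiological)."""


def apply_exclusion_criteria(tst_hat: float, age: float,
                             technical_fault: bool = False,
                             ) -> tuple[bool, str | None]:
    """Exclusion flag + reason with precedence
    technical_fault > tst_lt_4 > age_lt_18; boundaries retained."""
    if technical_fault:
        return True, "technical_fault"
    if tst_hat < MIN_TST_HOURS:
        return True, "tst_lt_4"
    if age < MIN_AGE_YEARS:
        return True, "age_lt_18"
    return False, None


def pad_or_truncate(spo2: np.ndarray, mask: np.ndarray, sleep_onset: int,
                    sleep_offset: int) -> tuple[np.ndarray, np.ndarray]:
    """Crop to [onset, offset] and fit into the 7-h frame.

    Shorter spans are right-padded with the per-record mean SpO2 (over valid
    samples) and masked invalid; longer spans keep their first 7 h.  The mean
    is the same value later used as the occlusion baseline, which makes the
    padding neutral to the model.
    """
    seg = spo2[sleep_onset:sleep_offset]
    seg_mask = mask[sleep_onset:sleep_offset]
    if seg.size >= FRAME_SAMPLES:
        return seg[:FRAME_SAMPLES].copy(), seg_mask[:FRAME_SAMPLES].copy()
    pad_value = float(seg[seg_mask].mean()) if seg_mask.any() else float(seg.mean())
    out = np.full(FRAME_SAMPLES, pad_value)
    out_mask = np.zeros(FRAME_SAMPLES, dtype=bool)
    out[:seg.size] = seg
    out_mask[:seg.size] = seg_mask
    return out, out_mask


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def preprocess_record(raw: RawRecord | CleanRecord,
                      true_ahi: float | None = None) -> CleanRecord:
    """Run all stages on a raw record.  A CleanRecord passes through
    unchanged (idempotence)."""
    if isinstance(raw, CleanRecord):
        return raw

    fault = False
    spo2 = np.asarray(raw.spo2, dtype=float)
    mask = np.zeros(0, dtype=bool)
    try:
        spo2 = resample_to_1hz(spo2, raw.sampling_rate)
        if spo2.size == 0:
            raise TechnicalFault("empty signal")
        spo2, mask = delta_filter(spo2)
        if not mask.any():
            raise TechnicalFault("all samples non-physiological")
        spo2, mask = interpolate_short_gaps(spo2, mask)
    except TechnicalFault:
        fault = True

    onset, offset, tst_hat = (estimate_sleep_bounds(raw.hypnogram)
                              if not fault else (0, 0, 0.0))
    excluded, reason = apply_exclusion_criteria(tst_hat, raw.age,
                                                technical_fault=fault)
    if excluded:
        return CleanRecord(record_id=raw.record_id,
                           spo2=np.zeros(0), validity_mask=np.zeros(0, bool),
                           sleep_onset=onset, sleep_offset=offset,
                           tst_hat=tst_hat, age=raw.age, sex=raw.sex,
                           excluded=True, exclusion_reason=reason,
                           true_ahi=true_ahi)
    out, out_mask = pad_or_truncate(spo2, mask, onset, offset)
    return CleanRecord(record_id=raw.record_id, spo2=out,
                       validity_mask=out_mask, sleep_onset=onset,
                       sleep_offset=offset, tst_hat=tst_hat, age=raw.age,
                       sex=raw.sex, true_ahi=true_ahi)


def preprocess_cohort(raws, true_ahis=None) -> tuple[list[CleanRecord], "pd.DataFrame"]:
    """Preprocess a list of RawRecords; returns (clean records incl. excluded,
    exclusion log DataFrame)."""
    import pandas as pd

    if true_ahis is None:
        true_ahis = [None] * len(raws)
    cleans = [preprocess_record(r, t) for r, t in zip(raws, true_ahis)]
    log = pd.DataFrame([
        {"record_id": c.record_id, "excluded": c.excluded,
         "reason": c.exclusion_reason or "", "tst_hat": c.tst_hat,
         "age": c.age}
        for c in cleans
    ])
    return cleans, log


def sim_to_raw(rec) -> RawRecord:
    """Adapter: a synthetic SimRecord viewed as an as-recorded RawRecord."""
    return RawRecord(record_id=rec.record_id, spo2=rec.spo2, sampling_rate=1.0,
                     hypnogram=rec.hypnogram, age=rec.age, sex=rec.sex)
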