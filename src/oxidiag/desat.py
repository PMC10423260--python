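"""Rule-based oxygen-desaturation detection and the ODI.

A desaturation is a transient drop of SpO2 below a running local baseline.
The detector operationalises the common published rule: the baseline at time
t is the maximum valid SpO2 over the preceding 100 s; an event opens when the
signal falls at least `threshold_pct` below that baseline, and closes when it
recovers to within 1 percentage point of the baseline that was in force when
the event opened, or when it reaches `max_len_s`.  The oxygen desaturation
index (ODI) is the number of such events per hour of (estimated) sleep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: seconds of history over which the local baseline (max valid SpO2) is taken
BASELINE_WINDOW_S = 100
#: event closes when the signal recovers to within this many % of baseline
RECOVERY_TOL_PCT = 1.0


@dataclass
class DesaturationEvent:
    """One desaturation: [start_s, end_s) against a local baseline."""

    start_s: int
    end_s: int
    depth: float       # % drop from local baseline at the nadir
    length: int        # seconds
    area: float        # %*s integrated below baseline
    slope_desc: float  # %/s of the descent (depth / time-to-nadir)

    def overlaps(self, other: "DesaturationEvent") -> bool:
        return self.start_s < other.end_s and other.start_s < self.end_s


def _running_baseline(spo2: np.ndarray, mask: np.ndarray,
                      window_s: int = BASELINE_WINDOW_S) -> np.ndarray:
    """Max of valid samples over the preceding `window_s` seconds.

    For the first samples the window is expanding.  Positions whose window
    holds no valid sample inherit the last defined baseline (or the first
    defined one at the start).
    """
    n = spo2.size
    x = np.where(mask, spo2, -np.inf)
    base = np.full(n, -np.inf)
    # monotonic deque sliding maximum, O(n)
    from collections import deque

    dq: deque[int] = deque()
    for i in range(n):
        j = i - 1  # baseline strictly precedes i
        if j >= 0:
            while dq and x[dq[-1]] <= x[j]:
                dq.pop()
            dq.append(j)
        while dq and dq[0] < i - window_s:
            dq.popleft()
        base[i] = x[dq[0]] if dq else -np.inf
    # fill undefined entries
    defined = np.isfinite(base)
    if not defined.any():
        return base
    first = np.argmax(defined)
    base[:first] = base[first]
    for i in range(first + 1, n):
        if not np.isfinite(base[i]):
            base[i] = base[i - 1]
    return base


def detect_desaturations(spo2, mask=None, threshold_pct: float = 3.0,
                         min_len_s: int = 10, max_len_s: int = 120,
                         recovery_tol: float = RECOVERY_TOL_PCT,
                         max_invalid_frac: float = 0.5,
                         ) -> list[DesaturationEvent]:
    """Detect desaturation events in a 1-Hz SpO2 series.

    Parameters
    ----------
    spo2 : 1-D array, % at 1 Hz (cleaned).
    mask : boolean validity mask; padding and artifact samples are False.
        Events whose samples are mostly invalid are discarded.
    threshold_pct : minimum drop below the local baseline to open an event
        (>= comparison; the classic ODI threshold is 3%).
    min_len_s, max_len_s : admissible event duration in seconds.
    """
    spo2 = np.asarray(spo2, dtype=float)
    if mask is None:
        mask = np.ones(spo2.size, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    base = _running_baseline(spo2, mask)

    events: list[DesaturationEvent] = []
    n = spo2.size
    i = int(np.argmax(np.isfinite(base)))
    while i < n:
        if mask[i] and np.isfinite(base[i]) and base[i] - spo2[i] >= threshold_pct:
            b0 = base[i]
            start = i
            j = i + 1
            while j < n and j - start < max_len_s:
                if mask[j] and spo2[j] >= b0 - recovery_tol:
                    break
                j += 1
            end = j  # exclusive
            # extend along the monotone descent/recovery flanks so the event
            # spans the full dip, not just the part >= threshold deep
            floor = events[-1].end_s if events else 0
            s2 = start
            while (s2 > floor and mask[s2 - 1] and spo2[s2 - 1] > spo2[s2]
                   and start - s2 < 30):
                s2 -= 1
            e2 = end
            while (e2 < n and mask[e2] and spo2[e2] > spo2[e2 - 1]
                   and spo2[e2] <= b0 and e2 - end < 30):
                e2 += 1
            seg = spo2[s2:e2]
            seg_mask = mask[s2:e2]
            length = e2 - s2
            if (length >= min_len_s
                    and seg_mask.mean() > max_invalid_frac):
                nadir = int(np.argmin(seg))
                depth = float(b0 - seg[nadir])
                area = float(np.sum(np.clip(b0 - seg, 0.0, None)))
                slope = depth / max(nadir + 1, 1)
                events.append(DesaturationEvent(start_s=s2, end_s=e2,
                                                depth=depth, length=length,
                                                area=area, slope_desc=slope))
            i = e2
        else:
            i += 1
    return events


def compute_odi(events: list[DesaturationEvent], tst_hat: float) -> float:
    """Oxygen desaturation index: events per hour of estimated sleep."""
    if tst_hat <= 0:
        raise ValueError("tst_hat must be positive (record should have been "
                         "excluded upstream)")
    return len(events) / tst_hat


def match_events(planted: list[DesaturationEvent],
                 detected: list[DesaturationEvent]) -> tuple[float, float]:
    """Event-level (recall, precision) by temporal overlap.

    A planted event is recalled if at least one detected event overlaps it;
    a detected event is a true positive if it overlaps at least one planted
    event.
    """
    if not planted and not detected:
        return 1.0, 1.0
    recall = (np.mean([any(d.overlaps(p) for d in detected) for p in planted])
              if planted else 1.0)
    precision = (np.mean([any(p.overlaps(d) for p in planted) for d in detected])
                 if detected else 1.0)
    return float(recall), float(precision)


def events_to_frame(events: list[DesaturationEvent], record_id: str = ""):
    """Events as a pandas DataFrame (one row per event)."""
    import pandas as pd

    return pd.DataFrame([
        {"record_id": record_id, "start_s": e.start_s, "end_s": e.end_s,
         "depth": e.depth, "length": e.length, "area": e.area,
         "slope": e.slope_desc}
        for e in events
    ], columns=["record_id", "start_s", "end_s", "depth", "length", "area",
                "slope"])
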