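"""Measurement procedures for simulated (and electrode-style) activity.

Ictal-discharge detection on extracellular-potassium traces, wavefront
speed estimation by the half-maximum delay between two sites and by the
slowest-fragment slope of the space-time front, inter-discharge
statistics (median and interquartile range, first event excluded), and
the K+-selective electrode calibration transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

ELECTRODE_SCALE = 0.044   # 1/mV, mean calibration of K+-selective electrodes
ELECTRODE_BASE = 2.5      # mM at zero electrode voltage


def electrode_transform(V_trace, S=ELECTRODE_SCALE):
    """[K+]_o(t) = 2.5 mM * exp(S * V(t)) — K+-electrode calibration."""
    if S <= 0:
        raise ValueError("electrode scaling factor must be positive")
    return ELECTRODE_BASE * np.exp(S * np.asarray(V_trace, float))


def electrode_inverse(K_trace, S=ELECTRODE_SCALE):
    """Electrode voltage (mV) from a [K+]_o trace; inverse of the above."""
    return np.log(np.asarray(K_trace, float) / ELECTRODE_BASE) / S


@dataclass
class IDEvent:
    """One detected ictal discharge at a recording site."""

    onset: float            # s
    offset: float           # s
    peak_K: float           # mM
    peak_time: float        # s

    def __post_init__(self):
        if not self.onset < self.offset:
            raise ValueError("event onset must precede offset")

    @property
    def duration(self):
        return self.offset - self.onset


def detect_id_events(t, K_o, baseline=3.5, onset_above=3.0, offset_above=1.0,
                     min_duration=0.5, min_quiet=5.0):
    """Detect discharges as sustained [K+]_o elevations at one site.

    Onset: K_o crosses baseline + ``onset_above`` and stays above
    baseline + ``offset_above`` for at least ``min_duration`` seconds;
    offset: K_o returns below baseline + ``offset_above`` for at least
    ``min_quiet`` seconds (events closer than that are merged).
    Thresholds separate full discharges (~several mM) from brief
    transients and are exposed here because the underlying study does
    not fix them.
    """
    t = np.asarray(t, float)
    K = np.asarray(K_o, float)
    hi = K >= baseline + onset_above
    lo = K >= baseline + offset_above
    events: List[IDEvent] = []
    i = 0
    n = len(t)
    while i < n:
        if not hi[i]:
            i += 1
            continue
        # expand to the enclosing above-offset-threshold region
        a = i
        while a > 0 and lo[a - 1]:
            a -= 1
        b = i
        while b + 1 < n and lo[b + 1]:
            b += 1
        if events and t[a] - events[-1].offset < min_quiet:
            prev = events.pop()
            a = int(np.searchsorted(t, prev.onset))
        seg = slice(a, b + 1)
        pk = int(np.argmax(K[seg])) + a
        if t[b] - t[a] >= min_duration:
            events.append(IDEvent(onset=float(t[a]), offset=float(t[b]),
                                  peak_K=float(K[pk]),
                                  peak_time=float(t[pk])))
        i = b + 1
    return events


def _half_max_crossing(t, K, event: IDEvent, baseline):
    """First crossing time of half the peak elevation during one event."""
    m = (t >= event.onset - 1.0) & (t <= event.peak_time)
    tt, kk = t[m], K[m]
    half = baseline + 0.5 * (event.peak_K - baseline)
    above = np.where(kk >= half)[0]
    if len(above) == 0:
        return None
    j = above[0]
    if j == 0:
        return float(tt[0])
    # linear interpolation between samples
    t0, t1 = tt[j - 1], tt[j]
    k0, k1 = kk[j - 1], kk[j]
    return float(t0 + (half - k0) / (k1 - k0) * (t1 - t0))


@dataclass
class SpeedResult:
    speed: Optional[float]   # mm/s; None if undefined
    lag: Optional[float]     # s
    reason: str = "ok"

    @property
    def propagated(self):
        return self.speed is not None


def speed_from_delay(t, trace1, trace2, distance, baseline=3.5,
                     min_lag=0.05, **detect_kw):
    """Propagation speed from the half-maximum delay between two sites.

    Each site's discharge rise is normalized to its own peak; the lag
    is the difference of the first half-maximum crossing times; speed =
    distance / |lag|. Flagged (no speed) when an event is missing at
    one site or the lag is unresolved (|lag| <= ``min_lag``).
    """
    if distance <= 0:
        raise ValueError("distance must be positive")
    t = np.asarray(t, float)
    e1 = detect_id_events(t, trace1, baseline=baseline, **detect_kw)
    e2 = detect_id_events(t, trace2, baseline=baseline, **detect_kw)
    if not e1 or not e2:
        return [SpeedResult(None, None, "failed to propagate")]
    out = []
    for ev1 in e1:
        # match the event at the other site whose peak is nearest
        ev2 = min(e2, key=lambda e: abs(e.peak_time - ev1.peak_time))
        if abs(ev2.peak_time - ev1.peak_time) > max(30.0, 2 * ev1.duration):
            out.append(SpeedResult(None, None, "failed to propagate"))
            continue
        h1 = _half_max_crossing(t, np.asarray(trace1, float), ev1, baseline)
        h2 = _half_max_crossing(t, np.asarray(trace2, float), ev2, baseline)
        if h1 is None or h2 is None:
            out.append(SpeedResult(None, None, "no half-max crossing"))
            continue
        lag = h2 - h1
        if abs(lag) <= min_lag:
            out.append(SpeedResult(None, float(lag), "unresolved (near-simultaneous)"))
            continue
        out.append(SpeedResult(float(distance / abs(lag)), float(lag)))
    return out


def front_onset_times(t, x, K_field, threshold=6.0):
    """First crossing time of ``threshold`` per spatial node (NaN if none)."""
    t = np.asarray(t, float)
    K = np.asarray(K_field, float)   # (n_t, n_x)
    onset = np.full(len(x), np.nan)
    for j in range(len(x)):
        w = np.where(K[:, j] >= threshold)[0]
        if len(w):
            k = w[0]
            if k > 0:
                k0, k1 = K[k - 1, j], K[k, j]
                onset[j] = t[k - 1] + (threshold - k0) / (k1 - k0) \
                    * (t[k] - t[k - 1])
            else:
                onset[j] = t[0]
    return onset


def speed_from_slope(t, x, K_field, threshold=6.0, window=5,
                     max_speed=10.0, min_extent=8, max_time_span=None):
    """Front speed from the slope of the slowest wavefront fragment.

    The front position is the first threshold crossing of [K+]_o per
    node; a line is fitted to the crossing times over a sliding window
    of nodes and the speed is the reciprocal of the steepest |dt/dx|
    (the slowest fragment). Fragments faster than ``max_speed`` mm/s
    (apparent, near-simultaneous onsets) are excluded, as are fragments
    whose onset-time span exceeds ``max_time_span`` (fits implying
    propagation longer than the discharge itself, which arise when
    separate discharges share one detection window). Returns None if no
    valid fragment exists or the front spans fewer than ``min_extent``
    nodes.
    """
    x = np.asarray(x, float)
    onset = front_onset_times(t, x, K_field, threshold)
    valid = ~np.isnan(onset)
    if valid.sum() < min_extent:
        return None
    oo, xx = onset[valid], x[valid]
    best = None
    for i in range(len(xx) - window + 1):
        seg_o = oo[i:i + window]
        if max_time_span is not None and np.ptp(seg_o) > max_time_span:
            continue   # implausible fragment (spans beyond the event)
        sl = np.polyfit(xx[i:i + window], seg_o, 1)[0]  # s/mm
        if abs(sl) < 1.0 / max_speed:
            continue   # apparent (near-simultaneous) fragment
        v = 1.0 / abs(sl)
        if best is None or v < best:
            best = v
    return best


def split_field_events(t, K_field, threshold=6.0, min_quiet=3.0):
    """Split a space-time field into per-discharge time windows.

    A discharge window is a maximal interval in which any node exceeds
    the threshold; windows separated by less than ``min_quiet`` seconds
    are merged. Returns a list of (i0, i1) index pairs.
    """
    t = np.asarray(t, float)
    act = (np.asarray(K_field, float) >= threshold).any(axis=1).astype(int)
    d = np.diff(act)
    on = list(np.where(d == 1)[0] + 1)
    off = list(np.where(d == -1)[0] + 1)
    if act[0]:
        on = [0] + on
    if act[-1]:
        off = off + [len(t) - 1]
    wins = []
    for a, b in zip(on, off):
        if wins and t[a] - t[wins[-1][1]] < min_quiet:
            wins[-1][1] = b
        else:
            wins.append([a, b])
    return [(a, b) for a, b in wins]


def slowest_front_speeds(t, x, K_field, threshold=6.0, pad=2.0, **kw):
    """Per-discharge slowest-fragment speeds over a whole recording.

    Each discharge window is analyzed separately; a fragment may not
    span more time than its own discharge window (see
    ``speed_from_slope``).
    """
    t = np.asarray(t, float)
    speeds = []
    for a, b in split_field_events(t, K_field, threshold):
        a0 = int(np.searchsorted(t, t[a] - pad))
        b0 = int(np.searchsorted(t, t[b] + pad))
        v = speed_from_slope(t[a0:b0], x, np.asarray(K_field)[a0:b0],
                            threshold=threshold,
                            max_time_span=t[b] - t[a] + 2 * pad, **kw)
        if v is not None:
            speeds.append(v)
    return speeds


def minimal_front_speed(t, x, K_field, skip_first=True, **kw):
    """The minimal-velocity discharge front of a recording (mm/s).

    The reported propagation measure: the minimum of the per-discharge
    slowest-fragment speeds, after excluding the first discharge of the
    run (initialization transient). None when no valid front exists.
    """
    speeds = slowest_front_speeds(t, x, K_field, **kw)
    if skip_first and len(speeds) > 1:
        speeds = speeds[1:]
    return min(speeds) if speeds else None


@dataclass
class IDStatistics:
    n: int
    median: Optional[float]
    iqr: tuple
    values: np.ndarray = field(repr=False, default=None)


def median_iqr(values):
    """Median and 25-75% interquartile range of a value set."""
    v = np.asarray(values, float)
    if v.size == 0:
        return IDStatistics(0, None, (None, None), v)
    lo, med, hi = np.percentile(v, [25, 50, 75])
    return IDStatistics(int(v.size), float(med), (float(lo), float(hi)), v)


def id_statistics(event_sets, skip_first=True, max_events=None):
    """Summary statistics over recordings, first event of each excluded.

    ``event_sets``: list (one per recording) of lists of IDEvent.
    Returns a dict of IDStatistics for the inter-discharge frequency
    (reciprocal inter-onset interval), peak [K+]_o and duration.
    """
    freqs, peaks, durs = [], [], []
    for events in event_sets:
        ev = events[1:] if skip_first else list(events)
        if max_events is not None:
            ev = ev[:max_events]
        peaks += [e.peak_K for e in ev]
        durs += [e.duration for e in ev]
        onsets = [e.onset for e in (events if skip_first else ev)]
        if len(onsets) >= 2:
            iv = np.diff(onsets)
            freqs += list(1.0 / iv)
    return {
        "frequency": median_iqr(freqs),
        "peak_K": median_iqr(peaks),
        "duration": median_iqr(durs),
    }


# --- event-sequence checks on a recording --------------------------------

def gaba_precedes_glutamate(t, I_hold, event: IDEvent, pos_thr=0.1,
                            neg_thr=-0.1, lead=10.0):
    """True when a positive (GABAergic, outward at -27 mV) holding-current
    deflection occurs before the first negative (glutamatergic) one
    within one discharge."""
    m = (t >= event.onset - lead) & (t <= event.offset)
    tt = np.asarray(t)[m]
    ih = np.asarray(I_hold)[m]
    tpos = tt[ih >= pos_thr]
    tneg = tt[ih <= neg_thr]
    if len(tneg) == 0:
        return len(tpos) > 0
    if len(tpos) == 0:
        return False
    return tpos[0] < tneg[0]


def has_undershoot(t, K_o, event: IDEvent, baseline=3.5, window=20.0):
    """True when [K+]_o dips below baseline after the discharge ends."""
    m = (t >= event.offset) & (t <= event.offset + window)
    if not m.any():
        return False
    return bool(np.min(np.asarray(K_o)[m]) < baseline)


def sodium_peaks_after_potassium(t, K_o, Na_i, event: IDEvent, pad=15.0):
    """True when intracellular Na+ peaks later than extracellular K+."""
    m = (t >= event.onset) & (t <= event.offset + pad)
    tt = np.asarray(t)[m]
    tK = tt[np.argmax(np.asarray(K_o)[m])]
    tNa = tt[np.argmax(np.asarray(Na_i)[m])]
    return bool(tNa > tK)
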