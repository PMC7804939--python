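"""Whole-cell voltage-clamp analysis: suppression trajectory, fast PSCs, charge.

In awake recordings the baseline is a dense barrage of spontaneous synaptic
currents; sounds evoke both fast compound PSCs and a slow suppression of the
barrage (network suppression).  To quantify fast-event charge without
contamination by the slow component, a suppression trajectory is first
estimated by iteratively smoothing the inactive portions of the
trial-averaged trace; fast events are excursions beyond 3 baseline SDs from
that trajectory, and each event's charge is the area between the raw trace
and the chord connecting its onset and offset (which removes any local
offset).  All analysis operates on polarity-normalized traces where the
evoked direction is positive (EPSCs recorded at -70 mV are negative-going,
IPSCs at +20 mV positive-going).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from .dsi_metrics import dsi as _dsi

__all__ = [
    "CurrentTrace",
    "FastEvent",
    "tone_windows",
    "estimate_suppression_trajectory",
    "detect_fast_events",
    "event_charge",
    "sweep_charge",
    "events_to_table",
    "events_from_table",
    "psc_timing_offsets",
    "dsi_from_charges",
]


@dataclass
class CurrentTrace:
    """Trial x sample current recording (pA) with polarity convention.

    ``t0`` is the time of the first sample relative to sound onset (s).
    ``polarity`` is 'epsc' (evoked events negative-going) or 'ipsc'
    (positive-going); :meth:`evoked` returns traces rectified so evoked is
    positive.
    """

    i: np.ndarray
    fs: float = 10_000.0
    t0: float = -0.5
    polarity: str = "epsc"
    sound_onset: float = 0.0
    sound_offset: float = 0.1
    baseline_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.i = np.atleast_2d(np.asarray(self.i, float))
        if not np.all(np.isfinite(self.i)):
            raise ValueError("current trace contains non-finite samples")
        if self.polarity not in ("epsc", "ipsc"):
            raise ValueError("polarity must be 'epsc' or 'ipsc'")
        if self.baseline_window is None:
            self.baseline_window = (self.t0, self.sound_onset)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.i.shape[1]) / self.fs

    @property
    def sign(self) -> float:
        return -1.0 if self.polarity == "epsc" else 1.0

    def evoked(self) -> np.ndarray:
        """Trial-averaged, polarity-normalized trace (evoked positive)."""
        return self.sign * self.i.mean(axis=0)

    def evoked_trials(self) -> np.ndarray:
        return self.sign * self.i

    def index_of(self, t: float) -> int:
        idx = int(round((t - self.t0) * self.fs))
        if idx < 0 or idx >= self.i.shape[1]:
            raise ValueError(f"time {t} s outside trace extent")
        return idx

    def baseline_sd(self) -> float:
        lo, hi = (self.index_of(t) for t in self.baseline_window)
        return float(self.evoked()[lo:hi].std(ddof=1))


@dataclass
class FastEvent:
    """A fast compound PSC: onset/peak/offset times (s) and chord charge (pC)."""

    onset: float
    peak: float
    offset: float
    charge: float = 0.0

    def __post_init__(self) -> None:
        if not (self.onset < self.peak < self.offset):
            raise ValueError("event requires onset < peak < offset")


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open (start, stop) index pairs of contiguous True runs."""
    if not mask.any():
        return []
    edges = np.flatnonzero(np.diff(mask.astype(int)))
    starts = ([0] if mask[0] else []) + [e + 1 for e in edges if mask[e + 1]]
    stops = [e + 1 for e in edges if not mask[e + 1]] + ([len(mask)] if mask[-1] else [])
    return list(zip(starts, stops))


def _extend_to_zero_crossings(core: np.ndarray, positive: np.ndarray) -> np.ndarray:
    """Extend each True run of ``core`` outward while ``positive`` holds."""
    out = np.zeros_like(core)
    for s, e in _runs(core):
        while s > 0 and positive[s - 1]:
            s -= 1
        while e < len(core) and positive[e]:
            e += 1
        out[s:e] = True
    return out


def _window_significant(
    trace: CurrentTrace, window: tuple[float, float], direction: float,
    threshold_sd: float = 1.0, trial_frac: float = 0.5,
) -> bool:
    """1-SD / half-window / half-trials rule on polarity-normalized trials."""
    lo, hi = trace.index_of(window[0]), trace.index_of(window[1])
    b0, b1 = (trace.index_of(t) for t in trace.baseline_window)
    trials = direction * trace.evoked_trials()
    base = trials[:, b0:b1]
    m, sd = base.mean(), base.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate baseline (zero SD)")
    thr = m + threshold_sd * sd
    need = max(1, math.ceil(0.5 * (hi - lo)))

    def max_run(flags):
        best = run = 0
        for f in flags:
            run = run + 1 if f else 0
            best = max(best, run)
        return best

    hits = sum(max_run(row[lo:hi] > thr) >= need for row in trials)
    avg = direction * trace.evoked()
    avg_base = avg[b0:b1]
    avg_thr = avg_base.mean() + threshold_sd * avg_base.std(ddof=1)
    return bool(hits > trial_frac * trials.shape[0] and max_run(avg[lo:hi] > avg_thr) >= need)


def tone_windows(
    trace: CurrentTrace,
    onset_window: tuple[float, float] = (0.015, 0.040),
    suppression_window: tuple[float, float] = (0.050, 0.175),
) -> dict:
    """Onset-locked and network-suppression amplitudes for a 100-ms tone.

    The onset-locked component is the baseline-subtracted mean of the
    polarity-normalized average in 15-40 ms after tone onset; network
    suppression is the opposite-sign current in 50-175 ms.  Each is tested
    with the whole-cell significance rule (1 baseline SD, half the window,
    more than half of trials).
    """
    avg = trace.evoked()
    b0, b1 = (trace.index_of(t) for t in trace.baseline_window)
    base_mean = avg[b0:b1].mean()
    out = {}
    for name, win, direction in (
        ("onset", onset_window, 1.0),
        ("suppression", suppression_window, -1.0),
    ):
        lo, hi = trace.index_of(win[0]), trace.index_of(win[1])
        amp = direction * (avg[lo:hi].mean() - base_mean)
        out[f"{name}_amplitude"] = float(amp)
        out[f"{name}_significant"] = _window_significant(trace, win, direction)
    return out


def estimate_suppression_trajectory(
    trace: CurrentTrace,
    smooth_ms: float = 50.0,
    threshold_sd: float = 3.0,
    max_iter: int = 10,
) -> np.ndarray:
    """Slow network-suppression baseline of the trial-averaged trace.

    Iterative robust smoother: smooth over currently unflagged samples
    (flagged samples are bridged by linear interpolation), flag samples
    deviating more than ``threshold_sd`` baseline SDs above the smooth in the
    evoked direction — each flagged run extended outward to the nearest
    zero-crossings of the deviation so the whole event, tails included, is
    treated as active — then repeat until the flag set stabilizes or
    ``max_iter`` passes.  The 50-ms default window matches the timescale of
    tone-evoked currents, so fast events are excluded while the slow
    suppression is followed.
    """
    avg = trace.evoked()
    sd = trace.baseline_sd()
    n = avg.size
    width = max(3, int(round(smooth_ms * 1e-3 * trace.fs)))
    flagged = np.zeros(n, bool)
    smooth = avg.copy()
    for _ in range(max_iter):
        work = avg.copy()
        if flagged.any():
            if flagged.all():
                break
            idx = np.arange(n)
            work[flagged] = np.interp(idx[flagged], idx[~flagged], avg[~flagged])
        smooth = uniform_filter1d(work, size=width, mode="nearest")
        resid = avg - smooth
        new_flagged = _extend_to_zero_crossings(resid > threshold_sd * sd, resid > 0)
        if np.array_equal(new_flagged, flagged):
            break
        flagged = new_flagged
    if flagged.mean() > 0.5:
        warnings.warn("more than half the trace flagged as events; trajectory unreliable")
    return smooth


def detect_fast_events(
    trace: CurrentTrace,
    trajectory: np.ndarray,
    threshold_sd: float = 3.0,
    merge_gap_ms: float = 2.0,
    peak_smooth_ms: float = 0.5,
    min_supra_ms: float = 0.5,
) -> list[FastEvent]:
    """Fast PSCs: evoked-direction excursions beyond the trajectory.

    Contiguous runs where the trial-averaged trace exceeds the trajectory by
    more than ``threshold_sd`` baseline SDs seed events; runs shorter than
    ``min_supra_ms`` are discarded as sampling noise (a synaptic event stays
    above threshold for milliseconds, an isolated noise sample does not).
    Onset and offset are extended outward to the nearest trajectory crossings
    (the automatic surrogate for the original manual onset/offset placement),
    and events separated by less than ``merge_gap_ms`` are merged.  Peak
    times are taken from a lightly smoothed residual for noise robustness.
    """
    avg = trace.evoked()
    resid = avg - trajectory
    sd = trace.baseline_sd()
    above = resid > threshold_sd * sd
    min_run = max(1, int(round(min_supra_ms * 1e-3 * trace.fs)))
    core = np.zeros_like(above)
    for s, e in _runs(above):
        if e - s >= min_run:
            core[s:e] = True
    if not core.any():
        return []
    # onset/offset from zero crossings of a 1-ms smoothed residual: raw-noise
    # crossings would truncate the decay tail where it sinks into the noise
    bound_width = max(1, int(round(1e-3 * trace.fs)))
    resid_b = uniform_filter1d(resid, size=bound_width, mode="nearest")
    ext = _runs(_extend_to_zero_crossings(core, resid_b > 0))
    # merge events with small gaps
    gap = int(round(merge_gap_ms * 1e-3 * trace.fs))
    merged = [ext[0]]
    for s, e in ext[1:]:
        if s - merged[-1][1] < gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    t = trace.times
    width = max(1, int(round(peak_smooth_ms * 1e-3 * trace.fs)))
    smooth_resid = uniform_filter1d(resid, size=width, mode="nearest")
    events = []
    for s, e in merged:
        e = min(e, len(resid) - 1)
        if e - s < 2:
            continue
        pk = s + 1 + int(np.argmax(smooth_resid[s + 1:e]))
        events.append(FastEvent(onset=t[s], peak=t[pk], offset=t[e]))
    return events


def event_charge(
    trace: CurrentTrace, events: list[FastEvent], trajectory: np.ndarray | None = None
) -> dict:
    """Total chord charge (pC) plus timing of the dominant event.

    Each event's charge is the area between the polarity-normalized average
    trace and the straight chord connecting its onset and offset points
    (pA x s = pC); adding a constant to the whole trace leaves it unchanged.
    The chord endpoints are taken from the suppression trajectory when one is
    supplied — the trajectory value is the trace's level at the event's foot,
    free of the sample noise a raw endpoint would imprint on the whole chord —
    and from the raw trace otherwise.  Charges sum over events; the peak and
    onset times come from the event with the largest charge.  An empty event
    list gives zero charge and missing timings.
    """
    if not events:
        return {"charge_pc": 0.0, "peak_time": None, "onset_time": None, "events": []}
    avg = trace.evoked()
    t = trace.times
    anchor = avg if trajectory is None else np.asarray(trajectory, float)
    out_events = []
    for ev in events:
        s, e = trace.index_of(ev.onset), trace.index_of(ev.offset)
        seg = avg[s:e + 1]
        chord = np.linspace(anchor[s], anchor[e], seg.size)
        q = float(np.trapezoid(seg - chord, t[s:e + 1]))
        out_events.append(FastEvent(onset=ev.onset, peak=ev.peak, offset=ev.offset, charge=q))
    total = sum(ev.charge for ev in out_events)
    biggest = max(out_events, key=lambda ev: ev.charge)
    return {
        "charge_pc": total,
        "peak_time": biggest.peak,
        "onset_time": biggest.onset,
        "events": out_events,
    }


def sweep_charge(
    trace: CurrentTrace,
    include_after_offset_s: float = 0.05,
    threshold_sd: float = 3.0,
) -> dict:
    """End-to-end fast-PSC charge for one FM-sweep response.

    Estimates the suppression trajectory, detects fast events, keeps those
    with onsets between sound onset and ``include_after_offset_s`` past sound
    offset, and returns their summed chord charge and dominant-event timing.
    """
    traj = estimate_suppression_trajectory(trace)
    events = detect_fast_events(trace, traj, threshold_sd=threshold_sd)
    lo = trace.sound_onset
    hi = trace.sound_offset + include_after_offset_s
    kept = [ev for ev in events if lo <= ev.onset <= hi]
    return event_charge(trace, kept, trajectory=traj)


def events_to_table(events: list[FastEvent]):
    """Review export: one row per event (times in s, charge in pC).

    The table can be edited (manual onset/offset correction) and fed back via
    :func:`events_from_table` to recompute charges with the corrected
    boundaries.
    """
    import pandas as pd

    return pd.DataFrame(
        [{"onset_s": e.onset, "peak_s": e.peak, "offset_s": e.offset,
          "charge_pc": e.charge} for e in events]
    )


def events_from_table(table) -> list[FastEvent]:
    """Rebuild events from a (possibly hand-corrected) review table."""
    return [
        FastEvent(onset=row.onset_s, peak=row.peak_s, offset=row.offset_s)
        for row in table.itertuples()
    ]


def psc_timing_offsets(epsc: dict | None, ipsc: dict | None) -> dict:
    """EPSC-vs-IPSC lead times (ms): positive when the EPSC comes first.

    Inputs are :func:`event_charge` / :func:`sweep_charge` results for the
    EPSC and IPSC traces of the same cell-sound pair; offsets are defined
    only when both sides have detected events.
    """
    missing = {"peak_lead_ms": None, "onset_lead_ms": None}
    if not epsc or not ipsc:
        return missing
    if epsc.get("peak_time") is None or ipsc.get("peak_time") is None:
        return missing
    return {
        "peak_lead_ms": (ipsc["peak_time"] - epsc["peak_time"]) * 1e3,
        "onset_lead_ms": (ipsc["onset_time"] - epsc["onset_time"]) * 1e3,
    }


def dsi_from_charges(up_charge: float, down_charge: float) -> float:
    """Charge-based DSI: the same clamped (U - D)/(U + D) as for amplitudes."""
    return _dsi(up_charge, down_charge)
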