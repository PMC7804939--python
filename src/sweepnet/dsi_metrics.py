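"""Direction-selectivity statistics and response-significance criteria.

Implements the experimental DSI, ``(U - D) / (U + D)`` with negative
amplitudes clamped to zero, together with the response-significance rules
used to decide which stimuli enter the statistic:

* imaging (dF/F traces): response exceeds baseline mean + 3.3 baseline SD
  consecutively for at least 0.5 s, in more than half of trials and in the
  trial-averaged trace;
* single units (50-ms spike-count PSTHs, baseline rate subtracted): counts
  exceed baseline mean + 3.7 SD at the same time bin in more than a third of
  trials, and the trial-averaged PSTH exceeds the threshold in some bin;
* whole cell (currents): traces exceed baseline mean + 1 SD consecutively for
  at least half the detection window, in more than half of trials and in the
  average.

A cell's DSI uses only FM rates that evoked a significant excitatory response
in at least one direction; amplitudes are averaged across included rates per
direction before the ratio is formed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrialSet",
    "ResponseCriteria",
    "CellDsiRecord",
    "is_significant",
    "response_amplitude",
    "dsi",
    "cell_dsi",
    "min_response_filter",
    "best_frequency",
    "fcent_analysis",
]


class DegenerateBaselineError(ValueError):
    """Baseline variability is zero; the significance rule is undefined."""


@dataclass
class TrialSet:
    """Trial x time response array with baseline and response windows.

    ``t0`` is the time of the first sample relative to sound onset (s), so a
    1-s pre-stimulus baseline has ``t0 = -1``.  ``data`` holds dF/F values,
    spike counts per bin, or current samples; ``fs`` is the sampling rate or
    1 / bin width in Hz.  Windows are (start, stop) in seconds relative to
    sound onset.
    """

    data: np.ndarray
    fs: float
    t0: float
    baseline_window: tuple[float, float]
    response_window: tuple[float, float]
    stim: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, float))
        if self.data.shape[0] < 1:
            raise ValueError("need at least one trial")
        for win in (self.baseline_window, self.response_window):
            lo, hi = self._indices(win)
            if hi <= lo:
                raise ValueError(f"window {win} is empty at fs={self.fs}")
            if lo < 0 or hi > self.data.shape[1]:
                raise ValueError(f"window {win} outside trace extent")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.data.shape[1]) / self.fs

    def _indices(self, window: tuple[float, float]) -> tuple[int, int]:
        lo = int(math.floor((window[0] - self.t0) * self.fs + 1e-9))
        hi = int(math.ceil((window[1] - self.t0) * self.fs - 1e-9))
        return lo, hi

    def window(self, window: tuple[float, float], data: np.ndarray | None = None) -> np.ndarray:
        lo, hi = self._indices(window)
        d = self.data if data is None else np.atleast_2d(data)
        return d[:, lo:hi]

    def trial_mean(self) -> np.ndarray:
        return self.data.mean(axis=0)


@dataclass(frozen=True)
class ResponseCriteria:
    """Significance rule: threshold (baseline SDs), duration, trial fraction."""

    threshold_sd: float
    min_consec_s: float | None
    trial_frac: float
    mode: str  # imaging | unit | wholecell

    @classmethod
    def imaging(cls) -> "ResponseCriteria":
        return cls(threshold_sd=3.3, min_consec_s=0.5, trial_frac=0.5, mode="imaging")

    @classmethod
    def unit(cls) -> "ResponseCriteria":
        # same-bin coincidence across trials; no duration requirement
        return cls(threshold_sd=3.7, min_consec_s=None, trial_frac=1.0 / 3.0, mode="unit")

    @classmethod
    def wholecell(cls) -> "ResponseCriteria":
        # min_consec_s derived from the detection window (half its duration)
        return cls(threshold_sd=1.0, min_consec_s=None, trial_frac=0.5, mode="wholecell")


def _max_run(flags: np.ndarray) -> int:
    """Longest run of True in a boolean vector."""
    best = run = 0
    for f in flags:
        run = run + 1 if f else 0
        best = max(best, run)
    return best


def _baseline_stats(ts: TrialSet, pooled: bool = True) -> tuple[float, float]:
    base = ts.window(ts.baseline_window)
    if base.size < 2:
        raise DegenerateBaselineError("baseline window has fewer than 2 samples")
    m, sd = float(base.mean()), float(base.std(ddof=1))
    if sd == 0:
        raise DegenerateBaselineError("baseline standard deviation is zero")
    return m, sd


def is_significant(ts: TrialSet, crit: ResponseCriteria) -> bool:
    """Apply the two-part significance rule (per-trial and trial-average).

    The threshold is a fixed value, baseline mean + ``threshold_sd`` x SD with
    both moments pooled over all trials' baseline samples; comparisons are
    strict (the trace must *exceed* the threshold).  For unit mode the
    per-trial baseline mean is first subtracted from each trial (spontaneous
    rate just before the sound).
    """
    data = ts.data
    if crit.mode == "unit":
        base = ts.window(ts.baseline_window)
        data = ts.data - base.mean(axis=1, keepdims=True)
        ts = TrialSet(
            data=data, fs=ts.fs, t0=ts.t0, baseline_window=ts.baseline_window,
            response_window=ts.response_window, stim=ts.stim,
        )
    m, sd = _baseline_stats(ts)
    thr = m + crit.threshold_sd * sd
    resp = ts.window(ts.response_window)
    if crit.mode == "unit":
        # same-bin coincidence in more than trial_frac of trials
        frac_per_bin = (resp > thr).mean(axis=0)
        per_trial_ok = bool(np.any(frac_per_bin > crit.trial_frac))
        avg_ok = bool(np.any(resp.mean(axis=0) > thr))
        return per_trial_ok and avg_ok
    if crit.min_consec_s is not None:
        need = max(1, math.ceil(crit.min_consec_s * ts.fs))
    else:  # wholecell: half the detection window
        need = max(1, math.ceil(0.5 * resp.shape[1]))
    hits = sum(_max_run(row > thr) >= need for row in resp)
    per_trial_ok = hits > crit.trial_frac * resp.shape[0]
    avg_ok = _max_run(resp.mean(axis=0) > thr) >= need
    return bool(per_trial_ok and avg_ok)


def response_amplitude(ts: TrialSet, subtract_baseline: bool = False) -> float:
    """Mean of the trial-averaged trace over the response window.

    ``subtract_baseline`` removes the trial-averaged baseline mean first
    (used for spike rates, where the spontaneous rate is not part of the
    evoked response; dF/F is already baseline-referenced).
    """
    mean_trace = ts.trial_mean()[None, :]
    resp = ts.window(ts.response_window, mean_trace)
    if resp.size == 0:
        raise ValueError("empty response window")
    amp = float(resp.mean())
    if subtract_baseline:
        amp -= float(ts.window(ts.baseline_window, mean_trace).mean())
    return amp


def dsi(U: float, D: float) -> float:
    """Clamped direction-selectivity index (U - D) / (U + D) in [-1, 1].

    Negative amplitudes are forced to zero before the ratio so the index
    stays within [-1, 1]; NaN when both clamp to zero.
    """
    u, d = max(U, 0.0), max(D, 0.0)
    if u + d == 0:
        return float("nan")
    return (u - d) / (u + d)


@dataclass
class CellDsiRecord:
    """Per-cell DSI with inclusion bookkeeping."""

    dsi: float
    n_rates_included: int
    responsive_count: int
    bf_khz: float | None = None


def cell_dsi(responses: pd.DataFrame, per_rate: bool = False):
    """Cell-level DSI from a per-(rate, direction) response table.

    ``responses`` needs columns ``rate``, ``direction`` ('up'/'down'),
    ``amplitude`` and ``significant``.  A rate is included iff it evoked a
    significant response in at least one direction; amplitudes are averaged
    across included rates within each direction before the clamped ratio.
    With ``per_rate`` the DSI is instead computed separately per included
    rate and a DataFrame is returned.
    """
    req = {"rate", "direction", "amplitude", "significant"}
    if not req.issubset(responses.columns):
        raise ValueError(f"responses table needs columns {sorted(req)}")
    sig_by_rate = responses.groupby("rate")["significant"].any()
    included = sig_by_rate[sig_by_rate].index
    responsive_count = int(responses["significant"].sum())
    sub = responses[responses["rate"].isin(included)]
    if per_rate:
        rows = []
        for rate, grp in sub.groupby("rate"):
            u = grp.loc[grp.direction == "up", "amplitude"].mean()
            d = grp.loc[grp.direction == "down", "amplitude"].mean()
            rows.append({"rate": rate, "dsi": dsi(u, d)})
        return pd.DataFrame(rows)
    if len(included) == 0:
        return CellDsiRecord(dsi=float("nan"), n_rates_included=0,
                             responsive_count=responsive_count)
    u = sub.loc[sub.direction == "up", "amplitude"].mean()
    d = sub.loc[sub.direction == "down", "amplitude"].mean()
    return CellDsiRecord(
        dsi=dsi(float(u), float(d)),
        n_rates_included=int(len(included)),
        responsive_count=responsive_count,
    )


def min_response_filter(cells: Sequence[CellDsiRecord], k: int = 3) -> list[CellDsiRecord]:
    """Keep cells significantly responsive to at least ``k`` stimuli.

    A permissive threshold for single responses admits spontaneous
    fluctuations; requiring several significant stimuli (default 3, variants
    1 and 5) suppresses those false positives.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    return [c for c in cells if c.responsive_count >= k]


def best_frequency(tone_responses: pd.DataFrame) -> float | None:
    """BF: the frequency with the strongest response, collapsed over intensity.

    Expects columns ``freq_khz``, ``amplitude`` and optionally ``significant``
    and ``intensity_db``.  Only significant entries count; returns None when
    nothing is significant.  Ties break toward the lowest frequency.
    """
    df = tone_responses
    if "significant" in df.columns:
        df = df[df["significant"]]
    if df.empty:
        return None
    collapsed = df.groupby("freq_khz")["amplitude"].max()
    best = collapsed.max()
    return float(min(collapsed.index[collapsed == best]))


def fcent_analysis(
    pairs: pd.DataFrame,
    bin_width_oct: float = 0.5,
    bin_range_oct: tuple[float, float] = (-3.0, 3.0),
) -> pd.DataFrame:
    """Binned mean DSI against the sweep centre's position relative to BF.

    ``pairs`` needs columns ``bf_khz``, ``f_cent_khz`` and ``dsi`` (one row
    per cell-F_cent pair).  The relative position is log2(F_cent / BF) in
    octaves; rows with missing DSI are dropped.  Returns per-bin mean DSI,
    SEM and count.
    """
    df = pairs.dropna(subset=["dsi"]).copy()
    df["relative_f_cent_oct"] = np.log2(df["f_cent_khz"] / df["bf_khz"])
    edges = np.arange(bin_range_oct[0], bin_range_oct[1] + bin_width_oct / 2, bin_width_oct)
    df["bin"] = pd.cut(df["relative_f_cent_oct"], edges)
    out = (
        df.groupby("bin", observed=True)["dsi"]
        .agg(mean_dsi="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan,
             n="count")
        .reset_index()
    )
    out["bin_center_oct"] = out["bin"].apply(lambda b: b.mid).astype(float)
    return out
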