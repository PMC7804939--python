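"""Seeded synthetic-data generators with ground truth for recovery tests.

Each generator emulates the statistical structure one analysis pipeline
assumes — no more: logarithmic chirps in Gaussian background noise for the
vocalization pipeline; trial-wise calcium responses as a slow double-
exponential kernel scaled by direction/rate-dependent amplitudes in additive
Gaussian noise; Poisson spike counts per 50-ms bin for unit PSTHs; and
voltage-clamp traces as a Poisson barrage of biexponential PSCs whose rate is
modulated by a slow suppression profile, plus injected fast compound events
of known charge.  Every generator takes an explicit seed and returns the
generated objects together with a ground-truth record; identical seeds give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dsi_metrics import TrialSet, dsi as _dsi
from .synaptic_charge import CurrentTrace

__all__ = [
    "GroundTruth",
    "gen_vocalization",
    "gen_calcium_trials",
    "gen_psth_trials",
    "gen_psc_trace",
]


@dataclass
class GroundTruth:
    """True values underlying a generated dataset, keyed by quantity name."""

    seed: int
    values: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.values[key]


def gen_vocalization(
    chirps: Sequence[tuple[float, float, float]],
    snr_db: float = 30.0,
    fs: float = 250_000.0,
    seed: int = 0,
    gap_s: float = 0.1,
    noise_sd: float = 1e-3,
    edge_ms: float = 3.0,
) -> tuple[np.ndarray, GroundTruth]:
    """Waveform of logarithmic chirps in Gaussian noise, plus per-segment truth.

    ``chirps`` is a list of (start kHz, rate oct/s, duration ms); syllables are
    placed sequentially with ``gap_s`` of silence between them.  Chirp
    amplitude is set ``snr_db`` above the noise SD; envelopes have
    ``edge_ms`` cosine ramps.  Truth lists the constant FM rate of every full
    5-ms segment of every chirp.
    """
    rng = np.random.default_rng(seed)
    events = []
    t_cursor = gap_s
    for f_khz, rate, dur_ms in chirps:
        dur = dur_ms * 1e-3
        f0 = f_khz * 1e3
        f_end = f0 * 2.0 ** (rate * dur)
        if max(f0, f_end) >= fs / 2:
            raise ValueError(f"chirp reaches {max(f0, f_end):.0f} Hz, beyond Nyquist {fs / 2:.0f}")
        events.append((t_cursor, f0, rate, dur))
        t_cursor += dur + gap_s
    total = t_cursor + gap_s
    n = int(round(total * fs))
    wave = rng.normal(0.0, noise_sd, n)
    amp = noise_sd * 10.0 ** (snr_db / 20.0)
    truth_rates, truth_tmid = [], []
    for t_on, f0, rate, dur in events:
        m = int(round(dur * fs))
        tt = np.arange(m) / fs
        if rate == 0:
            phase = 2 * np.pi * f0 * tt
        else:
            phase = 2 * np.pi * f0 * (2.0 ** (rate * tt) - 1.0) / (rate * np.log(2.0))
        env = np.ones(m)
        ne = min(m // 2, int(round(edge_ms * 1e-3 * fs)))
        if ne > 0:
            ramp = 0.5 * (1 - np.cos(np.pi * np.arange(ne) / ne))
            env[:ne] = ramp
            env[-ne:] = ramp[::-1]
        i0 = int(round(t_on * fs))
        wave[i0:i0 + m] += amp * env * np.sin(phase)
        for k in range(int(np.floor(dur / 5e-3))):
            truth_rates.append(rate)
            truth_tmid.append(t_on + (k + 0.5) * 5e-3)
    truth = GroundTruth(
        seed=seed,
        values={
            "segment_rates_oct_s": np.asarray(truth_rates, float),
            "segment_t_mid_s": np.asarray(truth_tmid, float),
            "chirps": events,
            "snr_db": snr_db,
            "fs": fs,
        },
    )
    return wave, truth


def _calcium_kernel(t: np.ndarray, rise_s: float = 0.1, decay_s: float = 1.0) -> np.ndarray:
    """Unit-peak double-exponential response kernel (indicator-like kinetics)."""
    k = (1 - np.exp(-np.clip(t, 0, None) / rise_s)) * np.exp(-np.clip(t, 0, None) / decay_s)
    k[t < 0] = 0.0
    peak = k.max()
    return k / peak if peak > 0 else k


def gen_calcium_trials(
    amplitudes: dict[float, tuple[float, float]],
    noise_sd: float = 0.15,
    n_trials: int = 5,
    fs: float = 30.0,
    pre_s: float = 1.0,
    post_s: float = 1.3,
    seed: int = 0,
) -> tuple[dict[tuple[float, str], TrialSet], GroundTruth]:
    """Trial-wise dF/F responses with known direction-dependent amplitudes.

    ``amplitudes`` maps FM rate (oct/s) to true (U, D) peak dF/F values; sweep
    duration is the 4-octave span over the rate.  Each trial is baseline
    Gaussian noise plus the amplitude-scaled slow response kernel.  Truth
    holds the per-stimulus amplitudes and the clamped DSI over all rates.
    """
    if n_trials < 5:
        raise ValueError("at least five trials per stimulus")
    rng = np.random.default_rng(seed)
    out: dict[tuple[float, str], TrialSet] = {}
    for rate in sorted(amplitudes):
        U, D = amplitudes[rate]
        dur = 4.0 / abs(rate)
        n = int(round((pre_s + dur + post_s) * fs))
        t = np.arange(n) / fs - pre_s
        kern = _calcium_kernel(t)
        for direction, amp in (("up", U), ("down", D)):
            data = rng.normal(0.0, noise_sd, (n_trials, n)) + amp * kern
            out[(rate, direction)] = TrialSet(
                data=data,
                fs=fs,
                t0=-pre_s,
                baseline_window=(-pre_s, 0.0),
                response_window=(0.0, dur + 0.3),
                stim={"rate": rate, "direction": direction},
            )
    U_mean = float(np.mean([uv[0] for uv in amplitudes.values()]))
    D_mean = float(np.mean([uv[1] for uv in amplitudes.values()]))
    truth = GroundTruth(
        seed=seed,
        values={
            "amplitudes": dict(amplitudes),
            "dsi": _dsi(U_mean, D_mean),
            "noise_sd": noise_sd,
            "n_trials": n_trials,
        },
    )
    return out, truth


def gen_psth_trials(
    baseline_hz: float,
    evoked_hz: Sequence[float],
    n_trials: int = 10,
    bin_ms: float = 50.0,
    pre_s: float = 0.5,
    post_s: float = 0.5,
    seed: int = 0,
) -> tuple[TrialSet, GroundTruth]:
    """Poisson spike-count PSTH trials at 50-ms bins.

    ``evoked_hz`` gives the added rate per response bin starting at sound
    onset; the baseline rate applies throughout.  The baseline window is the
    200 ms just before onset.
    """
    if baseline_hz < 0 or np.any(np.asarray(evoked_hz) < 0):
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    bw = bin_ms * 1e-3
    n_pre = int(round(pre_s / bw))
    n_resp = len(evoked_hz)
    n_post = int(round(post_s / bw))
    rate = np.concatenate([
        np.full(n_pre, baseline_hz),
        baseline_hz + np.asarray(evoked_hz, float),
        np.full(n_post, baseline_hz),
    ])
    counts = rng.poisson(rate * bw, (n_trials, rate.size)).astype(float)
    ts = TrialSet(
        data=counts,
        fs=1.0 / bw,
        t0=-pre_s,
        baseline_window=(-0.2, 0.0),
        response_window=(0.0, n_resp * bw),
        stim={"kind": "psth"},
    )
    truth = GroundTruth(
        seed=seed,
        values={"baseline_hz": baseline_hz, "evoked_hz": np.asarray(evoked_hz, float)},
    )
    return ts, truth


def _biexp_kernel(fs: float, rise_ms: float, decay_ms: float, span_ms: float = 60.0) -> np.ndarray:
    t = np.arange(int(round(span_ms * 1e-3 * fs))) / fs
    k = np.exp(-t / (decay_ms * 1e-3)) - np.exp(-t / (rise_ms * 1e-3))
    return k / k.max()


def gen_psc_trace(
    duration_s: float = 1.5,
    fs: float = 10_000.0,
    t0: float = -0.5,
    spont_rate_hz: float = 300.0,
    event_amp_pa: float = 15.0,
    rise_ms: float = 0.5,
    decay_ms: float = 4.0,
    suppression: tuple[float, float, float] | None = (0.05, 0.4, 0.5),
    evoked_events: Sequence[tuple[float, float]] = (),
    noise_sd: float = 2.0,
    n_trials: int = 6,
    polarity: str = "epsc",
    sound_offset: float = 0.2,
    seed: int = 0,
) -> tuple[CurrentTrace, GroundTruth]:
    """Voltage-clamp traces: spontaneous barrage, slow suppression, fast events.

    Each trial is a Poisson barrage of biexponential unitary PSCs (rate
    ``spont_rate_hz``, amplitudes exponentially distributed around
    ``event_amp_pa``) whose instantaneous rate is scaled down during the
    suppression window ``(start_s, stop_s, remaining_fraction)``, plus
    injected compound events given as (time s, charge pC) pairs, plus white
    noise.  Truth stores the barrage-mean suppression trajectory and the
    injected event times and charges.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = t0 + np.arange(n) / fs
    kern = _biexp_kernel(fs, rise_ms, decay_ms)
    kern_area = kern.sum() / fs  # seconds (unit amplitude)
    supp = np.ones(n)
    if suppression is not None:
        s0, s1, frac = suppression
        supp[(t >= s0) & (t < s1)] = frac
    traces = np.zeros((n_trials, n))
    for j in range(n_trials):
        lam = spont_rate_hz * supp / fs
        spikes = rng.random(n) < lam
        amps = rng.exponential(event_amp_pa, int(spikes.sum()))
        drive = np.zeros(n)
        drive[np.flatnonzero(spikes)] = amps
        barrage = np.convolve(drive, kern)[:n]
        traces[j] = barrage + rng.normal(0.0, noise_sd, n)
    for t_ev, q_pc in evoked_events:
        # scale a biexponential to the requested chord charge (pC = pA*s)
        amp = q_pc / kern_area
        i0 = int(round((t_ev - t0) * fs))
        seg = kern[: max(0, n - i0)]
        traces[:, i0:i0 + seg.size] += amp * seg
    # the barrage mean is the rate profile filtered by the unitary kernel
    mean_traj = np.convolve(spont_rate_hz * supp / fs * event_amp_pa, kern)[:n]
    sign = -1.0 if polarity == "epsc" else 1.0
    trace = CurrentTrace(
        i=sign * traces, fs=fs, t0=t0, polarity=polarity,
        sound_onset=0.0, sound_offset=sound_offset,
    )
    truth = GroundTruth(
        seed=seed,
        values={
            "suppression_trajectory_pa": mean_traj,
            "times_s": t,
            "evoked_events": list(evoked_events),
            "event_peak_times_s": [
                t_ev + (np.argmax(kern) / fs) for t_ev, _ in evoked_events
            ],
            "spont_rate_hz": spont_rate_hz,
            "kernel_area_s": kern_area,
        },
    )
    return trace, truth
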