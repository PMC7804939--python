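"""FM-rate extraction from mouse vocalization audio.

Pipeline: detect syllables from the waveform (amplitude threshold on a short
envelope, refined edges, 15-ms margins), compute a spectrogram per syllable,
extract the vocal contour as a binary mask (category-specific preprocessing
and power threshold), isolate temporally connected contour components, divide
each component into 5-ms segments and fit the FM rate of each segment as the
least-squares slope of log2(frequency) against time (oct/s, upward positive).

Category presets follow the three vocalization classes: pup isolation calls
and male courtship songs use a plain power threshold (20% / 25% of the
per-syllable maximum, 0.5-ms resolution); pain vocalizations are broadband
and noisy, so the spectrogram is first cleaned per time bin by subtracting a
4000-Hz moving average along the frequency axis, median filtered (3x3), and
ridge-enhanced with a Frangi filter before a 5% threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.ndimage import maximum_filter1d, median_filter, uniform_filter1d
from skimage.filters import frangi
from skimage.measure import label, regionprops

__all__ = [
    "CategoryParams",
    "Syllable",
    "ContourMask",
    "ContourComponent",
    "FmSegment",
    "detect_syllables",
    "extract_contour_mask",
    "components",
    "segment_fm_rates",
    "usage_summary",
    "extract_fm_rates",
]


@dataclass(frozen=True)
class CategoryParams:
    """Contour-extraction preset for one vocalization category."""

    category: str
    power_frac: float
    time_res_ms: float
    preproc: bool
    min_component_ms: float
    nperseg: int = 512

    def __post_init__(self) -> None:
        if not (0 < self.power_frac < 1):
            raise ValueError("power_frac must lie in (0, 1)")

    @classmethod
    def pup(cls) -> "CategoryParams":
        return cls("pup", power_frac=0.20, time_res_ms=0.5, preproc=False, min_component_ms=3.0)

    @classmethod
    def song(cls) -> "CategoryParams":
        return cls("song", power_frac=0.25, time_res_ms=0.5, preproc=False, min_component_ms=3.0)

    @classmethod
    def pain(cls) -> "CategoryParams":
        return cls("pain", power_frac=0.05, time_res_ms=1.0, preproc=True, min_component_ms=7.0)

    @classmethod
    def preset(cls, name: str) -> "CategoryParams":
        try:
            return getattr(cls, name)()
        except AttributeError:
            raise ValueError(f"unknown category {name!r}") from None


@dataclass
class Syllable:
    """A dissected syllable: samples with 15-ms margins around the call."""

    start: float
    stop: float
    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        if not self.stop > self.start:
            raise ValueError("syllable stop must exceed start")


@dataclass
class ContourMask:
    """Binary time-frequency mask with its spectrogram axes."""

    mask: np.ndarray  # (freq, time) bool
    freqs_hz: np.ndarray
    times_s: np.ndarray
    power: np.ndarray


@dataclass
class ContourComponent:
    """A temporally connected contour fragment: pixel times, frequencies, powers."""

    times_s: np.ndarray
    freqs_hz: np.ndarray
    powers: np.ndarray
    duration_ms: float


@dataclass(frozen=True)
class FmSegment:
    """FM rate (oct/s, signed, upward positive) of one 5-ms contour segment."""

    t_mid: float
    rate: float


def detect_syllables(
    wave: np.ndarray,
    fs: float,
    detect_sd: float = 10.0,
    edge_sd: float = 5.0,
    margin_s: float = 0.015,
    env_window_s: float = 1e-3,
) -> list[Syllable]:
    """Detect syllables where the amplitude envelope exceeds ``detect_sd`` noise SDs.

    The noise SD is estimated robustly from the median absolute deviation of
    the whole waveform (valid when calls are temporally sparse).  Onsets and
    offsets are refined outward to where the envelope falls below ``edge_sd``
    SDs, 15-ms margins are added, and overlapping detections are merged.
    Returns an empty list for silent or pure-noise input.
    """
    wave = np.asarray(wave, float)
    sd = 1.4826 * np.median(np.abs(wave - np.median(wave)))
    if sd == 0:
        return []
    env = maximum_filter1d(np.abs(wave), size=max(3, int(round(env_window_s * fs))))
    core = env > detect_sd * sd
    if not core.any():
        return []
    low = env > edge_sd * sd
    # expand each core run outward along the low-threshold mask
    idx = np.flatnonzero(np.diff(core.astype(int)))
    starts = ([0] if core[0] else []) + [i + 1 for i in idx if core[i + 1]]
    stops = [i + 1 for i in idx if not core[i + 1]] + ([len(core)] if core[-1] else [])
    margin = int(round(margin_s * fs))
    bounds = []
    for s, e in zip(starts, stops):
        while s > 0 and low[s - 1]:
            s -= 1
        while e < len(low) and low[e]:
            e += 1
        bounds.append((max(0, s - margin), min(len(wave), e + margin)))
    merged = [bounds[0]]
    for s, e in bounds[1:]:
        if s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(e, merged[-1][1]))
        else:
            merged.append((s, e))
    return [
        Syllable(start=s / fs, stop=e / fs, samples=wave[s:e].copy(), fs=fs)
        for s, e in merged
    ]


def extract_contour_mask(syllable: Syllable, params: CategoryParams) -> ContourMask:
    """Binary contour mask of a syllable's spectrogram.

    The spectrogram hop matches the preset time resolution.  With
    ``params.preproc`` (pain preset) the per-time-bin frequency profile is
    high-passed by subtracting a 4000-Hz moving average, median filtered and
    Frangi ridge-enhanced before thresholding at ``power_frac`` of the
    syllable maximum; otherwise the raw power is thresholded directly.
    """
    fs = syllable.fs
    hop = max(1, int(round(params.time_res_ms * 1e-3 * fs)))
    nperseg = params.nperseg
    if len(syllable.samples) < nperseg:
        raise ValueError("syllable shorter than one spectrogram window")
    freqs, times, S = signal.spectrogram(
        syllable.samples, fs=fs, nperseg=nperseg, noverlap=nperseg - hop, mode="psd",
        window="hann",
    )
    if S.size == 0:
        raise ValueError("empty spectrogram")
    img = S
    if params.preproc:
        df = freqs[1] - freqs[0]
        win = max(3, int(round(4000.0 / df)))
        img = img - uniform_filter1d(img, size=win, axis=0, mode="nearest")
        img = median_filter(img, size=(3, 3), mode="nearest")
        img = np.clip(img, 0, None)
        mx = img.max()
        if mx > 0:
            img = frangi(img / mx, black_ridges=False)
    mask = img >= params.power_frac * img.max() if img.max() > 0 else np.zeros_like(img, bool)
    return ContourMask(mask=mask, freqs_hz=freqs, times_s=times + syllable.start, power=S)


def components(cmask: ContourMask, params: CategoryParams) -> list[ContourComponent]:
    """Connected contour components (8-connectivity) above the duration minimum."""
    lab = label(cmask.mask, connectivity=2)
    out = []
    hop_s = cmask.times_s[1] - cmask.times_s[0] if len(cmask.times_s) > 1 else 1e-3
    for region in regionprops(lab):
        fi, ti = region.coords[:, 0], region.coords[:, 1]
        times = cmask.times_s[ti]
        duration_ms = (times.max() - times.min() + hop_s) * 1e3
        if duration_ms < params.min_component_ms:
            continue
        order = np.argsort(times)
        out.append(
            ContourComponent(
                times_s=times[order],
                freqs_hz=cmask.freqs_hz[fi][order],
                powers=cmask.power[fi, ti][order],
                duration_ms=float(duration_ms),
            )
        )
    return out


def _centroid_track(comp: ContourComponent) -> tuple[np.ndarray, np.ndarray]:
    """One frequency per time bin: power-weighted centroid of the mask pixels."""
    t_unique, inv = np.unique(comp.times_s, return_inverse=True)
    f = np.zeros_like(t_unique)
    w = np.zeros_like(t_unique)
    np.add.at(f, inv, comp.freqs_hz * comp.powers)
    np.add.at(w, inv, comp.powers)
    good = w > 0
    return t_unique[good], f[good] / w[good]


def segment_fm_rates(comp: ContourComponent, segment_ms: float = 5.0) -> list[FmSegment]:
    """FM rate per 5-ms segment: least-squares slope of log2(frequency) vs time.

    The component is first collapsed to one power-weighted centroid frequency
    per time bin (harmonic stacks and thick ridges reduce to a single track).
    Residual tail segments shorter than ``segment_ms`` and segments with
    fewer than two distinct time bins are dropped.
    """
    t, f = _centroid_track(comp)
    if t.size < 2:
        return []
    seg = segment_ms * 1e-3
    t_rel = t - t[0]
    n_seg = int(np.floor((t_rel[-1] + 1e-12) / seg))
    out = []
    for k in range(n_seg):
        sel = (t_rel >= k * seg) & (t_rel < (k + 1) * seg)
        if np.count_nonzero(sel) < 2:
            continue
        ts, fsr = t[sel], f[sel]
        slope = np.polyfit(ts, np.log2(fsr), 1)[0]
        out.append(FmSegment(t_mid=float(ts.mean()), rate=float(slope)))
    return out


def usage_summary(
    segments: list[FmSegment] | np.ndarray,
    bins: np.ndarray | None = None,
    fast_cutoff_oct_s: float = 40.0,
) -> dict:
    """FM-rate usage: probability histogram, up/down fractions, fast fraction.

    Upward and downward usage fractions sum to 1 (zero-rate segments split
    evenly between the two).  The fast fraction is the probability of
    |rate| > ``fast_cutoff_oct_s``.
    """
    if isinstance(segments, np.ndarray):
        rates = segments.astype(float)
    else:
        rates = np.asarray(
            [s.rate if isinstance(s, FmSegment) else s for s in segments], float
        )
    if rates.size == 0:
        raise ValueError("no segments to summarize")
    if bins is None:
        bins = np.arange(-102.5, 105.0, 5.0)
    counts, edges = np.histogram(np.clip(rates, bins[0], bins[-1]), bins=bins)
    prob = counts / counts.sum()
    n_zero = np.count_nonzero(rates == 0)
    up = (np.count_nonzero(rates > 0) + 0.5 * n_zero) / rates.size
    return {
        "bin_edges": edges,
        "probability": prob,
        "upward_fraction": float(up),
        "downward_fraction": float(1.0 - up),
        "fast_fraction": float(np.mean(np.abs(rates) > fast_cutoff_oct_s)),
        "mean_abs_rate": float(np.mean(np.abs(rates))),
        "n_segments": int(rates.size),
    }


def extract_fm_rates(
    wave: np.ndarray, fs: float, params: CategoryParams | str = "pup"
) -> list[FmSegment]:
    """Full pipeline: waveform -> syllables -> contours -> 5-ms FM rates."""
    if isinstance(params, str):
        params = CategoryParams.preset(params)
    out: list[FmSegment] = []
    for syl in detect_syllables(wave, fs):
        try:
            cmask = extract_contour_mask(syl, params)
        except ValueError:
            continue
        for comp in components(cmask, params):
            out.extend(segment_fm_rates(comp))
    return out
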