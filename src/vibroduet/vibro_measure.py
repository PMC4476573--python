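"""Measurement definitions for substrate-borne vibratory signals.

Implements, as code, the measurement conventions used for oscillogram and
sonogram analysis of stinkbug songs: a pulse lasts from the point where the
amplitude envelope rises above the background-noise level to the point where
it falls back below it; repetition time is the onset-to-onset interval of
successive pulses; the dominant frequency is the magnitude-spectrum peak of a
Blackman-Harris-windowed segment; frequency modulation is the dominant
frequency difference between 500-ms windows at the start and end of a pulse,
optionally normalised per 1000 ms.

The amplitude envelope itself is the analytic-signal magnitude with light
moving-average smoothing — a programmatic stand-in for the oscillogram
amplitude measured visually in audio software.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.ndimage import uniform_filter1d

from .substrate import Trace

__all__ = [
    "SegmentedPulse",
    "FMMetrics",
    "envelope",
    "estimate_noise_level",
    "segment_pulses",
    "repetition_times",
    "dominant_frequency",
    "fm_metrics",
]

#: dominant-frequency search band (Hz); song content lies well inside it
FREQ_BAND = (20.0, 500.0)

#: pulses shorter than this cannot carry a meaningful spectral peak estimate
MIN_SPECTRUM_MS = 50.0


@dataclass
class SegmentedPulse:
    """A detected pulse: onset/offset (s), duration (ms), peak velocity
    (mm/s) and dominant frequency (Hz; NaN for pulses too short to
    estimate)."""

    onset: float
    offset: float
    peak_velocity: float
    dominant_frequency: float

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError("offset must be after onset")

    @property
    def duration(self) -> float:
        """Duration in ms."""
        return (self.offset - self.onset) * 1000.0


@dataclass
class FMMetrics:
    """Window-averaged frequency-modulation metrics of one pulse."""

    f_start_window: float
    f_end_window: float
    f_mid_window: float | None
    fm_start_end: float
    fm_per_1000ms: float


def envelope(trace: Trace, smooth_ms: float = 2.0) -> Trace:
    """Non-negative amplitude envelope of a trace.

    Analytic-signal (Hilbert) magnitude followed by a centred moving average
    of ``smooth_ms``. The default 2-ms window passes beat modulation up to
    ~150 Hz; for measuring beat pulses the window should stay well below the
    beat period (use a smaller ``smooth_ms`` for repetition rates near
    100 Hz).
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    env = np.abs(signal.hilbert(trace.samples))
    n = int(round(smooth_ms / 1000.0 * trace.sample_rate))
    if n > 1:
        n += 1 - n % 2  # odd length keeps the filter centred (no lag)
        env = uniform_filter1d(env, n, mode="nearest")
    return Trace(env, trace.sample_rate, trace.start_time)


def estimate_noise_level(trace: Trace, silent_interval: tuple[float, float],
                         k: float = 2.0) -> float:
    """Segmentation threshold from a signal-free stretch of the recording.

    Returns ``k`` times the RMS velocity within ``silent_interval`` — the
    programmatic version of "the noise level" above which a pulse onset is
    declared. ``k`` = 2 keeps Gaussian background below threshold ~95% of
    the time.
    """
    t0, t1 = silent_interval
    seg = trace.crop(t0, t1)
    if len(seg) == 0:
        raise ValueError("empty silent interval")
    return k * float(np.sqrt(np.mean(seg.samples ** 2)))


def segment_pulses(trace: Trace, threshold: float,
                   min_gap_ms: float = 3.0, min_duration_ms: float = 5.0,
                   hysteresis: float = 0.1,
                   smooth_ms: float = 2.0) -> list[SegmentedPulse]:
    """Threshold the amplitude envelope into pulses.

    Onsets sit at upward envelope crossings of ``threshold``; offsets at the
    following downward crossing of ``threshold * (1 - hysteresis)`` (the
    hysteresis stops envelope ripple from splitting a pulse at its own
    threshold). Sub-threshold gaps shorter than ``min_gap_ms`` are merged,
    pulses shorter than ``min_duration_ms`` discarded. Each pulse is
    annotated with its peak velocity and, when long enough, its dominant
    frequency.

    Returns an empty list on silence.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    env = envelope(trace, smooth_ms=smooth_ms).samples
    fs = trace.sample_rate
    thr_off = threshold * (1.0 - hysteresis)
    above_off = env >= thr_off
    # runs of env >= thr_off that reach the onset threshold are pulses
    edges = np.diff(above_off.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above_off[0]:
        starts = np.r_[0, starts]
    if above_off[-1]:
        ends = np.r_[ends, len(env)]
    intervals = []
    for s, e in zip(starts, ends):
        peak_i = s + int(np.argmax(env[s:e]))
        if env[peak_i] < threshold:
            continue
        # onset: first sample of the run at or above the onset threshold
        on = s + int(np.argmax(env[s:e] >= threshold))
        intervals.append([on, e])
    # merge gaps shorter than min_gap
    min_gap = int(round(min_gap_ms / 1000.0 * fs))
    merged: list[list[int]] = []
    for iv in intervals:
        if merged and iv[0] - merged[-1][1] < min_gap:
            merged[-1][1] = iv[1]
        else:
            merged.append(iv)
    min_dur = min_duration_ms / 1000.0
    pulses = []
    for on, off in merged:
        onset_t = trace.start_time + on / fs
        offset_t = trace.start_time + off / fs
        if offset_t - onset_t < min_dur:
            continue
        peak_v = float(np.max(np.abs(trace.samples[on:off])))
        if (offset_t - onset_t) * 1000.0 >= MIN_SPECTRUM_MS:
            f_dom = dominant_frequency(trace, (onset_t, offset_t))
        else:
            f_dom = float("nan")
        pulses.append(SegmentedPulse(onset_t, offset_t, peak_v, f_dom))
    return pulses


def repetition_times(pulses: list[SegmentedPulse]) -> list[float]:
    """Onset-to-onset intervals of successive pulses, in ms.

    Length ``n - 1``; empty for fewer than two pulses.
    """
    if len(pulses) < 2:
        return []
    onsets = np.array([p.onset for p in pulses])
    return list(np.diff(onsets) * 1000.0)


def dominant_frequency(trace: Trace, interval: tuple[float, float],
                       band: tuple[float, float] = FREQ_BAND) -> float:
    """Frequency of the magnitude-spectrum peak of a segment.

    The segment is Blackman-Harris windowed and zero-padded to a grid of at
    most 0.5 Hz, the peak restricted to ``band`` and refined by parabolic
    interpolation. Segments shorter than 50 ms are rejected: their intrinsic
    spectral resolution is too coarse for a single-value estimate.
    """
    seg = trace.crop(*interval)
    if len(seg) / seg.sample_rate * 1000.0 < MIN_SPECTRUM_MS:
        raise ValueError("interval must be at least 50 ms for a spectrum")
    x = (seg.samples - np.mean(seg.samples)) * signal.windows.blackmanharris(len(seg))
    nfft = 1 << int(np.ceil(np.log2(max(len(x), 2 * seg.sample_rate))))
    spec = np.abs(np.fft.rfft(x, nfft))
    freqs = np.fft.rfftfreq(nfft, 1.0 / seg.sample_rate)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    mag = spec[sel]
    f_sel = freqs[sel]
    i = int(np.argmax(mag))
    if 0 < i < len(mag) - 1:
        # parabolic refinement on the three bins around the peak
        y0, y1, y2 = mag[i - 1], mag[i], mag[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            delta = 0.5 * (y0 - y2) / denom
            return float(f_sel[i] + delta * (f_sel[1] - f_sel[0]))
    return float(f_sel[i])


def fm_metrics(trace: Trace, pulse: SegmentedPulse,
               with_middle: bool = False, window_ms: float = 500.0) -> FMMetrics:
    """Frequency-modulation metrics of one segmented pulse.

    Dominant frequency over the first and last ``window_ms`` of the pulse
    (and a centred middle window when ``with_middle``); for pulses shorter
    than three windows the window shrinks to one third of the duration.
    ``fm_per_1000ms`` normalises the start/end difference by the pulse
    duration.
    """
    dur_ms = pulse.duration
    if dur_ms < 150.0:
        raise ValueError("pulse too short (< 150 ms) for FM metrics")
    w = min(window_ms, dur_ms / 3.0) / 1000.0
    f_start = dominant_frequency(trace, (pulse.onset, pulse.onset + w))
    f_end = dominant_frequency(trace, (pulse.offset - w, pulse.offset))
    f_mid = None
    if with_middle:
        mid = (pulse.onset + pulse.offset) / 2.0
        f_mid = dominant_frequency(trace, (mid - w / 2, mid + w / 2))
    fm = abs(f_start - f_end)
    return FMMetrics(f_start_window=f_start, f_end_window=f_end,
                     f_mid_window=f_mid, fm_start_end=fm,
                     fm_per_1000ms=fm / dur_ms * 1000.0)
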