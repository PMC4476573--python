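"""Substrate model: superposition of scheduled vibrations at one recording point.

The plant is reduced to the simplest honest transmission model: each source
reaches the laser recording point with a flat (frequency-independent) gain,
signals add linearly, and the recording carries additive band-limited noise.
Bending-wave dispersion, resonance and amplitude-distance profiles are
deliberately out of scope; they would require transfer functions the model
does not attempt to invent.

Units are physical throughout: substrate velocity in mm/s, as a laser
vibrometer reports it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal
from scipy.io import wavfile

__all__ = [
    "Trace",
    "mix",
    "add_noise",
    "write_wav",
    "read_wav",
]


@dataclass
class Trace:
    """Uniformly sampled substrate-velocity time series.

    Parameters
    ----------
    samples : ndarray
        Velocity samples in mm/s.
    sample_rate : float
        Sampling rate in Hz.
    start_time : float, default 0
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    sample_rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("Trace samples must be one-dimensional")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("Trace samples must be finite")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        """Trace length in seconds."""
        return len(self.samples) / self.sample_rate

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.start_time + np.arange(len(self.samples)) / self.sample_rate

    def index_at(self, t: float) -> int:
        """Index of the sample at absolute time ``t`` (clipped to bounds)."""
        i = int(round((t - self.start_time) * self.sample_rate))
        return min(max(i, 0), len(self.samples))

    def crop(self, t0: float, t1: float) -> "Trace":
        """Sub-trace covering [t0, t1] in absolute time."""
        if t1 <= t0:
            raise ValueError("empty interval")
        i0, i1 = self.index_at(t0), self.index_at(t1)
        if i1 <= i0:
            raise ValueError("interval outside trace")
        return Trace(self.samples[i0:i1].copy(), self.sample_rate,
                     self.start_time + i0 / self.sample_rate)

    def copy(self) -> "Trace":
        return Trace(self.samples.copy(), self.sample_rate, self.start_time)


def mix(emissions: Sequence[tuple[Trace, float, float]],
        total_time: float) -> Trace:
    """Superimpose gain-scaled traces at their onsets.

    Parameters
    ----------
    emissions : sequence of (Trace, onset_s, gain)
        Each trace is placed with its first sample at ``onset_s`` and scaled
        by ``gain``. All traces must share one sample rate.
    total_time : float
        Length of the output trace in seconds; emissions are clipped to it.

    Returns
    -------
    Trace
        Sample-wise sum; zero where nothing is placed.
    """
    if not emissions:
        raise ValueError("mix requires at least one emission")
    fs = emissions[0][0].sample_rate
    for tr, _, _ in emissions:
        if tr.sample_rate != fs:
            raise ValueError("all traces passed to mix must share a sample rate")
    n_total = int(round(total_time * fs))
    out = np.zeros(n_total)
    for tr, onset, gain in emissions:
        i0 = int(round(onset * fs))
        if i0 >= n_total:
            continue
        n = min(len(tr.samples), n_total - max(i0, 0))
        src0 = max(-i0, 0)
        dst0 = max(i0, 0)
        n = min(n, len(tr.samples) - src0)
        if n > 0:
            out[dst0:dst0 + n] += gain * tr.samples[src0:src0 + n]
    return Trace(out, fs)


def add_noise(trace: Trace, noise_rms: float,
              band: tuple[float, float] = (20.0, 500.0),
              rng_seed: int | np.random.Generator = 0) -> Trace:
    """Add band-limited Gaussian noise of a stated RMS to a trace.

    The noise stands in for substrate background vibration and sets the
    "noise level" that the pulse-duration measurement rule references.
    White within the band (default 20-500 Hz), seed-reproducible.
    """
    if noise_rms < 0:
        raise ValueError("noise_rms must be >= 0")
    if noise_rms == 0:
        return trace.copy()
    lo, hi = band
    nyq = trace.sample_rate / 2
    if not (0 < lo < hi < nyq):
        raise ValueError(f"noise band {band} must lie inside (0, {nyq}) Hz")
    rng = np.random.default_rng(rng_seed) if not isinstance(
        rng_seed, np.random.Generator) else rng_seed
    white = rng.standard_normal(len(trace.samples))
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=trace.sample_rate,
                        output="sos")
    noise = signal.sosfiltfilt(sos, white)
    rms = np.sqrt(np.mean(noise ** 2))
    noise *= noise_rms / rms
    return Trace(trace.samples + noise, trace.sample_rate, trace.start_time)


# --- WAV + sidecar I/O -----------------------------------------------------
#
# WAV files are written as normalised float32 mono; the JSON sidecar records
# the physical scale so mm/s velocities survive normalisation.

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_wav(path: str | Path, trace: Trace,
              target_rate: float | None = None,
              extra_meta: dict | None = None) -> Path:
    """Write a trace as normalised mono float32 WAV plus a JSON sidecar.

    The sidecar stores ``{sample_rate, units, scale, start_time}``;
    ``samples_mm_s = wav_samples * scale``. If ``target_rate`` is given, the
    trace is resampled (polyphase) to that rate before writing.
    """
    path = Path(path)
    samples = trace.samples
    rate = trace.sample_rate
    if target_rate is not None and target_rate != rate:
        from fractions import Fraction
        frac = Fraction(target_rate / rate).limit_denominator(1000)
        samples = signal.resample_poly(samples, frac.numerator, frac.denominator)
        rate = target_rate
    scale = float(np.max(np.abs(samples)))
    if scale == 0:
        scale = 1.0
    wavfile.write(path, int(round(rate)), (samples / scale).astype(np.float32))
    meta = {
        "sample_rate": rate,
        "units": "mm/s",
        "scale": scale,
        "start_time": trace.start_time,
    }
    if extra_meta:
        meta.update(extra_meta)
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_wav(path: str | Path) -> Trace:
    """Read a WAV written by :func:`write_wav`, restoring physical units."""
    path = Path(path)
    rate, data = wavfile.read(path)
    data = np.asarray(data, dtype=float)
    if data.ndim > 1:
        data = data[:, 0]
    sidecar = _sidecar_path(path)
    scale, start_time, fs = 1.0, 0.0, float(rate)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        scale = float(meta.get("scale", 1.0))
        start_time = float(meta.get("start_time", 0.0))
        fs = float(meta.get("sample_rate", rate))
    return Trace(data * scale, fs, start_time)
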