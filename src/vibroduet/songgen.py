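"""Synthetic generator for stinkbug vibratory duet signals.

Emulates the songs *Euschistus heros* produces by abdominal tremulation on a
plant: the female first song (FS-1, triggering signal of the calling duet),
the male first song (MS-1, seconds-long pulses with a slow downward frequency
sweep), the male second song (MS-2, trains of short broadband pulses emitted
in courtship), and the male rival song (MRS, pulses with a stepped
down-sweep). Published per-song means and standard deviations of duration,
repetition time, dominant frequency and frequency-modulation endpoints are
built in as default parameter sets; every sampled quantity is drawn from a
truncated-at-zero normal with those (mean, sd).

Pure-tone and stepped-tone playback stimuli, and the standard five-pulse
MS-1 playback sequence, are provided as additional "song types" so masking
experiments can be simulated with the same machinery.

All randomness flows through a single :class:`numpy.random.Generator`; the
same seed gives bit-identical timelines and waveforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import signal, stats

from .substrate import Trace, mix

__all__ = [
    "PulseSpec",
    "SongSpec",
    "UShapeFMSpec",
    "DuetConfig",
    "ScheduledEmission",
    "TABLE_DEFAULTS",
    "DEFAULT_SAMPLE_RATE",
    "sample_pulse_spec",
    "synthesize_pulse",
    "synthesize_song",
    "synthesize_stepped_tone",
    "simulate_duet",
    "render_emissions",
    "AliasingError",
]

#: Default sample rate (Hz). All song content lies below ~450 Hz, so 4096 Hz
#: keeps traces compact while satisfying the 4x-oversampling rule below.
DEFAULT_SAMPLE_RATE = 4096.0

FMShape = Literal["constant", "linear", "plateau", "u_shape", "broadband"]


class AliasingError(ValueError):
    """Sample rate too low for the requested frequency content."""


@dataclass
class UShapeFMSpec:
    """U-shaped frequency sweep: down from the start frequency to a trough,
    then up past it — the modulation overlapped MS-1 pulses adopt.

    ``trough_position`` is the trough location as a fraction of pulse
    duration.
    """

    start_frequency: float
    downward_sweep: float
    upward_sweep: float
    trough_position: float = 0.4

    def __post_init__(self) -> None:
        if self.downward_sweep < 0 or self.upward_sweep < 0:
            raise ValueError("sweeps must be >= 0")
        if not 0 < self.trough_position < 1:
            raise ValueError("trough_position must be in (0, 1)")

    @property
    def trough_frequency(self) -> float:
        return self.start_frequency - self.downward_sweep

    @property
    def end_frequency(self) -> float:
        return self.trough_frequency + self.upward_sweep


@dataclass
class PulseSpec:
    """One vibratory pulse: duration, peak velocity and FM trajectory.

    Frequencies in Hz, duration in ms, peak velocity in mm/s.  ``fm_shape``
    selects the instantaneous-frequency trajectory:

    - ``constant``: pure tone at ``f_dominant``;
    - ``linear``: linear sweep ``f_start`` -> ``f_end``;
    - ``plateau``: linear down / flat / linear down in equal thirds,
      through ``f_mid`` (the rival-song pattern of rapid decreases
      separated by flat stretches);
    - ``u_shape``: down-then-up piecewise-linear sweep per ``ushape``;
    - ``broadband``: band-limited Gaussian noise of width ``bandwidth``
      centred on ``f_dominant`` (courtship MS-2 pulses).
    """

    duration: float
    peak_velocity: float
    f_dominant: float
    f_start: float
    f_end: float
    f_mid: float | None = None
    fm_shape: FMShape = "constant"
    bandwidth: float | None = None
    rise_fraction: float = 0.1
    fall_fraction: float = 0.1
    ushape: UShapeFMSpec | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.peak_velocity <= 0:
            raise ValueError("peak_velocity must be > 0")
        for name in ("f_dominant", "f_start", "f_end"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0 <= self.rise_fraction <= 0.5 and 0 <= self.fall_fraction <= 0.5):
            raise ValueError("rise/fall fractions must be in [0, 0.5]")
        if self.rise_fraction + self.fall_fraction > 1:
            raise ValueError("rise_fraction + fall_fraction must be <= 1")
        if self.fm_shape == "constant" and not (
                self.f_start == self.f_end == self.f_dominant):
            raise ValueError("constant shape requires f_start = f_end = f_dominant")
        if self.fm_shape == "plateau" and self.f_mid is None:
            raise ValueError("plateau shape requires f_mid")
        if self.fm_shape == "u_shape" and self.ushape is None:
            raise ValueError("u_shape requires a UShapeFMSpec")
        if self.fm_shape == "broadband" and self.bandwidth is None:
            raise ValueError("broadband shape requires bandwidth")

    @property
    def max_frequency(self) -> float:
        """Highest instantaneous frequency the pulse contains."""
        if self.fm_shape == "broadband":
            return self.f_dominant + self.bandwidth / 2
        freqs = [self.f_start, self.f_end]
        if self.f_mid is not None:
            freqs.append(self.f_mid)
        if self.ushape is not None:
            freqs += [self.ushape.start_frequency, self.ushape.end_frequency]
        return max(freqs)


@dataclass
class ScheduledEmission:
    """A pulse placed on the shared timeline, with ground-truth annotations.

    ``overlapped`` flags temporal intersection with an emission from the
    other duet partner; ``suppressed`` marks a female pulse inhibited by an
    ongoing male response (scheduled but never emitted).
    """

    source: Literal["female", "male1", "male2", "masker"]
    onset: float  # s
    spec: PulseSpec
    overlapped: bool = False
    suppressed: bool = False

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError("onset must be >= 0")

    @property
    def offset(self) -> float:
        return self.onset + self.spec.duration / 1000.0


# --- published per-song parameter sets -------------------------------------
# Each song type carries the (mean, sd) of its pulse parameters for the
# minimal-mean ("min") and maximal-mean ("max") individual, as reported for
# plant-recorded songs. MS-1 pulse duration did not differ between
# individuals, so one pooled value serves both columns. PLAYBACK_MS1 is the
# standard five-pulse playback stimulus.

TABLE_DEFAULTS: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    "FS1a": {
        "min": {"duration": (817.4, 67.8), "repetition_time": (2748.0, 718.4),
                "f_dominant": (111.2, 1.7), "f_start": (102.3, 3.3),
                "f_end": (127.1, 2.5)},
        "max": {"duration": (1381.5, 150.3), "repetition_time": (5014.0, 1607.3),
                "f_dominant": (129.7, 3.9), "f_start": (119.7, 8.7),
                "f_end": (152.0, 5.1)},
    },
    "FS1b": {
        "min": {"duration": (924.5, 186.0), "repetition_time": (2475.4, 328.7),
                "f_dominant": (107.4, 4.1), "f_start": (105.4, 2.3),
                "f_end": (119.2, 6.0)},
        "max": {"duration": (1605.0, 295.0), "repetition_time": (3097.6, 534.5),
                "f_dominant": (134.4, 1.7), "f_start": (133.4, 3.2),
                "f_end": (144.7, 4.5)},
    },
    "MS1": {
        "min": {"duration": (6839.2, 1872.6), "repetition_time": (16104.5, 9103.0),
                "f_dominant": (106.9, 3.6), "f_start": (118.8, 3.6),
                "f_end": (101.5, 2.9)},
        "max": {"duration": (6839.2, 1872.6), "repetition_time": (34069.5, 8859.0),
                "f_dominant": (158.7, 3.7), "f_start": (190.5, 4.9),
                "f_end": (153.5, 4.8)},
    },
    "MS2": {
        "min": {"duration": (57.9, 9.1), "repetition_time": (140.7, 39.5),
                "f_dominant": (105.0, 3.3)},
        "max": {"duration": (130.5, 19.3), "repetition_time": (288.8, 50.7),
                "f_dominant": (153.3, 10.2)},
    },
    "MRS": {
        "min": {"duration": (735.2, 225.1), "repetition_time": (998.0, 185.0),
                "f_dominant": (108.3, 3.0), "f_start": (143.7, 7.2),
                "f_mid": (107.8, 2.4), "f_end": (86.1, 4.3)},
        "max": {"duration": (1403.8, 382.4), "repetition_time": (1853.1, 492.8),
                "f_dominant": (136.4, 7.1), "f_start": (167.2, 8.7),
                "f_mid": (126.6, 4.0), "f_end": (101.0, 6.1)},
    },
    "PLAYBACK_MS1": {
        "min": {"duration": (6092.6, 775.3), "repetition_time": (11317.0, 1045.3),
                "f_dominant": (115.8, 2.1)},
        "max": {"duration": (6092.6, 775.3), "repetition_time": (11317.0, 1045.3),
                "f_dominant": (115.8, 2.1)},
    },
}

_FM_SHAPE_BY_TYPE: dict[str, FMShape] = {
    "FS1a": "linear", "FS1b": "linear", "MS1": "linear",
    "MRS": "plateau", "MS2": "broadband",
    "PURE_TONE": "constant", "STEPPED_TONE": "constant",
    "PLAYBACK_MS1": "constant",
}

_SONG_TYPES = tuple(_FM_SHAPE_BY_TYPE)


@dataclass
class SongSpec:
    """Distributional description of one song: per-pulse parameter (mean, sd)
    pairs, the onset-to-onset repetition time, and the pulse count.

    For MS-2, ``repetition_time`` is the within-train pulse repetition and
    ``train_repetition_time`` spaces consecutive train onsets (courtship
    trains alternate with the female call at roughly her calling rate).
    """

    song_type: str
    pulse_params: dict[str, tuple[float, float]]
    repetition_time: tuple[float, float]
    n_pulses: int = 5
    pulses_per_train: int = 5
    train_repetition_time: tuple[float, float] | None = None
    bandwidth: float = 200.0
    rise_fraction: float = 0.1
    fall_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.song_type not in _SONG_TYPES:
            raise ValueError(
                f"unknown song_type {self.song_type!r}; expected one of {_SONG_TYPES}")
        if self.n_pulses < 1:
            raise ValueError("n_pulses must be >= 1")
        for name, (_, sd) in {**self.pulse_params,
                              "repetition_time": self.repetition_time}.items():
            if sd < 0:
                raise ValueError(f"sd of {name} must be >= 0")
        if self.song_type == "MS2" and self.train_repetition_time is None:
            self.train_repetition_time = (2475.4, 0.0)

    @classmethod
    def from_table(cls, song_type: str, column: str = "min",
                   n_pulses: int = 5, peak_velocity: tuple[float, float] = (1.0, 0.0),
                   sd_scale: float = 1.0, **overrides) -> "SongSpec":
        """Build a song from the published parameter table.

        ``column`` selects the minimal- or maximal-mean individual;
        ``sd_scale`` scales every sd (0 gives deterministic pulses at the
        table means).
        """
        if song_type not in TABLE_DEFAULTS:
            raise ValueError(f"no table defaults for song_type {song_type!r}")
        if column not in ("min", "max"):
            raise ValueError("column must be 'min' or 'max'")
        row = dict(TABLE_DEFAULTS[song_type][column])
        rep = row.pop("repetition_time")
        params = {k: (m, s * sd_scale) for k, (m, s) in row.items()}
        params["peak_velocity"] = peak_velocity
        return cls(song_type=song_type, pulse_params=params,
                   repetition_time=(rep[0], rep[1] * sd_scale),
                   n_pulses=n_pulses, **overrides)

    @classmethod
    def pure_tone(cls, frequency: float, duration_ms: float = 1000.0,
                  velocity: float = 1.0, n_pulses: int = 1,
                  repetition_time: tuple[float, float] | None = None) -> "SongSpec":
        """A constant-frequency playback stimulus."""
        rep = repetition_time or (2 * duration_ms, 0.0)
        return cls(song_type="PURE_TONE",
                   pulse_params={"duration": (duration_ms, 0.0),
                                 "f_dominant": (frequency, 0.0),
                                 "peak_velocity": (velocity, 0.0)},
                   repetition_time=rep, n_pulses=n_pulses,
                   rise_fraction=0.0, fall_fraction=0.0)


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _draw_truncated(mean: float, sd: float, rng: np.random.Generator) -> float:
    """Normal(mean, sd) truncated at zero; degenerate at the mean when sd=0."""
    if sd == 0:
        return mean
    a = (0.0 - mean) / sd
    return float(stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd,
                                     random_state=rng))


def sample_pulse_spec(song: SongSpec,
                      rng_seed: int | np.random.Generator) -> PulseSpec:
    """Draw one pulse specification from a song's parameter distributions.

    Every field comes from a truncated-at-zero normal with the configured
    (mean, sd); the FM shape is fixed by the song type.
    """
    rng = _as_rng(rng_seed)
    shape = _FM_SHAPE_BY_TYPE[song.song_type]
    draw = {k: _draw_truncated(m, s, rng) for k, (m, s) in song.pulse_params.items()}
    duration = draw.get("duration", 1000.0)
    velocity = draw.get("peak_velocity", 1.0)
    f_dom = draw.get("f_dominant", 100.0)
    common = dict(duration=duration, peak_velocity=velocity,
                  rise_fraction=song.rise_fraction,
                  fall_fraction=song.fall_fraction)
    if shape == "constant":
        return PulseSpec(f_dominant=f_dom, f_start=f_dom, f_end=f_dom,
                         fm_shape="constant", **common)
    if shape == "broadband":
        return PulseSpec(f_dominant=f_dom, f_start=f_dom, f_end=f_dom,
                         fm_shape="broadband", bandwidth=song.bandwidth, **common)
    f_start, f_end = draw["f_start"], draw["f_end"]
    if shape == "linear":
        return PulseSpec(f_dominant=f_dom, f_start=f_start, f_end=f_end,
                         fm_shape="linear", **common)
    if shape == "plateau":
        return PulseSpec(f_dominant=f_dom, f_start=f_start, f_end=f_end,
                         f_mid=draw["f_mid"], fm_shape="plateau", **common)
    raise ValueError(f"unhandled fm shape {shape!r}")  # pragma: no cover


# --- waveform synthesis ----------------------------------------------------

def _frequency_trajectory(spec: PulseSpec, n: int) -> np.ndarray:
    """Instantaneous frequency f(t) at each of ``n`` samples."""
    x = np.linspace(0.0, 1.0, n)
    if spec.fm_shape == "constant":
        return np.full(n, spec.f_dominant)
    if spec.fm_shape == "linear":
        return spec.f_start + (spec.f_end - spec.f_start) * x
    if spec.fm_shape == "plateau":
        # equal thirds: sweep down to the plateau, hold, sweep down again
        return np.interp(x, [0.0, 1 / 3, 2 / 3, 1.0],
                         [spec.f_start, spec.f_mid, spec.f_mid, spec.f_end])
    if spec.fm_shape == "u_shape":
        u = spec.ushape
        return np.interp(x, [0.0, u.trough_position, 1.0],
                         [u.start_frequency, u.trough_frequency, u.end_frequency])
    raise ValueError(f"no trajectory for shape {spec.fm_shape!r}")


def _envelope(spec: PulseSpec, n: int) -> np.ndarray:
    """Trapezoidal amplitude envelope: linear rise, flat, linear fall."""
    x = np.linspace(0.0, 1.0, n)
    env = np.ones(n)
    if spec.rise_fraction > 0:
        env = np.minimum(env, x / spec.rise_fraction)
    if spec.fall_fraction > 0:
        env = np.minimum(env, (1.0 - x) / spec.fall_fraction)
    return np.clip(env, 0.0, 1.0)


def synthesize_pulse(spec: PulseSpec, sample_rate: float = DEFAULT_SAMPLE_RATE,
                     rng: int | np.random.Generator | None = None) -> Trace:
    """Render one pulse as a velocity trace.

    Tonal shapes integrate the instantaneous-frequency trajectory into a
    phase-continuous sinusoid; ``broadband`` draws Gaussian noise band-pass
    filtered to ``f_dominant +- bandwidth/2``. The amplitude envelope is a
    linear-ramp trapezoid and the trace length equals the spec duration.

    The sample rate must be at least 4x the highest frequency content.
    """
    if sample_rate < 4 * spec.max_frequency:
        raise AliasingError(
            f"sample_rate {sample_rate} Hz < 4 x max frequency "
            f"{spec.max_frequency} Hz")
    n = max(int(round(spec.duration / 1000.0 * sample_rate)), 2)
    env = _envelope(spec, n)
    if spec.fm_shape == "broadband":
        gen = _as_rng(rng if rng is not None else 0)
        # Gaussian-shaped power spectrum centred on f_dominant with FWHM =
        # bandwidth, realised by frequency-domain shaping of white noise.
        # Content below 20 Hz is zeroed: song energy lives above it, and
        # near-DC components smear analytic-signal envelopes across gaps.
        white = gen.standard_normal(n)
        spec_f = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n, 1.0 / sample_rate)
        sigma = spec.bandwidth / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        profile = np.exp(-0.5 * ((freqs - spec.f_dominant) / sigma) ** 2)
        profile[freqs < 20.0] = 0.0
        wave = np.fft.irfft(spec_f * profile, n)
        wave /= np.max(np.abs(wave))
    else:
        freq = _frequency_trajectory(spec, n)
        phase = 2 * np.pi * np.cumsum(freq) / sample_rate
        wave = np.sin(phase - phase[0])
    return Trace(spec.peak_velocity * env * wave, sample_rate)


def synthesize_song(song: SongSpec, rng_seed: int | np.random.Generator,
                    sample_rate: float = DEFAULT_SAMPLE_RATE,
                    max_retries: int = 100,
                    tail_s: float = 0.25
                    ) -> tuple[Trace, list[ScheduledEmission]]:
    """Render a whole song and its ground-truth annotations.

    Pulses are placed onset-to-onset at sampled repetition times. For
    non-overlapping song types a repetition draw shorter than the pulse it
    follows is redrawn (bounded retries). MS-2 places its short pulses in
    trains of ``pulses_per_train``, trains spaced by
    ``train_repetition_time``.
    """
    rng = _as_rng(rng_seed)
    source = "female" if song.song_type.startswith("FS") else (
        "masker" if song.song_type in ("PURE_TONE", "STEPPED_TONE") else "male1")
    emissions: list[ScheduledEmission] = []
    onset = 0.0
    if song.song_type == "MS2":
        train_start = 0.0
        placed = 0
        while placed < song.n_pulses:
            onset = train_start
            for _ in range(min(song.pulses_per_train, song.n_pulses - placed)):
                spec = sample_pulse_spec(song, rng)
                emissions.append(ScheduledEmission(source, onset, spec))
                onset += _sample_repetition(song, spec, rng, max_retries) / 1000.0
                placed += 1
            train_start += _draw_truncated(*song.train_repetition_time, rng) / 1000.0
    else:
        for _ in range(song.n_pulses):
            spec = sample_pulse_spec(song, rng)
            emissions.append(ScheduledEmission(source, onset, spec))
            onset += _sample_repetition(song, spec, rng, max_retries) / 1000.0
    total = max(e.offset for e in emissions) + tail_s
    trace = render_emissions(emissions, total, sample_rate, rng)
    return trace, emissions


def _sample_repetition(song: SongSpec, spec: PulseSpec,
                       rng: np.random.Generator, max_retries: int) -> float:
    """Repetition-time draw, redrawn while it undercuts the pulse duration."""
    rep = _draw_truncated(*song.repetition_time, rng)
    tries = 0
    while rep < spec.duration:
        tries += 1
        if tries > max_retries:
            raise RuntimeError(
                f"could not draw repetition time >= pulse duration "
                f"({spec.duration:.1f} ms) in {max_retries} tries")
        rep = _draw_truncated(*song.repetition_time, rng)
    return rep


def synthesize_stepped_tone(frequencies: list[float], step_duration: float,
                            sample_rate: float = DEFAULT_SAMPLE_RATE,
                            velocity: float = 1.0) -> Trace:
    """Fused sequence of constant-frequency steps, phase-continuous at joins.

    Emulates the stepped playback program: contiguous one-second pure-tone
    segments rising across the stimulus range, no inter-segment gaps.
    """
    if not frequencies:
        raise ValueError("frequencies must be non-empty")
    if sample_rate < 4 * max(frequencies):
        raise AliasingError("sample_rate < 4 x max frequency")
    n_step = int(round(step_duration / 1000.0 * sample_rate))
    freq = np.repeat(np.asarray(frequencies, dtype=float), n_step)
    phase = 2 * np.pi * np.cumsum(freq) / sample_rate
    return Trace(velocity * np.sin(phase - phase[0]), sample_rate)


# --- duet simulation -------------------------------------------------------

#: Duration multipliers of the overlapped female call, by masker frequency
#: (Hz), from the control-vs-overlapped duration table: prolongation is
#: strong near the song's own frequency band and absent far from it.
DEFAULT_FEMALE_PROLONGATION: dict[float, float] = {
    75.0: 1083.1 / 1118.1,
    100.0: 2745.5 / 1281.7,
    125.0: 1565.3 / 1071.8,
    150.0: 1388.3 / 1221.5,
    200.0: 1169.0 / 1183.0,
}


@dataclass
class DuetConfig:
    """Timing and reaction rules for a simulated female-male calling duet.

    The female emits FS-1 at her repetition time; each emitted FS-1 triggers
    one MS-1 after ``male_latency``. A pending FS-1 whose onset falls inside
    an ongoing MS-1 is suppressed with ``inhibition_probability`` (the paper
    reports both inhibition and continued calling). With
    ``reactions_enabled``, overlapped FS-1 pulses are prolonged per
    ``female_prolongation`` and overlapped MS-1 pulses switch to a U-shaped
    sweep whose start frequency restores ``male_frequency_shift`` Hz of
    FS-1/MS-1 start-frequency separation.
    """

    female_song: SongSpec = field(
        default_factory=lambda: SongSpec.from_table("FS1a", "min"))
    male_song: SongSpec = field(
        default_factory=lambda: SongSpec.from_table("MS1", "min"))
    male_latency: tuple[float, float] = (600.0, 150.0)  # ms
    inhibition_probability: float = 0.5
    female_prolongation: dict[float, float] = field(
        default_factory=lambda: dict(DEFAULT_FEMALE_PROLONGATION))
    male_frequency_shift: float = 48.5  # Hz, target FS-1/MS-1 start separation
    male_ushape_downward: float = 29.2  # Hz
    male_ushape_upward: float = 28.3  # Hz
    male_ushape_trough: float = 0.4
    reactions_enabled: bool = False

    def __post_init__(self) -> None:
        if self.male_latency[0] < 0 or self.male_latency[1] < 0:
            raise ValueError("latency mean and sd must be >= 0")
        if not 0 <= self.inhibition_probability <= 1:
            raise ValueError("inhibition_probability must be in [0, 1]")
        if any(m <= 0 for m in self.female_prolongation.values()):
            raise ValueError("prolongation multipliers must be > 0")


def simulate_duet(config: DuetConfig, total_time: float,
                  rng_seed: int | np.random.Generator) -> list[ScheduledEmission]:
    """Generate the scheduled-emission timeline of one calling duet.

    Returns every scheduled emission (suppressed female pulses included,
    flagged) sorted by onset, with ground-truth overlap flags computed by
    interval intersection between female and male emissions.
    """
    if total_time <= 0:
        raise ValueError("total_time must be > 0")
    rng = _as_rng(rng_seed)
    emissions: list[ScheduledEmission] = []
    male_intervals: list[tuple[float, float]] = []
    t = 0.0
    while t < total_time:
        fspec = sample_pulse_spec(config.female_song, rng)
        inside_ms1 = any(s <= t < e for s, e in male_intervals)
        if inside_ms1 and rng.random() < config.inhibition_probability:
            emissions.append(ScheduledEmission("female", t, fspec, suppressed=True))
        else:
            emissions.append(ScheduledEmission("female", t, fspec))
            latency = _draw_truncated(*config.male_latency, rng) / 1000.0
            mspec = sample_pulse_spec(config.male_song, rng)
            m_onset = t + latency
            emissions.append(ScheduledEmission("male1", m_onset, mspec))
            male_intervals.append((m_onset, m_onset + mspec.duration / 1000.0))
        t += _draw_truncated(*config.female_song.repetition_time, rng) / 1000.0
    _flag_overlaps(emissions)
    if config.reactions_enabled:
        _apply_reactions(emissions, config)
    emissions.sort(key=lambda e: e.onset)
    return emissions


def _flag_overlaps(emissions: list[ScheduledEmission]) -> None:
    """Mark emissions whose interval intersects one from the other partner."""
    active = [e for e in emissions if not e.suppressed]
    females = [e for e in active if e.source == "female"]
    males = [e for e in active if e.source.startswith("male")]
    for a, others in ((females, males), (males, females)):
        for e in a:
            e.overlapped = any(
                e.onset < o.offset and o.onset < e.offset for o in others)


def _nearest_key(table: dict[float, float], value: float) -> float:
    return min(table, key=lambda k: abs(k - value))


def _apply_reactions(emissions: list[ScheduledEmission],
                     config: DuetConfig) -> None:
    """Masking reactions: female prolongation, male U-shaped frequency shift.

    Applied to the overlap pattern of the unreacted timeline (one pass);
    the reactions model the insects' response to hearing an overlap, not a
    re-planned schedule.
    """
    females = [e for e in emissions
               if e.source == "female" and not e.suppressed]
    males = [e for e in emissions if e.source.startswith("male")]
    for e in emissions:
        if e.suppressed or not e.overlapped:
            continue
        if e.source == "female":
            partner = next((m for m in males
                            if e.onset < m.offset and m.onset < e.offset), None)
            f_mask = partner.spec.f_dominant if partner else e.spec.f_dominant
            mult = config.female_prolongation[
                _nearest_key(config.female_prolongation, f_mask)]
            e.spec = replace(e.spec, duration=e.spec.duration * mult)
        else:
            partner = next((f for f in females
                            if e.onset < f.offset and f.onset < e.offset), None)
            f_ref = partner.spec.f_start if partner else e.spec.f_start
            u = UShapeFMSpec(
                start_frequency=f_ref + config.male_frequency_shift,
                downward_sweep=config.male_ushape_downward,
                upward_sweep=config.male_ushape_upward,
                trough_position=config.male_ushape_trough)
            e.spec = replace(e.spec, fm_shape="u_shape", ushape=u,
                             f_start=u.start_frequency, f_end=u.end_frequency)


def render_emissions(emissions: list[ScheduledEmission], total_time: float,
                     sample_rate: float = DEFAULT_SAMPLE_RATE,
                     rng: int | np.random.Generator | None = None,
                     gains: dict[str, float] | None = None) -> Trace:
    """Render a timeline to one substrate trace (suppressed pulses omitted).

    ``gains`` maps source name to a flat per-source gain (default 1); the
    relative amplitudes of co-propagating signals at the recording point are
    free parameters of the substrate model.
    """
    gains = gains or {}
    gen = _as_rng(rng if rng is not None else 0)
    placed = [(synthesize_pulse(e.spec, sample_rate, gen), e.onset,
               gains.get(e.source, 1.0))
              for e in emissions if not e.suppressed]
    if not placed:
        return Trace(np.zeros(int(round(total_time * sample_rate))), sample_rate)
    return mix(placed, total_time)
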