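"""Shared helpers for building small synthetic traces in tests."""

import numpy as np

from vibroduet import (
    SongSpec,
    Trace,
    add_noise,
    mix,
    sample_pulse_spec,
    synthesize_pulse,
)

FS = 4096.0


def make_tone(freq: float, duration_ms: float, velocity: float = 1.0,
              fs: float = FS) -> Trace:
    """Rectangular-envelope pure tone."""
    spec = sample_pulse_spec(SongSpec.pure_tone(freq, duration_ms, velocity), 0)
    return synthesize_pulse(spec, fs)


def two_tone_overlap(f_a: float, f_b: float, overlap_s: float,
                     velocity: float = 1.0, fs: float = FS) -> Trace:
    """Two fully overlapped equal-amplitude tones, no lead-in."""
    return mix([(make_tone(f_a, overlap_s * 1000.0, velocity, fs), 0.0, 1.0),
                (make_tone(f_b, overlap_s * 1000.0, velocity, fs), 0.0, 1.0)],
               overlap_s)


def masked_tone_recording(f_mask: float, f_sig: float, overlap_s: float,
                          noise_rms: float, seed: int,
                          velocity: float = 1.0, lead_s: float = 1.0,
                          fs: float = FS) -> tuple[Trace, float, float]:
    """Masker + signal tone with a silent lead-in for noise estimation.

    Returns (trace, overlap_start_s, overlap_end_s); the masker runs from
    ``lead_s`` to the end, the signal tone from ``lead_s + 0.5`` for
    ``overlap_s`` seconds.
    """
    total = lead_s + 0.5 + overlap_s + 0.5
    trace = mix(
        [(make_tone(f_mask, (overlap_s + 1.0) * 1000.0, velocity, fs), lead_s, 1.0),
         (make_tone(f_sig, overlap_s * 1000.0, velocity, fs), lead_s + 0.5, 1.0)],
        total)
    trace = add_noise(trace, noise_rms, rng_seed=seed)
    return trace, lead_s + 0.5, lead_s + 0.5 + overlap_s
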