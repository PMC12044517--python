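"""Roving-oddball tone sequences and three-tone waveform synthesis.

The roving oddball paradigm presents runs of identical "standard" tones
(250, 500 or 1000 Hz here) whose frequency changes at unpredictable run
boundaries.  The first tone of a new run is the "deviant"; by repetition it
becomes the new standard.  Two products are generated:

* event streams with a 550 ms stimulus-onset asynchrony, consumed by the
  sensor-level simulation (:mod:`rovingnet.meg_synth`), and
* three-tone "triad" waveforms (50 ms tones separated by 199 ms silences,
  548 ms total at 5000 Hz), the acoustic inputs to the network model
  (:mod:`rovingnet.rnn_core`).

The two timing conventions are deliberately distinct and never mixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ToneEvent",
    "StimulusTriad",
    "DEFAULT_FREQUENCIES",
    "AUDIO_RATE_HZ",
    "TONE_DURATION_MS",
    "TRIAD_GAP_MS",
    "TRIAD_DURATION_MS",
    "SOA_MS",
    "generate_roving_sequence",
    "synthesize_triad_waveform",
    "events_to_table",
    "write_wav",
]

DEFAULT_FREQUENCIES: tuple[float, ...] = (250.0, 500.0, 1000.0)
AUDIO_RATE_HZ: float = 5000.0
TONE_DURATION_MS: float = 50.0
#: silence between triad tones (network-input convention, not the 500 ms
#: inter-tone interval of the sensor-level stream)
TRIAD_GAP_MS: float = 199.0
TRIAD_DURATION_MS: float = 548.0
#: stimulus-onset asynchrony of the sensor-level event stream
SOA_MS: float = 550.0

_TONE_SAMPLES = int(round(TONE_DURATION_MS / 1000.0 * AUDIO_RATE_HZ))  # 250
_GAP_SAMPLES = int(round(TRIAD_GAP_MS / 1000.0 * AUDIO_RATE_HZ))  # 995
TRIAD_SAMPLES = 3 * _TONE_SAMPLES + 2 * _GAP_SAMPLES  # 2740


@dataclass(frozen=True)
class ToneEvent:
    """A single tone in a roving-oddball stream.

    ``role`` is ``"deviant"`` for the first tone of a non-initial run,
    ``"first_repeat"`` for the second, and ``"standard"`` otherwise.
    """

    frequency_hz: float
    role: str
    onset_ms: float


@dataclass(frozen=True)
class StimulusTriad:
    """A three-tone input sequence and its sampled waveform.

    ``condition`` is ``"D"`` iff the third frequency differs from the first
    two (which are always equal), otherwise ``"S"``.
    """

    frequencies: tuple[float, float, float]
    condition: str
    waveform: np.ndarray = field(repr=False)
    sampling_rate_hz: float = AUDIO_RATE_HZ


def triad_condition(frequencies) -> str:
    """Classify a frequency triple as standard ('S') or deviant ('D')."""
    f1, f2, f3 = frequencies
    if f1 != f2:
        raise ValueError(
            f"first two triad frequencies must be equal, got {f1} and {f2}"
        )
    return "D" if f3 != f1 else "S"


def generate_roving_sequence(
    n_runs: int,
    run_length_range: tuple[int, int] = (3, 12),
    frequencies=DEFAULT_FREQUENCIES,
    seed: int = 0,
) -> list[ToneEvent]:
    """Generate a roving-oddball event stream.

    Each run's length is drawn uniformly from ``run_length_range``
    (inclusive) and its frequency uniformly from ``frequencies`` excluding
    the previous run's frequency.  Events are spaced ``SOA_MS`` apart.
    """
    frequencies = tuple(float(f) for f in frequencies)
    if len(set(frequencies)) < 2:
        raise ValueError("need at least 2 distinct frequencies for a roving design")
    lo, hi = int(run_length_range[0]), int(run_length_range[1])
    if lo > hi or lo < 1:
        raise ValueError(f"invalid run length range [{lo}, {hi}]")
    if n_runs < 1:
        raise ValueError("n_runs must be positive")

    rng = np.random.default_rng(seed)
    events: list[ToneEvent] = []
    prev_freq: float | None = None
    onset = 0.0
    for run in range(n_runs):
        choices = [f for f in frequencies if f != prev_freq]
        freq = choices[rng.integers(len(choices))]
        length = int(rng.integers(lo, hi + 1))
        for i in range(length):
            if run == 0:
                role = "standard"
            elif i == 0:
                role = "deviant"
            elif i == 1:
                role = "first_repeat"
            else:
                role = "standard"
            events.append(ToneEvent(freq, role, onset))
            onset += SOA_MS
        prev_freq = freq
    return events


def synthesize_triad_waveform(frequencies) -> StimulusTriad:
    """Synthesize the 548 ms three-tone waveform sampled at 5000 Hz.

    Tones are 50 ms unit-amplitude sinusoids starting at phase zero; the two
    199 ms gaps are exact zeros.
    """
    freqs = tuple(float(f) for f in frequencies)
    if len(freqs) != 3:
        raise ValueError("a triad needs exactly 3 frequencies")
    for f in freqs:
        if f >= AUDIO_RATE_HZ / 2.0:
            raise ValueError(
                f"tone frequency {f} Hz at or above Nyquist ({AUDIO_RATE_HZ / 2:g} Hz)"
            )
        if f <= 0:
            raise ValueError("tone frequency must be positive")
    condition = triad_condition(freqs)

    t_tone = np.arange(_TONE_SAMPLES) / AUDIO_RATE_HZ
    wave = np.zeros(TRIAD_SAMPLES)
    step = _TONE_SAMPLES + _GAP_SAMPLES
    for k, f in enumerate(freqs):
        start = k * step
        wave[start : start + _TONE_SAMPLES] = np.sin(2.0 * np.pi * f * t_tone)
    return StimulusTriad(freqs, condition, wave)


def events_to_table(events: list[ToneEvent]) -> pd.DataFrame:
    """Event stream as a table with columns onset_ms, frequency_hz, role."""
    return pd.DataFrame(
        {
            "onset_ms": [e.onset_ms for e in events],
            "frequency_hz": [e.frequency_hz for e in events],
            "role": [e.role for e in events],
        }
    )


def write_wav(triad: StimulusTriad, path) -> None:
    """Write a triad waveform as a mono 16-bit WAV file."""
    from scipy.io import wavfile

    scaled = np.int16(np.clip(triad.waveform, -1.0, 1.0) * 32767)
    wavfile.write(path, int(triad.sampling_rate_hz), scaled)
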