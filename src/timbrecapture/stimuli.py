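"""Harmonic-tone synthesis with controlled brightness and roughness.

Every stimulus is a harmonic complex: ``N`` harmonics at ``n * f0`` with
amplitude weights ``1 / n**alpha``.  The spectral slope exponent ``alpha``
sets the spectral centroid (SC), the amplitude-weighted mean frequency that
correlates with perceived brightness::

    SC(alpha) = f0 * sum_{i=1..N} i * i**-alpha / sum_{i=1..N} i**-alpha

SC is strictly decreasing in ``alpha`` (for N >= 2), so a tone can be
specified either by its exponent or — as the experiments do — by a target SC
that is inverted numerically to an exponent.

Roughness is introduced by sinusoidal amplitude modulation at ``f_mod``
(50 Hz by default) with depth ``m``::

    s_sing(t) = (1 + m * cos(2*pi*f_mod*t)) * s_dis(t)

Tones carry linear onset/offset ramps and are peak-normalized; presentation
level in dB SPL is metadata only (loudness equalization is a measured
constant of the experimental setup, not something synthesis reproduces).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.io import wavfile
from scipy.optimize import brentq

DEFAULT_RATE = 44_100

__all__ = [
    "ToneSpec",
    "AudioBuffer",
    "spectral_centroid",
    "solve_alpha_for_sc",
    "synth_tone",
    "apply_am",
    "measured_sc",
    "measured_am_depth",
    "assemble_sequence",
    "write_wav",
]


@dataclass(frozen=True)
class ToneSpec:
    """Full parametric description of one tone.

    Parameters
    ----------
    f0
        Fundamental frequency in Hz.
    alpha
        Spectral slope exponent; harmonic ``n`` is weighted ``1/n**alpha``.
    n_harmonics
        Number of harmonics (>= 1).
    duration_ms
        Total tone duration, ramps included.
    ramp_ms
        Linear onset and offset ramp duration.
    am_depth
        Amplitude-modulation depth ``m`` in [0, 1]; 0 disables modulation.
    am_freq_hz
        Modulation frequency (roughness range, default 50 Hz).
    level_db
        Nominal presentation level in dB SPL.  Metadata only.
    """

    f0: float
    alpha: float
    n_harmonics: int = 20
    duration_ms: float = 170.0
    ramp_ms: float = 5.0
    am_depth: float = 0.0
    am_freq_hz: float = 50.0
    level_db: float = 80.0

    def __post_init__(self) -> None:
        if not self.f0 > 0:
            raise ValueError(f"f0 must be positive, got {self.f0}")
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")
        if not np.isfinite(self.alpha):
            raise ValueError("alpha must be finite")
        if not 0.0 <= self.am_depth <= 1.0:
            raise ValueError(f"am_depth must lie in [0, 1], got {self.am_depth}")
        if 2 * self.ramp_ms > self.duration_ms:
            raise ValueError("ramps longer than the tone itself")

    def replace(self, **changes) -> "ToneSpec":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class AudioBuffer:
    """Peak-normalized mono audio: samples in [-1, 1] at a given rate."""

    samples: np.ndarray
    rate: int = DEFAULT_RATE

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate

    def time(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.rate


def _harmonic_weights(alpha: float, n_harmonics: int) -> np.ndarray:
    n = np.arange(1, n_harmonics + 1, dtype=float)
    return n ** -float(alpha)


def spectral_centroid(alpha: float, f0: float, n_harmonics: int = 20) -> float:
    """Closed-form spectral centroid of the 1/n**alpha harmonic complex, in Hz."""
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    w = _harmonic_weights(alpha, n_harmonics)
    n = np.arange(1, n_harmonics + 1, dtype=float)
    return float(f0 * np.sum(n * w) / np.sum(w))


def solve_alpha_for_sc(
    target_sc: float,
    f0: float,
    n_harmonics: int = 20,
    alpha_range: tuple[float, float] = (-10.0, 80.0),
    rel_tol: float = 1e-9,
) -> float:
    """Invert the SC formula: exponent alpha whose centroid equals ``target_sc``.

    SC is strictly monotone decreasing in alpha, so the root is unique when it
    exists.  Raises ``ValueError`` with the attainable [low, high] interval if
    the target lies outside it.
    """
    lo_a, hi_a = alpha_range
    sc_hi = spectral_centroid(lo_a, f0, n_harmonics)  # small alpha -> bright
    sc_lo = spectral_centroid(hi_a, f0, n_harmonics)  # large alpha -> ~f0
    if not sc_lo < target_sc <= sc_hi:
        raise ValueError(
            f"target SC {target_sc:.3f} Hz outside attainable range "
            f"({sc_lo:.3f}, {sc_hi:.3f}] Hz for f0={f0:.3f}, "
            f"alpha in [{lo_a}, {hi_a}]"
        )
    f = lambda a: spectral_centroid(a, f0, n_harmonics) - target_sc
    alpha = brentq(f, lo_a, hi_a, xtol=1e-12, rtol=8.882e-16)
    # refine guarantee: relative SC error
    achieved = spectral_centroid(alpha, f0, n_harmonics)
    assert abs(achieved - target_sc) <= rel_tol * target_sc + 1e-9
    return float(alpha)


def _ramp_envelope(n_samples: int, ramp_ms: float, rate: int) -> np.ndarray:
    env = np.ones(n_samples)
    n_ramp = int(round(ramp_ms * 1e-3 * rate))
    if n_ramp > 0:
        ramp = np.linspace(0.0, 1.0, n_ramp, endpoint=False)
        env[:n_ramp] = ramp
        env[-n_ramp:] = ramp[::-1]
    return env


def synth_tone(
    spec: ToneSpec, rate: int = DEFAULT_RATE, strict_nyquist: bool = False
) -> AudioBuffer:
    """Render a ToneSpec to audio.

    Harmonics are summed in sine phase (all phases zero); harmonics at or above
    the Nyquist frequency are silently dropped unless ``strict_nyquist``, in
    which case the offending harmonic index is reported.  Amplitude modulation
    (if any) is applied to the summed complex, then linear ramps, then peak
    normalization, so presentation level is envelope-independent.
    """
    n_samples = int(round(spec.duration_ms * 1e-3 * rate))
    t = np.arange(n_samples) / rate
    w = _harmonic_weights(spec.alpha, spec.n_harmonics)
    y = np.zeros(n_samples)
    nyquist = rate / 2
    for n in range(1, spec.n_harmonics + 1):
        f_n = n * spec.f0
        if f_n >= nyquist:
            if strict_nyquist:
                raise ValueError(
                    f"harmonic {n} at {f_n:.1f} Hz exceeds Nyquist ({nyquist:.1f} Hz)"
                )
            continue
        y += w[n - 1] * np.sin(2 * np.pi * f_n * t)
    if spec.am_depth > 0:
        y *= 1.0 + spec.am_depth * np.cos(2 * np.pi * spec.am_freq_hz * t)
    y *= _ramp_envelope(n_samples, spec.ramp_ms, rate)
    peak = np.max(np.abs(y))
    if peak > 0:
        y /= peak
    return AudioBuffer(samples=y, rate=rate)


def apply_am(
    buffer: AudioBuffer, m: float, fmod: float = 50.0, renormalize: bool = True
) -> AudioBuffer:
    """Multiply by the modulator ``1 + m*cos(2*pi*fmod*t)``.

    ``renormalize`` re-peak-normalizes afterwards so nominal level does not
    depend on the modulation envelope.
    """
    if not 0.0 <= m <= 1.0:
        raise ValueError(f"modulation depth must lie in [0, 1], got {m}")
    y = buffer.samples * (1.0 + m * np.cos(2 * np.pi * fmod * buffer.time()))
    if renormalize:
        peak = np.max(np.abs(y))
        if peak > 0:
            y = y / peak
    return AudioBuffer(samples=y, rate=buffer.rate)


def _steady_segment(buffer: AudioBuffer, edge_ms: float = 10.0) -> np.ndarray:
    n_edge = int(round(edge_ms * 1e-3 * buffer.rate))
    seg = buffer.samples[n_edge : len(buffer.samples) - n_edge]
    if len(seg) < 16:
        seg = buffer.samples
    return seg


def measured_sc(buffer: AudioBuffer, edge_ms: float = 10.0) -> float:
    """Spectral oracle: amplitude-weighted mean frequency of the steady state.

    Hann-windowed rFFT of the segment with on/off ramps excluded.  Raises on a
    silent buffer.
    """
    seg = _steady_segment(buffer, edge_ms)
    if np.max(np.abs(seg)) == 0:
        raise ValueError("cannot measure the spectral centroid of silence")
    win = np.hanning(len(seg))
    spec = np.abs(np.fft.rfft(seg * win))
    freqs = np.fft.rfftfreq(len(seg), d=1.0 / buffer.rate)
    return float(np.sum(freqs * spec) / np.sum(spec))


def measured_am_depth(
    buffer: AudioBuffer, fmod: float = 50.0, edge_ms: float = 15.0
) -> float:
    """Demodulation oracle: AM depth recovered from the Hilbert envelope.

    Projects the envelope of the steady-state segment onto the complex
    modulator at ``fmod``; the depth is twice the normalized projection
    magnitude, which is exact for ``env = A*(1 + m*cos(2*pi*fmod*t + phi))``.
    """
    seg = _steady_segment(buffer, edge_ms)
    env = np.abs(signal.hilbert(seg))
    t = np.arange(len(env)) / buffer.rate
    # whole modulation cycles only, to keep the projection unbiased
    cycle = buffer.rate / fmod
    n_keep = int(len(env) // cycle * cycle)
    env, t = env[:n_keep], t[:n_keep]
    proj = np.mean(env * np.exp(-2j * np.pi * fmod * t))
    return float(2 * np.abs(proj) / np.mean(env))


def assemble_sequence(
    specs: list[ToneSpec], ioi_ms: float = 230.0, rate: int = DEFAULT_RATE
) -> AudioBuffer:
    """Lay out tones at a constant inter-onset interval and sum overlaps.

    Tone ``k`` (0-based) starts at ``k * ioi_ms``; the buffer ends with the
    last sample of the latest-ending tone.  If summed overlaps exceed full
    scale the result is re-peak-normalized (with the default 230 ms IOI and
    <= 220 ms tones nothing overlaps and samples are untouched).
    """
    n_ioi = int(round(ioi_ms * 1e-3 * rate))
    rendered = [synth_tone(s, rate) for s in specs]
    total = max(
        k * n_ioi + len(buf.samples) for k, buf in enumerate(rendered)
    )
    out = np.zeros(total)
    for k, buf in enumerate(rendered):
        start = k * n_ioi
        out[start : start + len(buf.samples)] += buf.samples
    peak = np.max(np.abs(out))
    if peak > 1.0:
        out /= peak
    return AudioBuffer(samples=out, rate=rate)


def write_wav(path, buffer: AudioBuffer) -> None:
    """Write PCM 16-bit mono WAV."""
    data = np.clip(buffer.samples, -1.0, 1.0)
    wavfile.write(path, buffer.rate, (data * 32767).astype(np.int16))
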