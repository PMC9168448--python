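"""Synthesis of the 40 Hz amplitude-modulated auditory stimulus.

The auditory steady-state response (ASSR) paradigm drives cortical gamma
synchrony with a pure-tone carrier whose amplitude is modulated at 40 Hz:

    A(t) = sin(2*pi*f_c*t) * (1 + m*cos(2*pi*f_m*t))

where ``f_c`` is the carrier frequency (1000 Hz), ``f_m`` the modulation
frequency (40 Hz) and ``m`` the modulation depth.  A short fade-in/out
ramp removes onset/offset clicks and the waveform is normalized to unit
peak so 16-bit quantization cannot clip.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile

__all__ = ["AMToneSpec", "generate_am_tone", "write_wav", "read_wav"]


@dataclass(frozen=True)
class AMToneSpec:
    """Parameters of the amplitude-modulated tone.

    Attributes
    ----------
    carrier_hz : float
        Carrier frequency ``f_c`` in Hz.
    mod_hz : float
        Modulation frequency ``f_m`` in Hz.
    mod_depth : float
        Modulation depth ``m`` in (0, 1].
    duration_s : float
        Stimulus duration in seconds.
    sample_rate_hz : float
        Audio sampling rate.
    fade_s : float
        Duration of the fade-in and fade-out ramps.
    normalize : bool
        Divide by the peak absolute amplitude so max|A| = 1.
    fade_shape : str
        ``"linear"`` ramp (default) or ``"cosine"`` (raised-cosine).
    """

    carrier_hz: float = 1000.0
    mod_hz: float = 40.0
    mod_depth: float = 1.0
    duration_s: float = 1.0
    sample_rate_hz: float = 44100.0
    fade_s: float = 0.006
    normalize: bool = True
    fade_shape: str = "linear"

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be positive, got {self.duration_s}")
        if self.sample_rate_hz <= 0:
            raise ValueError(f"sample_rate_hz must be positive, got {self.sample_rate_hz}")
        if not (0 < self.mod_depth <= 1):
            raise ValueError(f"mod_depth must lie in (0, 1], got {self.mod_depth}")
        if not (self.carrier_hz > self.mod_hz > 0):
            raise ValueError(
                f"need carrier_hz > mod_hz > 0, got {self.carrier_hz}, {self.mod_hz}"
            )
        if 2 * self.fade_s >= self.duration_s:
            raise ValueError("fade windows overlap: 2*fade_s must be < duration_s")
        if self.sample_rate_hz <= 2 * (self.carrier_hz + self.mod_hz):
            raise ValueError("sample rate below Nyquist limit for the upper sideband")
        if self.fade_shape not in ("linear", "cosine"):
            raise ValueError(f"unknown fade_shape {self.fade_shape!r}")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sample_rate_hz))


def _fade_ramp(n: int, shape: str) -> np.ndarray:
    if shape == "linear":
        return np.linspace(0.0, 1.0, n, endpoint=False)
    # raised cosine from 0 to 1
    return 0.5 * (1.0 - np.cos(np.pi * np.arange(n) / n))


def generate_am_tone(spec: AMToneSpec = AMToneSpec()) -> np.ndarray:
    """Generate the amplitude-modulated tone as a 1-D float array.

    Sample ``k`` (before fading/normalization) equals
    ``sin(2*pi*f_c*t_k) * (1 + m*cos(2*pi*f_m*t_k))`` with
    ``t_k = k / sample_rate_hz``; ``t`` starts at 0.
    """
    t = np.arange(spec.n_samples) / spec.sample_rate_hz
    wave = np.sin(2 * np.pi * spec.carrier_hz * t) * (
        1.0 + spec.mod_depth * np.cos(2 * np.pi * spec.mod_hz * t)
    )

    n_fade = int(round(spec.fade_s * spec.sample_rate_hz))
    if n_fade > 0:
        ramp = _fade_ramp(n_fade, spec.fade_shape)
        wave[:n_fade] *= ramp
        wave[-n_fade:] *= ramp[::-1]

    if spec.normalize:
        peak = np.max(np.abs(wave))
        if peak > 0:
            wave = wave / peak
    return wave


def write_wav(waveform: np.ndarray, sample_rate_hz: float, path: str | Path) -> Path:
    """Write a waveform in [-1, 1] to a 16-bit PCM WAV file."""
    waveform = np.asarray(waveform, dtype=np.float64)
    if waveform.size and np.max(np.abs(waveform)) > 1.0 + 1e-12:
        raise ValueError("samples must lie in [-1, 1]; normalize before writing")
    path = Path(path)
    pcm = np.round(np.clip(waveform, -1.0, 1.0) * 32767.0).astype(np.int16)
    wavfile.write(path, int(round(sample_rate_hz)), pcm)
    return path


def read_wav(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a 16-bit PCM WAV back to float samples in [-1, 1]."""
    rate, pcm = wavfile.read(Path(path))
    return pcm.astype(np.float64) / 32767.0, rate
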