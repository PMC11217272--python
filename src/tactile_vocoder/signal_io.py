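"""Audio container and WAV I/O.

`AudioSignal` is the mono, finite-sample container every stage operates on.
WAV files are read/written with scipy.io.wavfile; integer PCM is converted to
float in [-1, 1] on read and float32 is always written (tactile stimuli carry
physical units of m/s², stored as float samples with the unit documented in
the sidecar metadata).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

__all__ = ["AudioSignal", "read_wav", "write_wav"]

_PCM_SCALE = {np.dtype(np.int16): 2.0 ** 15, np.dtype(np.int32): 2.0 ** 31,
              np.dtype(np.uint8): 2.0 ** 7}


@dataclass(frozen=True)
class AudioSignal:
    """A mono audio (or acceleration) waveform with its sampling rate."""

    samples: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        x = np.asarray(self.samples, dtype=np.float64)
        if x.ndim != 1:
            raise ValueError("AudioSignal must be mono (1-D)")
        if not np.all(np.isfinite(x)):
            raise ValueError("AudioSignal samples must be finite")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        object.__setattr__(self, "samples", x)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate_hz

    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.square(self.samples))))

    def resample(self, rate_hz: int) -> "AudioSignal":
        """Polyphase anti-aliased resampling to an integer target rate."""
        if rate_hz == self.rate_hz:
            return self
        from math import gcd
        src = int(round(self.rate_hz))
        if abs(src - self.rate_hz) > 1e-9:
            raise ValueError("resampling requires an integer source rate")
        g = gcd(int(rate_hz), src)
        y = resample_poly(self.samples, int(rate_hz) // g, src // g)
        return AudioSignal(y, rate_hz)

    def scaled(self, gain: float) -> "AudioSignal":
        return AudioSignal(self.samples * gain, self.rate_hz)


def read_wav(path) -> AudioSignal:
    """Read a mono WAV file (PCM 8/16/32-bit or float), scaling PCM to ±1."""
    rate, data = wavfile.read(path)
    if data.ndim == 2:
        if data.shape[1] != 1:
            raise ValueError(f"{path}: expected mono audio, got "
                             f"{data.shape[1]} channels")
        data = data[:, 0]
    if data.size == 0:
        raise ValueError(f"{path}: empty audio file")
    x = data.astype(np.float64)
    if data.dtype in _PCM_SCALE:
        if data.dtype == np.uint8:
            x -= 128.0
        x /= _PCM_SCALE[data.dtype]
    return AudioSignal(x, rate)


def write_wav(path, audio: AudioSignal | np.ndarray, rate_hz: float | None = None,
              channels: np.ndarray | None = None) -> None:
    """Write float32 WAV; `channels` writes an (n_ch, N) matrix as multichannel."""
    if isinstance(audio, AudioSignal):
        samples, rate_hz = audio.samples, audio.rate_hz
    else:
        if rate_hz is None:
            raise ValueError("rate_hz required when writing a bare array")
        samples = np.asarray(audio, dtype=np.float64)
    if channels is not None:
        data = np.asarray(channels, dtype=np.float32).T
    else:
        data = samples.astype(np.float32)
    wavfile.write(path, int(rate_hz), data)
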