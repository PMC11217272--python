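"""Speech-shaped masking noise.

The long-term average speech spectrum (LTASS) of a phoneme corpus is
estimated from 4096-sample STFT magnitudes averaged over all non-silent
frames of all tokens.  A 2049-tap linear-phase FIR filter is fitted to that
spectrum by least-squares and used to filter white Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve, get_window, welch

from .signal_io import AudioSignal

__all__ = ["LTASSpectrum", "NoiseShapingFilter", "estimate_ltass",
           "fit_noise_filter", "generate_speech_shaped_noise"]

WINDOW_LEN = 4096
NUM_TAPS = 2049
#: Frame-RMS silence criterion: frames below this fraction of the token's
#: peak frame RMS are excluded, mirroring the 10 % amplitude convention used
#: for endpoint trimming elsewhere in the pipeline.
SILENCE_RMS_FRAC = 0.10


@dataclass(frozen=True)
class LTASSpectrum:
    """Mean one-sided STFT magnitude on the 2049-bin grid of a 4096 FFT."""

    freqs_hz: np.ndarray
    magnitude: np.ndarray
    rate_hz: float
    window_len: int = WINDOW_LEN
    num_frames: int = 0

    def __post_init__(self) -> None:
        if self.freqs_hz.shape != self.magnitude.shape:
            raise ValueError("frequency grid and magnitude length mismatch")
        if np.any(self.magnitude < 0):
            raise ValueError("LTASS magnitudes must be non-negative")


@dataclass(frozen=True)
class NoiseShapingFilter:
    """Linear-phase FIR fitted to an LTASS, with the least-squares residual."""

    taps: np.ndarray
    rate_hz: float
    residual: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.taps)):
            raise ValueError("filter taps must be finite")

    @property
    def num_taps(self) -> int:
        return self.taps.size


def _frames(x: np.ndarray, win_len: int, hop: int) -> np.ndarray:
    n = 1 + (x.size - win_len) // hop if x.size >= win_len else 0
    if n == 0:  # short token: single zero-padded frame
        buf = np.zeros(win_len)
        buf[:x.size] = x
        return buf[None, :]
    idx = hop * np.arange(n)[:, None] + np.arange(win_len)
    return x[idx]


def estimate_ltass(corpus: list[AudioSignal], hop: int | None = None
                   ) -> LTASSpectrum:
    """Average STFT magnitude over all non-silent frames of all tokens.

    Frames are 4096 samples, Hann-windowed, hopped by half the window.
    A frame is silent when its RMS falls below 10 % of the token's peak
    frame RMS; an entirely silent corpus is an error.
    """
    if not corpus:
        raise ValueError("empty corpus")
    rate = corpus[0].rate_hz
    if any(tok.rate_hz != rate for tok in corpus):
        raise ValueError("corpus tokens must share one sampling rate")
    hop = hop or WINDOW_LEN // 2
    window = get_window("hann", WINDOW_LEN, fftbins=True)

    acc = np.zeros(WINDOW_LEN // 2 + 1)
    count = 0
    for tok in corpus:
        frames = _frames(tok.samples, WINDOW_LEN, hop)
        rms = np.sqrt(np.mean(np.square(frames), axis=1))
        peak = rms.max()
        if peak <= 0:
            continue
        keep = frames[rms >= SILENCE_RMS_FRAC * peak]
        if keep.size == 0:
            continue
        acc += np.abs(np.fft.rfft(keep * window, axis=1)).sum(axis=0)
        count += keep.shape[0]
    if count == 0:
        raise ValueError("corpus is entirely silent; LTASS undefined")
    freqs = np.fft.rfftfreq(WINDOW_LEN, 1.0 / rate)
    return LTASSpectrum(freqs_hz=freqs, magnitude=acc / count, rate_hz=rate,
                        num_frames=count)


def fit_noise_filter(ltass: LTASSpectrum, num_taps: int = NUM_TAPS
                     ) -> NoiseShapingFilter:
    """Least-squares linear-phase FIR fit to the LTASS on its bin grid.

    A type-I filter of odd length L has zero-phase amplitude
    ``A(w) = a0 + Σ a_m cos(m w)`` with M = (L+1)/2 free coefficients; the
    coefficients minimising ``Σ_k (A(w_k) − LTASS_k)²`` over the 2049-bin
    grid are found directly, and the squared residual reported.
    """
    if num_taps % 2 == 0:
        raise ValueError("num_taps must be odd (type-I linear phase)")
    target = ltass.magnitude
    grid = np.pi * np.arange(target.size) / (target.size - 1)
    half = (num_taps + 1) // 2
    basis = np.cos(np.outer(grid, np.arange(half)))
    coef, res, *_ = np.linalg.lstsq(basis, target, rcond=None)
    fitted = basis @ coef
    residual = float(np.sum(np.square(fitted - target)))
    taps = np.zeros(num_taps)
    mid = num_taps // 2
    taps[mid] = coef[0]
    taps[mid + 1:] = coef[1:] / 2.0
    taps[:mid] = taps[:mid:-1]
    return NoiseShapingFilter(taps=taps, rate_hz=ltass.rate_hz,
                              residual=residual)


def generate_speech_shaped_noise(filt: NoiseShapingFilter, duration_s: float,
                                 rng: np.random.Generator) -> AudioSignal:
    """White Gaussian noise of ``duration_s`` shaped by ``filt``.

    The white source is drawn longer than requested so the filter transient
    can be discarded; the spectrum of the output follows the fitted
    magnitude response.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration_s * filt.rate_hz))
    pad = filt.num_taps - 1
    white = rng.standard_normal(n + pad)
    shaped = fftconvolve(white, filt.taps, mode="full")[pad:pad + n]
    return AudioSignal(shaped, filt.rate_hz)


def noise_spectrum_db(noise: AudioSignal, nperseg: int = WINDOW_LEN
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Welch amplitude spectrum of a noise token in dB (helper for checks)."""
    f, pxx = welch(noise.samples, fs=noise.rate_hz, nperseg=nperseg)
    return f, 10.0 * np.log10(np.maximum(pxx, 1e-30))
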