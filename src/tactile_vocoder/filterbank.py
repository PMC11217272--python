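"""ERB-spaced FIR analysis filter bank.

Eight linear-phase band-pass filters whose nine edges are equally spaced on
the ERB-number scale (Glasberg & Moore):

    ERBn(f) = 21.4 * log10(0.00437 * f + 1)

between 50 and 7000 Hz.  Filters are windowed-sinc (Hamming) designs of the
configured order; their -6 dB points sit at the band edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import firwin

from .config import VocoderConfig

__all__ = ["erb_number", "erb_number_to_hz", "erb_band_edges",
           "FilterBank", "design_erb_filterbank"]


def erb_number(freq_hz):
    """Frequency in Hz → ERB number (cochlear-filter count below freq)."""
    return 21.4 * np.log10(0.00437 * np.asarray(freq_hz, dtype=float) + 1.0)


def erb_number_to_hz(erb):
    """Inverse of :func:`erb_number`."""
    return (10.0 ** (np.asarray(erb, dtype=float) / 21.4) - 1.0) / 0.00437


def erb_band_edges(lo_hz: float, hi_hz: float, num_bands: int) -> np.ndarray:
    """num_bands+1 edges equally spaced in ERB number between lo and hi."""
    e = np.linspace(erb_number(lo_hz), erb_number(hi_hz), num_bands + 1)
    edges = erb_number_to_hz(e)
    edges[0], edges[-1] = lo_hz, hi_hz  # pin endpoints against round-trip error
    return edges


@dataclass(frozen=True)
class FilterBank:
    """Per-band FIR taps plus the ERB design metadata."""

    taps: np.ndarray        # (num_bands, fir_order + 1)
    edges_hz: np.ndarray    # (num_bands + 1,) monotone band edges
    edges_erb: np.ndarray   # same edges on the ERB-number scale
    rate_hz: float

    @property
    def num_bands(self) -> int:
        return self.taps.shape[0]

    @property
    def order(self) -> int:
        return self.taps.shape[1] - 1

    def apply(self, x: np.ndarray) -> np.ndarray:
        """Filter x through every band, zero-phase (symmetric taps, centred).

        Returns an (num_bands, len(x)) matrix aligned with the input.
        """
        from scipy.signal import fftconvolve
        out = np.empty((self.num_bands, x.size))
        for i in range(self.num_bands):
            out[i] = fftconvolve(x, self.taps[i], mode="same")
        return out


def design_erb_filterbank(config: VocoderConfig) -> FilterBank:
    """Design the analysis bank for ``config``.

    Raises ``ValueError`` if the upper band limit reaches Nyquist or the
    lower limit sits below 20 Hz (edge response undefined that low for the
    configured order).
    """
    if config.band_lo_hz < 20.0:
        raise ValueError("band_lo_hz must be >= 20 Hz")
    if config.band_hi_hz >= config.audio_rate_hz / 2:
        raise ValueError("band_hi_hz must be below Nyquist")
    edges = erb_band_edges(config.band_lo_hz, config.band_hi_hz,
                           config.num_bands)
    ntaps = config.fir_order + 1
    taps = np.empty((config.num_bands, ntaps))
    for i in range(config.num_bands):
        taps[i] = firwin(ntaps, [edges[i], edges[i + 1]], window="hamming",
                         pass_zero=False, fs=config.audio_rate_hz)
    return FilterBank(taps=taps, edges_hz=edges, edges_erb=erb_number(edges),
                      rate_hz=config.audio_rate_hz)
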