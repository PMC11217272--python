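"""Spectrogram rendering for audio input and tactile envelope matrices.

Audio style: 8-ms Hann window, hop of 1 sample, zero-padded to 8192 points,
shown in dB relative to the maximum STFT magnitude.  Tactile style: the
band-envelope matrix itself, in dB relative to the maximum envelope
amplitude (no windowing).
"""

from __future__ import annotations

import numpy as np

from .signal_io import AudioSignal
from .vocoder import BandEnvelopes

__all__ = ["audio_spectrogram_db", "tactile_spectrogram_db",
           "render_tactile_spectrogram"]

_FLOOR_DB = -120.0


def audio_spectrogram_db(audio: AudioSignal, window_ms: float = 8.0,
                         hop: int = 1, nfft: int = 8192,
                         max_frames: int | None = None):
    """(times_s, freqs_hz, dB matrix) with dB re the maximum magnitude."""
    x = audio.samples
    win_len = int(round(window_ms * 1e-3 * audio.rate_hz))
    window = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(win_len) / win_len))
    n_frames = max(1, (x.size - win_len) // hop + 1)
    if max_frames is not None and n_frames > max_frames:
        hop = int(np.ceil((x.size - win_len) / (max_frames - 1)))
        n_frames = (x.size - win_len) // hop + 1
    mag = np.empty((nfft // 2 + 1, n_frames), dtype=np.float32)
    for chunk in range(0, n_frames, 512):
        stop = min(chunk + 512, n_frames)
        idx = (hop * np.arange(chunk, stop))[:, None] + np.arange(win_len)
        mag[:, chunk:stop] = np.abs(
            np.fft.rfft(x[idx] * window, n=nfft, axis=1)).T
    peak = mag.max()
    if peak <= 0:
        db = np.full(mag.shape, _FLOOR_DB, dtype=np.float32)
    else:
        db = 20.0 * np.log10(np.maximum(mag / peak, 10.0 ** (_FLOOR_DB / 20)))
    times = (hop * np.arange(n_frames) + win_len / 2) / audio.rate_hz
    freqs = np.fft.rfftfreq(nfft, 1.0 / audio.rate_hz)
    return times, freqs, db


def tactile_spectrogram_db(env: BandEnvelopes):
    """(times_s, band indices, dB matrix) re the maximum envelope amplitude."""
    peak = env.env.max()
    if peak <= 0:
        db = np.full(env.env.shape, _FLOOR_DB)
    else:
        db = 20.0 * np.log10(np.maximum(env.env / peak,
                                        10.0 ** (_FLOOR_DB / 20)))
    times = np.arange(env.num_samples) / env.rate_hz
    return times, np.arange(env.num_bands), db


def render_tactile_spectrogram(source, style: str = "tactile",
                               out_path=None, title: str | None = None,
                               max_frames: int = 2000):
    """Render a spectrogram figure; returns the matplotlib Figure.

    ``source`` is an :class:`AudioSignal` for ``style='audio'`` or a
    :class:`BandEnvelopes` for ``style='tactile'``.  ``max_frames`` bounds
    the audio-style frame count (the hop is widened for long inputs).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    if style == "audio":
        if not isinstance(source, AudioSignal):
            raise TypeError("audio style requires an AudioSignal")
        t, f, db = audio_spectrogram_db(source, max_frames=max_frames)
        im = ax.pcolormesh(t, f, db, vmin=-80, vmax=0, shading="auto")
        ax.set_ylabel("Frequency (Hz)")
        ax.set_ylim(0, min(5000, f[-1]))
    elif style == "tactile":
        if not isinstance(source, BandEnvelopes):
            raise TypeError("tactile style requires BandEnvelopes")
        t, bands, db = tactile_spectrogram_db(source)
        im = ax.pcolormesh(t, bands, db, vmin=-60, vmax=0, shading="auto")
        ax.set_ylabel("Band index")
    else:
        raise ValueError("style must be 'audio' or 'tactile'")
    ax.set_xlabel("Time (s)")
    fig.colorbar(im, ax=ax, label="dB re max")
    if title:
        ax.set_title(title)
    if out_path is not None:
        fig.savefig(out_path, dpi=120, bbox_inches="tight")
    return fig
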