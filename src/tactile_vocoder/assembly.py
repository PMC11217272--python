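"""Trial-stimulus assembly: endpoint trimming, duration matching, SNR mixing,
and noise-interval construction.

Conventions (all configurable through :class:`AssemblyParams`): phoneme
endpoints are where |x| first/last reaches 10 % of the token's peak; SNR is
defined on the phoneme's trimmed RMS against the noise token's full RMS; in
noise conditions the noise token is 400 ms longer than the longest phoneme
in the trial, ramped on/off with 50 ms raised-cosine ramps, and the phoneme
starts 200 ms after noise onset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import AssemblyParams
from .signal_io import AudioSignal

__all__ = ["DurationMatchExceptions", "NoiseInterval", "detect_endpoints",
           "trimmed_rms", "match_durations", "mix_at_snr",
           "assemble_noise_interval", "measure_snr_db"]

#: Consonants whose isolated productions differ from running speech, exempt
#: (together with all diphthongs) from duration matching.
EXEMPT_CONSONANTS = frozenset({"g", "d", "l", "r", "v", "w", "j"})
DIPHTHONGS = frozenset({"ɔɪ", "eɪ", "aʊ", "ɪə", "əʊ", "ʊə", "eə"})


@dataclass(frozen=True)
class DurationMatchExceptions:
    """Phoneme labels exempt from duration matching."""

    labels: frozenset[str] = field(
        default_factory=lambda: EXEMPT_CONSONANTS | DIPHTHONGS)

    def exempt(self, label: str) -> bool:
        return label in self.labels


def detect_endpoints(audio: AudioSignal, threshold_frac: float = 0.10
                     ) -> tuple[int, int]:
    """First and last sample indices where |x| reaches the relative threshold.

    The threshold is ``threshold_frac`` of the token's maximum absolute
    amplitude, so endpoints are invariant to overall gain.
    """
    x = np.abs(audio.samples)
    peak = x.max() if x.size else 0.0
    if peak <= 0.0:
        raise ValueError("endpoints undefined for all-zero audio")
    above = np.nonzero(x >= threshold_frac * peak)[0]
    return int(above[0]), int(above[-1])


def trimmed_rms(audio: AudioSignal, threshold_frac: float = 0.10) -> float:
    """RMS of the token between its relative-threshold endpoints."""
    start, end = detect_endpoints(audio, threshold_frac)
    seg = audio.samples[start:end + 1]
    return float(np.sqrt(np.mean(np.square(seg))))


def _raised_cosine_fade_out(n: int) -> np.ndarray:
    """Half-Hann fade from 1 to 0 over n samples (reaching 0 at the end)."""
    return 0.5 * (1.0 + np.cos(np.pi * np.arange(1, n + 1) / n))


def _raised_cosine_fade_in(n: int) -> np.ndarray:
    return _raised_cosine_fade_out(n)[::-1]


def match_durations(tok_a: AudioSignal, tok_b: AudioSignal,
                    label_a: str, label_b: str,
                    exceptions: DurationMatchExceptions | None = None,
                    params: AssemblyParams | None = None
                    ) -> tuple[AudioSignal, AudioSignal]:
    """Fade both tokens to zero at the shorter token's 1 %-threshold end.

    Pairs containing a diphthong or an exempt consonant are returned
    unchanged.  Otherwise both tokens are multiplied by a raised-cosine
    fade-out of ``match_ramp_ms`` that reaches zero at the shorter token's
    end point (where its level last exceeds 1 % of peak); samples beyond that
    point are zeroed.  Matching never lengthens a token.
    """
    exceptions = exceptions or DurationMatchExceptions()
    params = params or AssemblyParams()
    if exceptions.exempt(label_a) or exceptions.exempt(label_b):
        return tok_a, tok_b
    thr = params.dur_end_threshold_frac
    end = min(detect_endpoints(tok_a, thr)[1], detect_endpoints(tok_b, thr)[1])
    ramp_len = int(round(params.match_ramp_ms * 1e-3 * tok_a.rate_hz))
    start = end + 1 - ramp_len
    if start < 0:
        warnings.warn("token shorter than the matching ramp; ramp truncated")
        ramp_len, start = end + 1, 0
    fade = _raised_cosine_fade_out(ramp_len)

    def apply(tok: AudioSignal) -> AudioSignal:
        y = tok.samples.copy()
        stop = min(start + ramp_len, y.size)
        y[start:stop] *= fade[:stop - start]
        y[stop:] = 0.0
        return AudioSignal(y, tok.rate_hz)

    return apply(tok_a), apply(tok_b)


def _snr_noise_gain(phoneme: AudioSignal, noise: AudioSignal,
                    params: AssemblyParams) -> float:
    """Gain making the noise RMS sit snr_db below the phoneme's trimmed RMS."""
    rms_p = trimmed_rms(phoneme, params.snr_trim_threshold_frac)
    rms_n = noise.rms()
    if rms_p <= 0 or rms_n <= 0:
        raise ValueError("SNR undefined for silent phoneme or noise")
    return rms_p / (rms_n * 10.0 ** (params.snr_db / 20.0))


def mix_at_snr(phoneme: AudioSignal, noise: AudioSignal,
               params: AssemblyParams | None = None) -> AudioSignal:
    """Sum phoneme and gain-adjusted noise at the configured SNR.

    The noise is scaled so its full-token RMS sits ``snr_db`` below the
    phoneme's trimmed RMS (10 % endpoints); leading/trailing silence in the
    phoneme therefore does not affect the gain.  The shorter signal is
    zero-padded.
    """
    params = params or AssemblyParams()
    if phoneme.rate_hz != noise.rate_hz:
        raise ValueError("phoneme and noise rates differ")
    gain = _snr_noise_gain(phoneme, noise, params)
    n = max(len(phoneme), len(noise))
    out = np.zeros(n)
    out[:len(phoneme)] += phoneme.samples
    out[:len(noise)] += gain * noise.samples
    return AudioSignal(out, phoneme.rate_hz)


@dataclass(frozen=True)
class NoiseInterval:
    """An assembled noise-condition interval, with components retained."""

    mixture: AudioSignal
    noise_token: AudioSignal      # scaled, ramped noise as presented
    phoneme_padded: AudioSignal   # phoneme aligned into the interval
    noise_start_sample: int       # excision offset into the noise source
    phoneme_onset_sample: int


def assemble_noise_interval(phoneme: AudioSignal, noise_src: AudioSignal,
                            longest_ms: float,
                            params: AssemblyParams | None = None,
                            rng: np.random.Generator | None = None
                            ) -> NoiseInterval:
    """Build one noise-condition interval around a phoneme token.

    The noise token is ``longest_ms + noise_pad_ms`` long, excised from
    ``noise_src`` at a random (seeded) start, ramped on/off with 50 ms
    raised-cosine ramps, and scaled so the trimmed-RMS SNR equals
    ``params.snr_db`` (the noise RMS is measured on the ramped token, so
    re-measuring the SNR on the components returns the requested value
    exactly).  The phoneme is summed in starting ``phoneme_delay_ms`` after
    noise onset, which also leaves at least that much noise after the
    phoneme ends.
    """
    params = params or AssemblyParams()
    if rng is None:
        raise ValueError("assembly requires a seeded random generator")
    if phoneme.rate_hz != noise_src.rate_hz:
        raise ValueError("phoneme and noise rates differ")
    fs = phoneme.rate_hz
    if len(phoneme) > int(round(longest_ms * 1e-3 * fs)) + 1:
        raise ValueError("longest_ms is shorter than the phoneme itself")
    n_noise = int(round((longest_ms + params.noise_pad_ms) * 1e-3 * fs))
    if len(noise_src) < n_noise:
        raise ValueError("noise source shorter than the required token")
    start = int(rng.integers(0, len(noise_src) - n_noise + 1))
    token = noise_src.samples[start:start + n_noise].copy()

    n_ramp = int(round(params.noise_ramp_ms * 1e-3 * fs))
    token[:n_ramp] *= _raised_cosine_fade_in(n_ramp)
    token[-n_ramp:] *= _raised_cosine_fade_out(n_ramp)

    ramped = AudioSignal(token, fs)
    gain = _snr_noise_gain(phoneme, ramped, params)
    noise_token = ramped.scaled(gain)

    delay = int(round(params.phoneme_delay_ms * 1e-3 * fs))
    padded = np.zeros(n_noise)
    padded[delay:delay + len(phoneme)] = phoneme.samples
    mixture = AudioSignal(noise_token.samples + padded, fs)
    return NoiseInterval(mixture=mixture, noise_token=noise_token,
                         phoneme_padded=AudioSignal(padded, fs),
                         noise_start_sample=start, phoneme_onset_sample=delay)


def measure_snr_db(phoneme: AudioSignal, noise_token: AudioSignal,
                   trim_threshold_frac: float = 0.10) -> float:
    """Re-measure SNR: trimmed phoneme RMS minus full noise-token RMS, dB."""
    rms_p = trimmed_rms(phoneme, trim_threshold_frac)
    rms_n = noise_token.rms()
    return 20.0 * np.log10(rms_p / rms_n)
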