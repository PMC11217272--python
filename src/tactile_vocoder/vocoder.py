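"""Audio-to-tactile conversion chain.

Stages, in order: active-level normalisation → resample to 16 kHz → ERB
filter bank → Hilbert envelope per band, low-passed at 23 Hz (zero-phase) →
optional multi-band dynamic-range expansion → amplitude modulation of eight
fixed-phase vibro-tactile carrier tones with per-band sensitivity gains →
RMS calibration to the nominal level, optionally roved ±3 dB.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import butter, filtfilt, hilbert

from .config import ExpansionParams, VocoderConfig
from .filterbank import FilterBank, design_erb_filterbank
from .level import normalize_active_level
from .signal_io import AudioSignal

__all__ = ["BandEnvelopes", "TactileStimulus", "extract_band_envelopes",
           "expand_envelopes", "synthesize_tactile", "scale_and_rove",
           "vocode"]


@dataclass(frozen=True)
class BandEnvelopes:
    """Non-negative per-band amplitude envelopes, (num_bands, N) at rate_hz."""

    env: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        e = np.asarray(self.env, dtype=np.float64)
        if e.ndim != 2:
            raise ValueError("env must be a (num_bands, N) matrix")
        if not np.all(np.isfinite(e)):
            raise ValueError("envelopes must be finite")
        if np.any(e < 0):
            raise ValueError("envelopes must be non-negative")
        object.__setattr__(self, "env", e)

    @property
    def num_bands(self) -> int:
        return self.env.shape[0]

    @property
    def num_samples(self) -> int:
        return self.env.shape[1]


@dataclass(frozen=True)
class TactileStimulus:
    """Calibrated acceleration waveform (m/s²) plus per-band components."""

    waveform: np.ndarray
    rate_hz: float
    per_band: np.ndarray | None = None
    applied_rove_db: float = 0.0

    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.square(self.waveform))))

    def level_db_re_1u_ms2(self) -> float:
        return 20.0 * np.log10(self.rms() / 1e-6)


def extract_band_envelopes(audio: AudioSignal, bank: FilterBank,
                           config: VocoderConfig) -> BandEnvelopes:
    """Band-pass → analytic-signal magnitude → zero-phase 23 Hz low-pass.

    The low-pass is a 6th-order Butterworth run forward and backward
    (zero-phase; 12th-order magnitude).  Small negative values produced by
    the backward pass are clamped to zero.
    """
    if audio.rate_hz != config.audio_rate_hz:
        raise ValueError(
            f"audio rate {audio.rate_hz} != configured {config.audio_rate_hz}")
    if len(audio) <= bank.order:
        raise ValueError(
            f"audio ({len(audio)} samples) shorter than the filter transient "
            f"({bank.order} samples)")
    bands = bank.apply(audio.samples)
    mag = np.abs(hilbert(bands, axis=-1))
    sos_ba = butter(config.env_lpf_order, config.env_lpf_corner_hz,
                    fs=config.audio_rate_hz)
    env = filtfilt(*sos_ba, mag, axis=-1)
    np.clip(env, 0.0, None, out=env)
    return BandEnvelopes(env=env, rate_hz=config.audio_rate_hz)


def _smooth_gain_db(target_db: np.ndarray, a_att: float, a_rel: float
                    ) -> np.ndarray:
    """One-pole smoothing with separate attack (rising) / release coefficients."""
    out = np.empty_like(target_db)
    g = 0.0
    tgt = target_db.tolist()
    for n, t in enumerate(tgt):
        a = a_att if t > g else a_rel
        g = a * g + (1.0 - a) * t
        out[n] = g
    return out


def expand_envelopes(env: BandEnvelopes, params: ExpansionParams
                     ) -> BandEnvelopes:
    """Per-band dynamic-range expansion of the amplitude envelopes.

    For each band, the threshold is the band's envelope RMS level plus
    ``params.threshold_offset_db`` (default −5 dB).  The static curve is the
    identity below threshold; above it, output level rises by the expansion
    ratio r = 1 + slope/6.0206 per input dB.  The per-sample gain (in dB) is
    smoothed by one-pole ballistics: the attack constant applies while the
    gain target is rising.  An all-zero band, whose RMS is undefined in dB,
    passes through unchanged.
    """
    if not params.enabled:
        return env
    fs = env.rate_hz
    a_att = float(np.exp(-1.0 / (fs * params.attack_ms * 1e-3)))
    a_rel = float(np.exp(-1.0 / (fs * params.release_ms * 1e-3)))
    excess_gain = params.ratio - 1.0

    out = np.empty_like(env.env)
    for i, e in enumerate(env.env):
        rms = np.sqrt(np.mean(np.square(e)))
        if rms <= 0.0:
            out[i] = e
            continue
        thresh_db = 20.0 * np.log10(rms) + params.threshold_offset_db
        with np.errstate(divide="ignore"):
            level_db = 20.0 * np.log10(e)  # e == 0 → -inf, below threshold
        target_db = excess_gain * np.maximum(level_db - thresh_db, 0.0)
        gain_db = _smooth_gain_db(target_db, a_att, a_rel)
        out[i] = e * 10.0 ** (gain_db / 20.0)
    return BandEnvelopes(env=out, rate_hz=fs)


def synthesize_tactile(env: BandEnvelopes, config: VocoderConfig
                       ) -> TactileStimulus:
    """Modulate the fixed-phase carrier tones with the band envelopes.

    Band i contributes ``env_i(t) * g_i * sin(2π f_i t)`` with linear gain
    ``g_i`` from ``carrier_gains_db`` and phase zero at stimulus onset.
    """
    if env.num_bands != config.num_bands:
        raise ValueError(f"envelope bands ({env.num_bands}) != configured "
                         f"bands ({config.num_bands})")
    t = np.arange(env.num_samples) / config.audio_rate_hz
    freqs = np.asarray(config.carrier_freqs_hz)[:, None]
    gains = 10.0 ** (np.asarray(config.carrier_gains_db)[:, None] / 20.0)
    carriers = np.sin(2.0 * np.pi * freqs * t)
    per_band = env.env * gains * carriers
    return TactileStimulus(waveform=per_band.sum(axis=0),
                           rate_hz=config.audio_rate_hz, per_band=per_band)


def scale_and_rove(stim: TactileStimulus, config: VocoderConfig,
                   rng: np.random.Generator | None = None,
                   rove_enabled: bool = False) -> TactileStimulus:
    """Calibrate the stimulus RMS to the nominal level, optionally roved.

    Without rove the output RMS is 141.5 dB re 1 µm/s² (≈11.885 m/s²,
    1.2 G).  With rove the level is drawn uniformly within ±3 dB of nominal
    and the draw recorded in ``applied_rove_db``.
    """
    rms = stim.rms()
    if rms <= 0.0:
        raise ValueError("cannot calibrate an all-zero stimulus")
    rove_db = 0.0
    if rove_enabled:
        if rng is None:
            raise ValueError("rove requires a seeded random generator")
        rove_db = float(rng.uniform(-config.rove_halfwidth_db,
                                    config.rove_halfwidth_db))
    target_rms = config.nominal_rms_ms2 * 10.0 ** (rove_db / 20.0)
    gain = target_rms / rms
    per_band = None if stim.per_band is None else stim.per_band * gain
    return TactileStimulus(waveform=stim.waveform * gain, rate_hz=stim.rate_hz,
                           per_band=per_band, applied_rove_db=rove_db)


def vocode(audio: AudioSignal, config: VocoderConfig | None = None,
           bank: FilterBank | None = None,
           rng: np.random.Generator | None = None,
           rove_enabled: bool = False,
           normalize_target_db: float = -26.0) -> TactileStimulus:
    """Run the full audio-to-tactile chain on one token.

    ``normalize_target_db`` is the active-speech-level target (dB re full
    scale) applied before vocoding; the final RMS calibration makes the
    tactile level independent of this choice, which only fixes headroom.
    """
    config = config or VocoderConfig()
    audio = normalize_active_level(audio, normalize_target_db)
    audio = audio.resample(config.audio_rate_hz)
    if bank is None:
        bank = design_erb_filterbank(config)
    env = extract_band_envelopes(audio, bank, config)
    if config.expansion.enabled:
        env = expand_envelopes(env, config.expansion)
    stim = synthesize_tactile(env, config)
    return scale_and_rove(stim, config, rng=rng, rove_enabled=rove_enabled)
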