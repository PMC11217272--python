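"""Configuration objects for the tactile vocoder processing chain.

The defaults reproduce the published eight-band wrist vocoder: an ERB-spaced
FIR analysis bank between 50 and 7000 Hz, 23 Hz envelope smoothing, optional
multi-band dynamic-range expansion, fixed-phase vibro-tactile carriers between
94.5 and 327.5 Hz with sensitivity-compensating gains, and RMS calibration to
141.5 dB re 1 µm/s² (≈1.2 G) with a ±3 dB level rove.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

__all__ = ["ExpansionParams", "VocoderConfig", "AssemblyParams", "RunConfig"]


@dataclass(frozen=True)
class ExpansionParams:
    """Multi-band dynamic-range expander settings.

    The expander raises envelope levels above a per-band threshold set
    ``threshold_offset_db`` relative to that band's envelope RMS.  The static
    curve adds ``slope_db_per_octave`` dB of output level per octave (6.0206
    dB) of input level above threshold; gain changes are smoothed with
    one-pole attack/release ballistics.
    """

    enabled: bool = True
    attack_ms: float = 10.0
    release_ms: float = 100.0
    slope_db_per_octave: float = 5.0
    threshold_offset_db: float = -5.0

    def __post_init__(self) -> None:
        if self.attack_ms <= 0 or self.release_ms <= 0:
            raise ValueError("attack_ms and release_ms must be positive")
        if self.slope_db_per_octave < 0:
            raise ValueError("slope_db_per_octave must be >= 0")

    @property
    def ratio(self) -> float:
        """Expansion ratio r: output dB above threshold per input dB above it."""
        octave_db = 20.0 * 3.0 * 0.1003433318879937  # 20*log10(2) = 6.0206 dB
        return 1.0 + self.slope_db_per_octave / octave_db


@dataclass(frozen=True)
class VocoderConfig:
    """Every numeric parameter of the audio-to-tactile conversion chain."""

    audio_rate_hz: int = 16000
    num_bands: int = 8
    band_lo_hz: float = 50.0
    band_hi_hz: float = 7000.0
    fir_order: int = 512
    env_lpf_corner_hz: float = 23.0
    env_lpf_order: int = 6
    carrier_freqs_hz: tuple[float, ...] = (
        94.5, 116.5, 141.5, 170.0, 202.5, 239.0, 280.5, 327.5)
    carrier_gains_db: tuple[float, ...] = (
        13.8, 12.1, 9.9, 6.4, 1.6, 0.0, 1.7, 4.0)
    nominal_level_db_re_1u_ms2: float = 141.5
    rove_halfwidth_db: float = 3.0
    expansion: ExpansionParams = field(default_factory=ExpansionParams)

    def __post_init__(self) -> None:
        cf = tuple(float(f) for f in self.carrier_freqs_hz)
        cg = tuple(float(g) for g in self.carrier_gains_db)
        object.__setattr__(self, "carrier_freqs_hz", cf)
        object.__setattr__(self, "carrier_gains_db", cg)
        if len(cf) != self.num_bands or len(cg) != self.num_bands:
            raise ValueError(
                f"need {self.num_bands} carrier frequencies and gains, "
                f"got {len(cf)} and {len(cg)}")
        if any(b <= a for a, b in zip(cf, cf[1:])):
            raise ValueError("carrier frequencies must be strictly increasing")
        if cf[-1] >= self.audio_rate_hz / 2:
            raise ValueError("carrier frequencies must lie below Nyquist")
        if not 0 < self.band_lo_hz < self.band_hi_hz:
            raise ValueError("need 0 < band_lo_hz < band_hi_hz")
        if self.band_hi_hz >= self.audio_rate_hz / 2:
            raise ValueError("band_hi_hz must lie below Nyquist")
        if self.fir_order < 2 or self.fir_order % 2:
            raise ValueError("fir_order must be a positive even integer")

    @property
    def nominal_rms_ms2(self) -> float:
        """Calibration target RMS in m/s² (141.5 dB re 1e-6 m/s² → 11.885)."""
        return 1e-6 * 10.0 ** (self.nominal_level_db_re_1u_ms2 / 20.0)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "VocoderConfig":
        d = dict(d)
        exp = d.pop("expansion", None)
        if isinstance(exp, dict):
            d["expansion"] = ExpansionParams(**exp)
        elif exp is not None:
            d["expansion"] = exp
        for key in ("carrier_freqs_hz", "carrier_gains_db"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def hash(self) -> str:
        """Stable short hash of the full parameter set, for sidecar metadata."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def with_expansion(self, enabled: bool) -> "VocoderConfig":
        return replace(self, expansion=replace(self.expansion, enabled=enabled))


@dataclass(frozen=True)
class AssemblyParams:
    """Timing, ramp, threshold and SNR constants for trial-stimulus assembly."""

    snr_db: float = 5.0
    noise_pad_ms: float = 400.0
    noise_ramp_ms: float = 50.0
    phoneme_delay_ms: float = 200.0
    match_ramp_ms: float = 20.0
    dur_end_threshold_frac: float = 0.01
    snr_trim_threshold_frac: float = 0.10
    interval_gap_ms: float = 250.0

    def __post_init__(self) -> None:
        for name in ("noise_pad_ms", "noise_ramp_ms", "phoneme_delay_ms",
                     "match_ramp_ms", "interval_gap_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("dur_end_threshold_frac", "snr_trim_threshold_frac"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")


@dataclass(frozen=True)
class RunConfig:
    """Top-level run configuration: vocoder + assembly parameters, seed, paths."""

    vocoder: VocoderConfig = field(default_factory=VocoderConfig)
    assembly: AssemblyParams = field(default_factory=AssemblyParams)
    seed: int = 0
    out_dir: str = "."
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("vocoder"), dict):
            d["vocoder"] = VocoderConfig.from_dict(d["vocoder"])
        if isinstance(d.get("assembly"), dict):
            d["assembly"] = AssemblyParams(**d["assembly"])
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
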