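"""Synthetic two-talker phoneme corpus.

Source-filter (Klatt-style cascade) formant synthesis of every phoneme in
the pair inventory, for a "male" talker (mean f0 145.4 Hz) and a "female"
talker (mean f0 208.2 Hz), four tokens per phoneme with per-token jitter in
f0, duration and formant frequencies.  Naturalness is a non-goal: the
corpus exists so the vocoder, noise, assembly and trial machinery can be
exercised end-to-end without the original recordings.

Vowel formant targets are canonical Southern British English monophthong
values (after Deterding 1997, J. Int. Phon. Assoc. 27, male speakers),
rounded; female formants are scaled by 1.17 (typical male→female vocal
tract ratio).  Diphthongs glide between two monophthong targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .signal_io import AudioSignal

__all__ = ["SyntheticPhonemeSpec", "SyntheticCorpus", "TALKER_F0",
           "phoneme_spec", "synthesize_phoneme", "build_synthetic_corpus",
           "estimate_f0"]

RATE = 16000
TALKER_F0 = {"male": 145.4, "female": 208.2}
FEMALE_FORMANT_SCALE = 1.17

# Male monophthong targets (F1, F2, F3) in Hz.
_VOWELS = {
    "iː": (280, 2250, 2900), "ɪ": (360, 2100, 2700), "e": (500, 1900, 2600),
    "æ": (700, 1550, 2500), "ʌ": (640, 1250, 2500), "ɑː": (640, 1150, 2450),
    "ɒ": (560, 1050, 2450), "ɔː": (430, 850, 2550), "ʊ": (380, 1160, 2400),
    "uː": (320, 1200, 2350), "ə": (500, 1450, 2450),
}
# Diphthongs as (start vowel, end vowel) target glides.
_DIPHTHONGS = {
    "eɪ": ("e", "ɪ"), "aʊ": ("æ", "ʊ"), "ɔɪ": ("ɔː", "ɪ"),
    "ɪə": ("ɪ", "ə"), "əʊ": ("ə", "ʊ"), "ʊə": ("ʊ", "ə"), "eə": ("e", "ə"),
}
# Sonorant consonants: formant targets (glides end at schwa for w, j).
_SONORANTS = {
    "m": ((250, 1100, 2200), None), "n": ((250, 1500, 2500), None),
    "l": ((360, 1300, 2700), None), "r": ((310, 1100, 1600), None),
    "w": ((300, 700, 2300), "ə"), "j": ((280, 2250, 2900), "ə"),
}
# Fricatives: (noise centre Hz, bandwidth Hz, voiced).
_FRICATIVES = {
    "f": (4500, 3000, False), "θ": (5500, 3200, False),
    "s": (6300, 1800, False), "ʃ": (3200, 1600, False),
    "v": (4500, 3000, True), "ð": (5500, 3200, True),
    "z": (6300, 1800, True), "ʒ": (3200, 1600, True),
}
# Plosives/affricate: (burst centre Hz, burst bw Hz, voiced, frication ms).
_PLOSIVES = {
    "p": (800, 1200, False, 25.0), "t": (4500, 2500, False, 30.0),
    "k": (2200, 1500, False, 35.0), "b": (800, 1200, True, 15.0),
    "d": (4500, 2500, True, 15.0), "g": (2200, 1500, True, 20.0),
    "tʃ": (3200, 1600, False, 120.0),
}
_DEFAULT_DUR_MS = {"monophthong": 350.0, "diphthong": 450.0,
                   "sonorant": 260.0, "fricative": 300.0, "plosive": 220.0}


@dataclass(frozen=True)
class SyntheticPhonemeSpec:
    """Source-filter recipe for one phoneme token family."""

    label: str
    klass: str                  # monophthong|diphthong|plosive|fricative|sonorant
    voiced: bool
    f0_hz: float
    duration_ms: float
    formant_tracks: np.ndarray | None = None   # (n_knots, 3), Hz, linear in time
    noise_center_hz: float | None = None
    noise_bw_hz: float | None = None
    frication_ms: float | None = None
    token_jitter: dict = field(default_factory=lambda: {
        "f0_frac": 0.01, "duration_frac": 0.08, "formant_frac": 0.03})

    def __post_init__(self) -> None:
        if self.f0_hz <= 0:
            raise ValueError("f0 must be positive")
        if self.duration_ms <= 50:
            raise ValueError("duration must exceed 50 ms")
        if self.formant_tracks is not None:
            ft = np.asarray(self.formant_tracks, dtype=float)
            if ft.ndim != 2 or ft.shape[1] != 3:
                raise ValueError("formant_tracks must be (n_knots, 3)")
            if np.any(np.diff(ft, axis=1) <= 0):
                raise ValueError("formants must satisfy F1 < F2 < F3")
            object.__setattr__(self, "formant_tracks", ft)


@dataclass(frozen=True)
class SyntheticCorpus:
    """Tokens indexed by (talker, phoneme, token 1-4), all at 16 kHz."""

    tokens: dict[tuple[str, str, int], AudioSignal]
    rate_hz: int = RATE

    def get(self, talker: str, phoneme: str, token: int) -> AudioSignal:
        return self.tokens[(talker, phoneme, token)]

    def phonemes(self) -> list[str]:
        return sorted({k[1] for k in self.tokens})

    def by_talker(self, talker: str) -> list[AudioSignal]:
        return [sig for (t, _, _), sig in sorted(self.tokens.items())
                if t == talker]


def phoneme_spec(label: str, talker: str = "male") -> SyntheticPhonemeSpec:
    """Recipe for ``label`` as spoken by ``talker``."""
    f0 = TALKER_F0[talker]
    scale = FEMALE_FORMANT_SCALE if talker == "female" else 1.0

    def tracks(*names: str) -> np.ndarray:
        return np.array([_VOWELS[n] for n in names], dtype=float) * scale

    if label in _VOWELS:
        return SyntheticPhonemeSpec(
            label=label, klass="monophthong", voiced=True, f0_hz=f0,
            duration_ms=_DEFAULT_DUR_MS["monophthong"],
            formant_tracks=tracks(label, label))
    if label in _DIPHTHONGS:
        a, b = _DIPHTHONGS[label]
        return SyntheticPhonemeSpec(
            label=label, klass="diphthong", voiced=True, f0_hz=f0,
            duration_ms=_DEFAULT_DUR_MS["diphthong"],
            formant_tracks=tracks(a, a, b))  # hold, then glide
    if label in _SONORANTS:
        start, glide_to = _SONORANTS[label]
        ft = np.array([start, start if glide_to is None else _VOWELS[glide_to]],
                      dtype=float) * scale
        return SyntheticPhonemeSpec(
            label=label, klass="sonorant", voiced=True, f0_hz=f0,
            duration_ms=_DEFAULT_DUR_MS["sonorant"], formant_tracks=ft)
    if label in _FRICATIVES:
        centre, bw, voiced = _FRICATIVES[label]
        return SyntheticPhonemeSpec(
            label=label, klass="fricative", voiced=voiced, f0_hz=f0,
            duration_ms=_DEFAULT_DUR_MS["fricative"],
            noise_center_hz=centre, noise_bw_hz=bw)
    if label in _PLOSIVES:
        centre, bw, voiced, fric_ms = _PLOSIVES[label]
        return SyntheticPhonemeSpec(
            label=label, klass="plosive", voiced=voiced, f0_hz=f0,
            duration_ms=_DEFAULT_DUR_MS["plosive"],
            formant_tracks=(np.array([_VOWELS["ə"], _VOWELS["ə"]]) * scale
                            if voiced else None),
            noise_center_hz=centre, noise_bw_hz=bw, frication_ms=fric_ms)
    raise KeyError(f"no synthesis recipe for phoneme {label!r}")


def _resonator_coeffs(freq: float, bw: float, fs: float):
    r = np.exp(-np.pi * bw / fs)
    c = -r * r
    b = 2.0 * r * np.cos(2.0 * np.pi * freq / fs)
    return np.array([1.0 - b - c]), np.array([1.0, -b, -c])


def _formant_filter(source: np.ndarray, tracks: np.ndarray, fs: float,
                    bandwidths=(90.0, 110.0, 170.0),
                    frame_ms: float = 10.0) -> np.ndarray:
    """Cascade of three resonators with piecewise-linear formant tracks."""
    n = source.size
    knots = np.linspace(0.0, 1.0, tracks.shape[0])
    frame = max(8, int(round(frame_ms * 1e-3 * fs)))
    out = np.empty(n)
    zi = [np.zeros(2) for _ in range(3)]
    for start in range(0, n, frame):
        stop = min(start + frame, n)
        pos = (start + stop) / 2.0 / n
        seg = source[start:stop]
        for k in range(3):
            f = np.interp(pos, knots, tracks[:, k])
            b, a = _resonator_coeffs(f, bandwidths[k], fs)
            seg, zi[k] = lfilter(b, a, seg, zi=zi[k])
        out[start:stop] = seg
    return out


def _glottal_source(n: int, f0: float, fs: float) -> np.ndarray:
    """Impulse train at f0 with -12 dB/octave glottal spectral tilt."""
    src = np.zeros(n)
    period = fs / f0
    idx = np.round(np.arange(0.0, n, period)).astype(int)
    src[idx[idx < n]] = 1.0
    for _ in range(2):  # two one-pole low-passes ≈ glottal rolloff
        src = lfilter([1.0], [1.0, -0.95], src)
    return src


def _shaped_noise(n: int, centre: float, bw: float, fs: float,
                  rng: np.random.Generator) -> np.ndarray:
    b, a = _resonator_coeffs(centre, bw, fs)
    return lfilter(b, a, rng.standard_normal(n))


def _edge_ramp(n_total: int, ramp_ms: float, fs: float) -> np.ndarray:
    w = np.ones(n_total)
    nr = min(int(round(ramp_ms * 1e-3 * fs)), n_total // 2)
    if nr > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(1, nr + 1) / nr))
        w[:nr], w[-nr:] = ramp, ramp[::-1]
    return w


def synthesize_phoneme(spec: SyntheticPhonemeSpec,
                       rng: np.random.Generator) -> AudioSignal:
    """Render one token of ``spec``; identical seed → identical token."""
    fs = RATE
    jit = spec.token_jitter
    f0 = spec.f0_hz * (1.0 + jit["f0_frac"] * rng.uniform(-1, 1))
    dur = spec.duration_ms * (1.0 + jit["duration_frac"] * rng.uniform(-1, 1))
    n = int(round(dur * 1e-3 * fs))
    tracks = None
    if spec.formant_tracks is not None:
        tracks = spec.formant_tracks * (
            1.0 + jit["formant_frac"] * rng.uniform(-1, 1, spec.formant_tracks.shape))
        tracks = np.sort(tracks, axis=1)  # keep F1<F2<F3 under jitter

    if spec.klass in ("monophthong", "diphthong", "sonorant"):
        voiced = _formant_filter(_glottal_source(n, f0, fs), tracks, fs)
        sig = np.diff(voiced, prepend=0.0)  # radiation characteristic
        sig *= _edge_ramp(n, 25.0, fs)
    elif spec.klass == "fricative":
        sig = _shaped_noise(n, spec.noise_center_hz, spec.noise_bw_hz, fs, rng)
        sig *= _edge_ramp(n, 40.0, fs)
        if spec.voiced:
            murmur = _glottal_source(n, f0, fs)
            murmur = lfilter(*_resonator_coeffs(250.0, 120.0, fs), murmur)
            sig = sig / max(np.abs(sig).max(), 1e-12) \
                + 1.2 * murmur / max(np.abs(murmur).max(), 1e-12)
    elif spec.klass == "plosive":
        closure = int(round(0.070 * fs))
        n_fric = int(round(spec.frication_ms * 1e-3 * fs))
        sig = np.zeros(n)
        burst = _shaped_noise(n_fric, spec.noise_center_hz, spec.noise_bw_hz,
                              fs, rng)
        burst *= np.exp(-np.arange(n_fric) / (0.4 * n_fric))  # decaying burst
        stop = min(closure + n_fric, n)
        sig[closure:stop] = burst[:stop - closure]
        if spec.voiced:
            # Voicing bar through closure, then a short schwa-like release.
            bar = _glottal_source(closure, f0, fs)
            bar = lfilter(*_resonator_coeffs(180.0, 100.0, fs), bar)
            sig[:closure] += 0.25 * bar / max(np.abs(bar).max(), 1e-12)
            rel_n = n - stop
            if rel_n > 40:
                rel = _formant_filter(_glottal_source(rel_n, f0, fs), tracks, fs)
                rel = np.diff(rel, prepend=0.0)
                rel *= _edge_ramp(rel_n, 20.0, fs)
                sig[stop:] += rel / max(np.abs(rel).max(), 1e-12)
        else:
            # Aspiration tail after the burst.
            asp_n = min(int(round(0.050 * fs)), n - stop)
            if asp_n > 0:
                asp = _shaped_noise(asp_n, 1500.0, 2500.0, fs, rng)
                sig[stop:stop + asp_n] += 0.3 * asp / max(np.abs(asp).max(), 1e-12)
    else:
        raise ValueError(f"unknown phoneme class {spec.klass!r}")

    sig = sig / max(np.abs(sig).max(), 1e-12) * 0.3
    silence = np.zeros(int(round(0.030 * fs)))
    return AudioSignal(np.concatenate([silence, sig, silence]), fs)


def build_synthetic_corpus(rng: np.random.Generator,
                           phonemes: list[str] | None = None,
                           tokens_per_phoneme: int = 4) -> SyntheticCorpus:
    """Four jittered tokens per (talker × phoneme) over the pair inventory."""
    if phonemes is None:
        from .experiment import phoneme_inventory
        phonemes = phoneme_inventory()
    out: dict[tuple[str, str, int], AudioSignal] = {}
    for talker in TALKER_F0:
        for ph in phonemes:
            spec = phoneme_spec(ph, talker)
            for k in range(1, tokens_per_phoneme + 1):
                out[(talker, ph, k)] = synthesize_phoneme(spec, rng)
    return SyntheticCorpus(tokens=out)


def estimate_f0(audio: AudioSignal, fmin: float = 80.0, fmax: float = 320.0
                ) -> float:
    """Autocorrelation f0 estimate over the plausible voice-pitch range."""
    x = audio.samples - np.mean(audio.samples)
    ac = np.correlate(x, x, mode="full")[x.size - 1:]
    lo = int(audio.rate_hz / fmax)
    hi = min(int(audio.rate_hz / fmin) + 1, ac.size - 1)
    seg = ac[lo:hi]
    # Shortest-lag peak within 85 % of the maximum: avoids octave errors from
    # the near-equal subharmonic peaks of a periodic signal.
    peaks = np.nonzero((seg[1:-1] >= seg[:-2]) & (seg[1:-1] >= seg[2:]) &
                       (seg[1:-1] >= 0.85 * seg.max()))[0] + 1
    lag = lo + (int(peaks[0]) if peaks.size else int(np.argmax(seg)))
    # Parabolic interpolation around the peak for sub-sample lag precision.
    if 0 < lag < ac.size - 1:
        y0, y1, y2 = ac[lag - 1], ac[lag], ac[lag + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom != 0:
            lag = lag + 0.5 * (y0 - y2) / denom
    return float(audio.rate_hz / lag)
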