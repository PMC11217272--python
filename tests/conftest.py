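import numpy as np
import pytest

import tactile_vocoder as tv


@pytest.fixture(scope="session")
def config() -> tv.VocoderConfig:
    return tv.VocoderConfig()


@pytest.fixture(scope="session")
def bank(config) -> tv.FilterBank:
    return tv.design_erb_filterbank(config)


@pytest.fixture(scope="session")
def corpus() -> tv.SyntheticCorpus:
    """Full two-talker synthetic corpus (304 tokens), one build per session."""
    return tv.build_synthetic_corpus(np.random.default_rng(20240701))


@pytest.fixture(scope="session")
def noise_chain(corpus):
    """LTASS → fitted filter → 60 s speech-shaped noise, shared by tests."""
    tokens = corpus.by_talker("male") + corpus.by_talker("female")
    ltass = tv.estimate_ltass(tokens)
    filt = tv.fit_noise_filter(ltass)
    noise = tv.generate_speech_shaped_noise(filt, 60.0,
                                            np.random.default_rng(99))
    return ltass, filt, noise


def make_tone(freq_hz: float, amp: float = 0.5, duration_s: float = 0.5,
              rate_hz: int = 16000) -> tv.AudioSignal:
    t = np.arange(int(round(duration_s * rate_hz))) / rate_hz
    return tv.AudioSignal(amp * np.sin(2 * np.pi * freq_hz * t), rate_hz)
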