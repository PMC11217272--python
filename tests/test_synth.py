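"""Synthetic phoneme corpus: formants, f0, coverage, pipeline compatibility."""

import numpy as np
import pytest

import tactile_vocoder as tv
from tactile_vocoder.synth import TALKER_F0, phoneme_spec

FS = 16000
MONOPHTHONGS = ("iː", "ɪ", "e", "æ", "ʌ", "ɑː", "ɒ", "ɔː", "ʊ", "uː")


def lpc_formants(audio: tv.AudioSignal, order: int = 14):
    """Oracle: LPC root frequencies with narrow bandwidths ≈ formants."""
    x = audio.samples * np.hamming(len(audio))
    r = np.correlate(x, x, mode="full")[len(x) - 1:len(x) + order]
    a = np.linalg.solve(
        np.array([[r[abs(i - j)] for j in range(order)] for i in range(order)]),
        r[1:order + 1])
    roots = np.roots(np.concatenate([[1.0], -a]))
    roots = roots[np.imag(roots) > 0]
    freqs = np.angle(roots) * FS / (2 * np.pi)
    bw = -FS / np.pi * np.log(np.abs(roots))
    cand = np.sort(freqs[(bw < 500) & (freqs > 150) & (freqs < 5000)])
    return cand


def test_monophthong_spectral_peaks_near_formant_targets():
    spec = phoneme_spec("ɑː", "male")
    token = tv.synthesize_phoneme(spec, np.random.default_rng(0))
    f1_t, f2_t = spec.formant_tracks[0, 0], spec.formant_tracks[0, 1]
    cand = lpc_formants(token)
    assert cand.size >= 2
    assert np.min(np.abs(cand - f1_t)) < 80.0
    assert np.min(np.abs(cand - f2_t)) < 80.0


def test_voiced_token_autocorrelation_period():
    spec = phoneme_spec("iː", "female")
    token = tv.synthesize_phoneme(spec, np.random.default_rng(1))
    x = token.samples - token.samples.mean()
    ac = np.correlate(x, x, mode="full")[x.size - 1:]
    lo, hi = int(FS / 320), int(FS / 80)
    lag = lo + np.argmax(ac[lo:hi])
    assert abs(FS / lag - spec.f0_hz) < 0.05 * spec.f0_hz


def test_same_spec_and_seed_identical_token():
    spec = phoneme_spec("s", "male")
    a = tv.synthesize_phoneme(spec, np.random.default_rng(7))
    b = tv.synthesize_phoneme(spec, np.random.default_rng(7))
    assert np.array_equal(a.samples, b.samples)


def test_corpus_counts_and_coverage(corpus):
    inventory = tv.phoneme_inventory()
    assert len(corpus.tokens) == 2 * len(inventory) * 4
    assert corpus.phonemes() == inventory
    for talker in ("male", "female"):
        for ph in inventory:
            toks = [corpus.get(talker, ph, k) for k in (1, 2, 3, 4)]
            assert len({t.samples.tobytes() for t in toks}) == 4  # distinct


def test_talker_f0_means_recovered(corpus):
    for talker, want in TALKER_F0.items():
        est = [tv.estimate_f0(corpus.get(talker, v, k))
               for v in MONOPHTHONGS for k in (1, 2, 3, 4)]
        assert abs(np.mean(est) - want) < 2.0


def test_all_tokens_pass_endpoint_detection(corpus):
    for sig in corpus.tokens.values():
        start, end = tv.detect_endpoints(sig)
        assert start <= end


def test_diphthong_formant_glide_visible_in_band_envelopes(config, bank):
    """A diphthong's F2 glide migrates energy across envelope bands."""
    token = tv.synthesize_phoneme(phoneme_spec("ɔɪ", "female"),
                                  np.random.default_rng(3))
    env = tv.extract_band_envelopes(token, bank, config)
    # Consider the mid-frequency bands that cover F2 (bands 2-5) and track
    # which carries the most energy over thirds of the voiced portion.
    start, end = tv.detect_endpoints(token, 0.10)
    # F2 starts near 1 kHz (band 3) and glides above 2 kHz (bands 5-6);
    # bands 0-2 stay F1-dominated, so track dominance among bands 3-6.
    sub = env.env[3:7, start:end]
    thirds = np.array_split(sub, 3, axis=1)
    dominant = [int(np.argmax(part.mean(axis=1))) for part in thirds]
    assert dominant[0] != dominant[-1]


def test_every_pair_renders_through_full_pipeline(config, bank, corpus,
                                                  noise_chain):
    """Every inventory pair survives vocoding and noise-interval assembly."""
    _, _, noise = noise_chain
    pairs = tv.load_phoneme_pairs()
    rng = np.random.default_rng(11)
    for pair in pairs[::9]:  # representative sample across contrast types
        for ph in (pair.phoneme_a, pair.phoneme_b):
            tok = corpus.get("male", ph, 1)
            iv = tv.assemble_noise_interval(tok, noise,
                                            1000 * tok.duration_s, rng=rng)
            stim = tv.vocode(iv.mixture, config, rng=rng, rove_enabled=True)
            assert np.all(np.isfinite(stim.waveform))
            assert abs(stim.level_db_re_1u_ms2()
                       - (141.5 + stim.applied_rove_db)) < 0.01


def test_invalid_specs_rejected():
    with pytest.raises(ValueError):
        tv.SyntheticPhonemeSpec(label="x", klass="monophthong", voiced=True,
                                f0_hz=-1.0, duration_ms=300)
    with pytest.raises(ValueError):
        tv.SyntheticPhonemeSpec(label="x", klass="monophthong", voiced=True,
                                f0_hz=100.0, duration_ms=30)
    with pytest.raises(ValueError):
        tv.SyntheticPhonemeSpec(
            label="x", klass="monophthong", voiced=True, f0_hz=100.0,
            duration_ms=300,
            formant_tracks=np.array([[900.0, 500.0, 2500.0]]))
    with pytest.raises(KeyError):
        phoneme_spec("ɜː")  # not in the pair inventory
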