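"""Endpoint detection, duration matching, SNR mixing, interval assembly."""

import numpy as np
import pytest

import tactile_vocoder as tv
from tactile_vocoder.assembly import DIPHTHONGS, EXEMPT_CONSONANTS

FS = 16000


def test_endpoints_hand_checked_example():
    x = tv.AudioSignal(np.array([0, 0, 0.05, 0.5, 1.0, 0.5, 0.05, 0.0]), FS)
    assert tv.detect_endpoints(x, 0.10) == (3, 5)


def test_endpoints_full_scale_constant():
    x = tv.AudioSignal(np.ones(100), FS)
    assert tv.detect_endpoints(x, 0.10) == (0, 99)


def test_endpoints_invariant_to_gain():
    rng = np.random.default_rng(0)
    x = np.concatenate([np.zeros(50), rng.standard_normal(500), np.zeros(30)])
    a = tv.detect_endpoints(tv.AudioSignal(x, FS))
    b = tv.detect_endpoints(tv.AudioSignal(0.3 * x, FS))
    assert a == b


def test_endpoints_all_zero_rejected():
    with pytest.raises(ValueError):
        tv.detect_endpoints(tv.AudioSignal(np.zeros(10), FS))


def ramped_token(end_s, n_s=0.8, amp=1.0):
    """Token active up to end_s, then silent."""
    n = int(n_s * FS)
    x = np.zeros(n)
    k = int(end_s * FS)
    x[:k] = amp * np.sin(2 * np.pi * 220 * np.arange(k) / FS)
    return tv.AudioSignal(x, FS)


def test_diphthong_pair_exempt_from_matching():
    a, b = ramped_token(0.3), ramped_token(0.5)
    oa, ob = tv.match_durations(a, b, "aʊ", "s")
    assert oa is a and ob is b


def test_exempt_consonants_listed():
    assert EXEMPT_CONSONANTS == {"g", "d", "l", "r", "v", "w", "j"}
    assert "eɪ" in DIPHTHONGS


def test_matching_fades_both_to_shorter_end():
    a, b = ramped_token(0.3), ramped_token(0.5)
    end_a = tv.detect_endpoints(a, 0.01)[1]
    oa, ob = tv.match_durations(a, b, "s", "ʃ")
    # Both outputs are silent beyond the shorter token's 1 % end point.
    assert np.all(oa.samples[end_a + 1:] == 0.0)
    assert np.all(ob.samples[end_a + 1:] == 0.0)
    # The 20-ms fade spans the last 20 ms before that end point.
    ramp_len = int(round(0.020 * FS))
    start = end_a + 1 - ramp_len
    assert np.any(ob.samples[start:end_a + 1] != 0.0)
    before = slice(max(0, start - 400), start)
    assert np.allclose(ob.samples[before], b.samples[before])


def test_equal_tokens_end_identically():
    a, b = ramped_token(0.4), ramped_token(0.4)
    oa, ob = tv.match_durations(a, b, "s", "f")
    za = np.nonzero(oa.samples)[0][-1]
    zb = np.nonzero(ob.samples)[0][-1]
    assert za == zb


def test_matching_never_lengthens():
    a, b = ramped_token(0.3), ramped_token(0.5)
    oa, ob = tv.match_durations(a, b, "s", "ʃ")
    assert len(oa) == len(a) and len(ob) == len(b)
    assert np.max(np.abs(oa.samples)) <= np.max(np.abs(a.samples)) + 1e-12


def test_mix_at_zero_snr_with_equal_rms_leaves_noise_unscaled():
    rng = np.random.default_rng(1)
    ph = ramped_token(0.5, amp=0.5)
    trimmed = tv.trimmed_rms(ph, 0.10)
    noise = rng.standard_normal(len(ph))
    noise *= trimmed / np.sqrt(np.mean(noise ** 2))
    params = tv.AssemblyParams(snr_db=1e-12)
    mixed = tv.mix_at_snr(ph, tv.AudioSignal(noise, FS), params)
    assert np.allclose(mixed.samples, ph.samples + noise, atol=1e-9)


def test_snr_round_trip_within_001db():
    rng = np.random.default_rng(2)
    ph = ramped_token(0.4, amp=0.3)
    noise = tv.AudioSignal(rng.standard_normal(len(ph)), FS)
    params = tv.AssemblyParams()
    gain = tv.trimmed_rms(ph) / (noise.rms() * 10 ** (params.snr_db / 20))
    mixed = tv.mix_at_snr(ph, noise, params)
    re_snr = tv.measure_snr_db(ph, noise.scaled(gain))
    assert abs(re_snr - 5.0) < 0.01
    assert len(mixed) == len(ph)


def test_leading_silence_does_not_change_noise_gain():
    rng = np.random.default_rng(3)
    ph = ramped_token(0.4, amp=0.3)
    padded = tv.AudioSignal(
        np.concatenate([np.zeros(FS // 2), ph.samples]), FS)
    noise = tv.AudioSignal(rng.standard_normal(2 * FS), FS)
    m1 = tv.mix_at_snr(ph, noise)
    m2 = tv.mix_at_snr(padded, noise)
    # Same gain → the noise-only head of m2 equals the scaled noise in m1.
    tail1 = m1.samples[len(ph) - 100:len(ph)] if len(noise) > len(ph) else None
    g1 = (m1.samples - np.pad(ph.samples, (0, len(m1) - len(ph))))[:FS]
    g2 = (m2.samples - np.pad(padded.samples, (0, len(m2) - len(padded))))[:FS]
    assert np.allclose(g1, g2, atol=1e-12)


def test_interval_duration_and_onset(noise_chain, corpus):
    _, _, noise = noise_chain
    ph = corpus.get("male", "ɑː", 1)
    longest_ms = 600.0
    iv = tv.assemble_noise_interval(ph, noise, longest_ms,
                                    rng=np.random.default_rng(4))
    assert len(iv.mixture) == int(round((longest_ms + 400.0) / 1000 * FS))
    assert iv.phoneme_onset_sample == int(round(0.200 * FS))
    # ≥200 ms of noise remains after the phoneme ends
    tail = len(iv.mixture) - (iv.phoneme_onset_sample + len(ph))
    assert tail >= int(0.200 * FS)


def test_interval_snr_round_trip_exact(noise_chain, corpus):
    _, _, noise = noise_chain
    ph = corpus.get("female", "s", 2)
    iv = tv.assemble_noise_interval(ph, noise, 1000 * ph.duration_s,
                                    rng=np.random.default_rng(5))
    assert abs(tv.measure_snr_db(ph, iv.noise_token) - 5.0) < 0.01
    assert np.allclose(iv.mixture.samples,
                       iv.noise_token.samples + iv.phoneme_padded.samples)


def test_three_intervals_get_distinct_noise_offsets(noise_chain, corpus):
    _, _, noise = noise_chain
    ph = corpus.get("male", "t", 1)
    rng = np.random.default_rng(6)
    offs = [tv.assemble_noise_interval(ph, noise, 600.0, rng=rng)
            .noise_start_sample for _ in range(3)]
    assert len(set(offs)) == 3


def test_assembly_deterministic_under_seed(noise_chain, corpus):
    _, _, noise = noise_chain
    ph = corpus.get("male", "m", 3)
    a = tv.assemble_noise_interval(ph, noise, 600.0,
                                   rng=np.random.default_rng(7))
    b = tv.assemble_noise_interval(ph, noise, 600.0,
                                   rng=np.random.default_rng(7))
    assert a.noise_start_sample == b.noise_start_sample
    assert np.array_equal(a.mixture.samples, b.mixture.samples)


def test_phoneme_longer_than_longest_rejected(noise_chain, corpus):
    _, _, noise = noise_chain
    ph = corpus.get("male", "ɑː", 1)
    with pytest.raises(ValueError):
        tv.assemble_noise_interval(ph, noise, 50.0,
                                   rng=np.random.default_rng(8))
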