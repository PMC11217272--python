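# Methods

## Scope and model

The package implements an audio-to-tactile vocoder: speech is analysed into
eight frequency bands, each band's amplitude envelope modulates a fixed
vibro-tactile carrier tone, and the summed waveform is calibrated in
physical acceleration units for presentation at a single skin site. An
optional per-band dynamic-range expander emphasises intense, spectrally
focused speech cues (formants, the voicing bar) and suppresses low-level
energy such as background noise between formants. Around the vocoder sit
the pieces needed to run a tactile phoneme-discrimination study: a
speech-shaped noise generator, SNR-controlled interval assembly, and 3AFC
schedule generation and scoring. The expander's published behavioural
benefits are psychophysical results and are not reproduced computationally;
the package reproduces the *pipeline* and its printed constants exactly.

## Vocoder stages

**Active-level normalisation (ITU-T P.56 method B).** The active speech
level excludes pauses: the rectified signal is smoothed by a double
exponential (time constant 30 ms), compared against a dB-spaced threshold
ladder with a 200 ms hangover, and the level is interpolated where the
candidate level sits 15.9 dB above its threshold. Implementation detail:
the ladder uses a fine 0.1 dB grid rather than the standard's octave
ladder, which removes the need for its coarse interpolation; for
stationary signals the result equals the RMS level to within ~0.1 dB (the
residual reflecting the envelope-smoothing onset). An all-zero signal has
no defined active level and raises an error.

**Resampling.** Polyphase anti-aliased resampling to 16 kHz
(`scipy.signal.resample_poly`); the paper-level constraint is only the
target rate, chosen to match compact real-time audio hardware.

**ERB filter bank.** Nine band edges are equally spaced in ERB number
(Glasberg–Moore, `ERBn(f) = 21.4·log10(0.00437 f + 1)`) between 50 and
7000 Hz; edges rather than centres are spaced because the published range
endpoints are limits of the analysed band. Each band is a 512th-order
(513-tap) linear-phase windowed-sinc (Hamming) band-pass, applied with a
centred convolution so the bank is zero-phase; its −6 dB points fall on
the band edges by construction. Band-edge placement is unit-tested against
an independent scalar inversion of the ERB formula to < 0.1 Hz.

**Envelope extraction.** Per band: analytic-signal magnitude (FFT Hilbert
transform) followed by a 6th-order Butterworth low-pass at 23 Hz run
forward and backward (`filtfilt`). Zero-phase operation means the
effective magnitude response is the square of the 6th-order response; the
AM-tone unit test asserts exactly that closed form. Tiny negative values
created by the backward pass are clamped to zero, making envelope
non-negativity an invariant of the representation.

**Expansion.** Per band, with threshold `T = 20·log10(envelope RMS) − 5 dB`
computed over the whole utterance (stimuli are prepared offline, so the
whole-token RMS is available). Static curve: identity below T; above T the
output level is `T + r·(input − T)` with `r = 1 + slope/20·log10(2)
≈ 1.830` for the 5 dB-per-octave slope — i.e. 5 dB of *additional* gain
per octave (6.0206 dB) of input above threshold. The alternative reading
(output growing only 5 dB per input octave, r < 1) is compression, not
expansion, and is rejected. The per-sample *gain* in dB (not the envelope)
is smoothed by a one-pole filter whose attack constant (10 ms) applies
while the target gain is rising and release constant (100 ms) otherwise;
the step-response unit test measures the 1−e⁻¹ point at 10 ms. An all-zero
band has no defined RMS in dB and passes through unchanged. No separate
makeup-gain stage exists: any overall level change introduced by expansion
is absorbed by the fixed-RMS calibration.

**Carrier synthesis and calibration.** Band i contributes
`env_i(t)·g_i·sin(2π f_i t)` with phase zero at onset ("fixed-phase" is
otherwise unconstrained) and gains compensating tactile sensitivity
differences across frequency. The sum is scaled to an RMS of 141.5 dB re
10⁻⁶ m/s² (≈11.885 m/s², 1.2 G); with roving enabled the level is drawn
uniformly within ±3 dB of nominal, the draw recorded per stimulus. With
23 Hz-limited envelopes, >99 % of output power lies within ±30 Hz of the
eight carriers (tested).

## Speech-shaped noise

The long-term average speech spectrum (LTASS) is the mean one-sided STFT
magnitude over all retained frames of all corpus tokens: 4096-sample Hann
windows, 50 % hop (the hop and window shape are free choices; results are
insensitive to both), discarding frames whose RMS falls below 10 % of the
token's peak frame RMS — the same 10 % relative-amplitude convention used
for endpoint trimming. The 2049-tap noise-shaping filter is the exact
linear-phase least-squares fit on the 2049-bin grid: a type-I filter's
amplitude is a cosine series with 1025 free coefficients, solved directly
(`numpy.linalg.lstsq`), with the squared residual reported. This is chosen
over frequency-sampling because it is a true least-squares minimiser and
makes residuals nested in tap count. White noise is drawn Gaussian and
convolved with the filter, discarding the transient.

On this package's synthetic corpus the LTASS carries strong harmonic comb
structure (two talkers at near-constant f0), which real multi-speaker
corpora do not; spectral round-trip tests therefore compare the generated
noise against the *fitted filter response* via the exact Welch expectation
(|H|² convolved with the Hann power kernel), on which agreement is within
1 dB over 50–7000 Hz.

## Stimulus assembly

Endpoints are the first and last samples whose magnitude reaches 10 % of
the token's peak (1 % for the duration-matching end point); both are
gain-invariant by construction. Duration matching fades both members of a
pair with a 20 ms raised-cosine (half-Hann) ramp that reaches zero at the
shorter token's 1 % end point — the ramp is placed so its *end* sits at
that point, the only placement the published description pins down — and
zeroes everything beyond; pairs containing a diphthong or /g, d, l, r, v,
w, j/ are exempt. SNR is defined as trimmed phoneme RMS minus noise-token
RMS in dB and set to 5 dB by scaling the noise; the noise-token RMS is
measured *after* the 50 ms on/off ramps are applied, so re-measuring the
SNR on the assembled components returns the requested value exactly
(measuring before ramping would bias it by the ramp energy loss, ~0.2 dB
for short tokens). SNR is set on audio before vocoding; the vocoder then
processes the mixture. Noise tokens are excised from the long noise at a
seeded random offset, one fresh token per interval; each interval is the
noise-pad duration (400 ms) longer than the trial's longest phoneme, with
the phoneme summed in 200 ms after noise onset, leaving ≥200 ms of noise
after the phoneme ends.

## Experiment machinery

The 45-pair inventory (27 consonant pairs in nine contrast subgroups of
three; 12 monophthong and 6 diphthong pairs) ships as packaged CSV. A
session crosses 4 conditions × 45 pairs × 2 talkers × 2 repeats = 720
trials, shuffled within each repeat block. Per trial: the doubled phoneme,
the odd-interval position (uniform over three), one token index (1–4) per
phoneme, an independent ±3 dB rove per interval, and (noise conditions)
three noise-excision draws, all from the schedule RNG, so a schedule is
fully reproducible from its seed. Interval-order randomisation is realised
by the independent draws of doubled phoneme and odd position. Scoring
aggregates percent correct over condition × phoneme type × talker ×
contrast type and exports a long-format table; inferential statistics
(RM-ANOVA, post-hoc t-tests) are deliberately left to general-purpose
statistics packages. Feedback duration is carried as metadata only.

## Synthetic corpus

Klatt-style cascade synthesis: a glottal impulse train at the talker's f0
(145.4 Hz "male", 208.2 Hz "female") with −12 dB/octave tilt, three
resonators following piecewise-linear formant tracks (10 ms update,
state-continuous), and a first-difference radiation characteristic.
Monophthong targets are canonical Southern British English values
(Deterding 1997, male), scaled ×1.17 for the female talker; diphthongs
hold the first target then glide to the second. Voiceless fricatives are
resonator-shaped noise; voiced fricatives add a low-frequency voicing
murmur; plosives are closure (with voicing bar if voiced) + shaped burst +
aspiration or a schwa-like release; /tʃ/ is rendered as closure plus a
long /ʃ/-shaped frication. Four tokens per phoneme differ by ±1 % f0,
±8 % duration and ±3 % formant jitter — enough token-to-token variability
to exercise the trial machinery while keeping talker-mean f0 recoverable
to < 2 Hz by autocorrelation (the estimator takes the shortest
autocorrelation peak within 85 % of the maximum, avoiding octave errors).

What the corpus does *not* emulate: coarticulation, natural prosody,
breathiness/aperiodicity, nasal antiresonances, and realistic LTASS
smoothness (see above). Tests passing on this corpus demonstrate that the
pipeline's signal processing and bookkeeping are correct, not that any
perceptual result would transfer to recorded speech.

## Numerical choices and degenerate inputs

Seeded `numpy.random.Generator`s are threaded through every stochastic
step; identical seeds give bit-identical outputs end to end (tested).
All-zero inputs raise errors where a quantity is undefined (active level,
endpoints, calibration) and pass through where identity is the natural
limit (expansion of a silent band). Tokens shorter than the matching ramp
truncate the ramp with a warning. Problem sizes in the test suite and the
acceptance script (60 s noise, single-token assembly, 40-repeat schedule
simulations) are chosen so the full suite runs in well under a minute on
one CPU while keeping Monte-Carlo tolerances comfortably beyond their
binomial/CLT standard errors.

## Known limitations

- The expander smooths the gain, not the detector input; hardware
  compressors sometimes smooth the envelope instead. The two differ only
  in transient detail at these time constants.
- P.56 activity measurement uses a fine threshold grid rather than the
  standard's exact octave ladder; levels agree to well under 0.1 dB but
  bit-exact conformance with reference P.56 implementations is not a goal.
- The 141.5 dB calibration is a numerical convention here; driving a real
  actuator requires transfer-function calibration against an accelerometer,
  which is out of scope.
- WAV output stores acceleration in m/s² as float samples; players that
  assume full-scale ±1 will clip the nominal 11.9 m/s² RMS — the files are
  data containers, not listening material.
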