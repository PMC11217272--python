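"""3AFC phoneme-discrimination experiment machinery.

The packaged inventory holds the 45 phoneme pairs (27 consonant, 18 vowel)
with their contrast taxonomy.  A full session tests every pair in all four
conditions (expansion on/off × noise on/off) for both talkers, twice, with
trial order randomised within each repeat block: 720 trials per participant,
180 per condition.  In each three-interval trial, two intervals carry one
randomly chosen member of the pair and the remaining interval — the target,
uniform over the three positions — carries the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["PhonemePair", "TrialRecord", "CONDITIONS", "TALKERS",
           "load_phoneme_pairs", "phoneme_inventory", "generate_trial_list",
           "trials_to_frame", "score_responses"]

CONDITIONS = ("quiet-noexp", "quiet-exp", "noise-noexp", "noise-exp")
TALKERS = ("male", "female")
NUM_INTERVALS = 3
NUM_TOKENS = 4

CONSONANT_SUBGROUPS = ("place-voiceless-plosive", "place-voiceless-fricative",
                       "place-voiced-plosive", "place-voiced-fricative",
                       "place-sonorant", "voicing", "manner", "manner+place",
                       "place+voicing")
VOWEL_SUBGROUPS = ("monophthong", "diphthong")


@dataclass(frozen=True)
class PhonemePair:
    phoneme_a: str
    phoneme_b: str
    phoneme_type: str   # consonant | vowel
    contrast_type: str

    @property
    def label(self) -> str:
        return f"{self.phoneme_a}-{self.phoneme_b}"


@dataclass
class TrialRecord:
    """One 3AFC trial: condition, pair, talker, interval layout, outcome."""

    trial_index: int
    repeat: int
    condition: str
    talker: str
    pair: PhonemePair
    odd_position: int                 # 1-based interval holding the odd one out
    interval_phonemes: tuple[str, str, str]
    interval_tokens: tuple[int, int, int]   # token index 1-4 per interval
    rove_db: tuple[float, float, float]
    noise_offsets: tuple[int, int, int] | None = None
    response: int | None = None
    feedback_ms: float = 500.0

    @property
    def correct(self) -> bool | None:
        if self.response is None:
            return None
        return self.response == self.odd_position


def load_phoneme_pairs() -> list[PhonemePair]:
    """The packaged 45-pair inventory with contrast labels."""
    src = resources.files("tactile_vocoder").joinpath("data/phoneme_pairs.csv")
    with resources.as_file(src) as path:
        df = pd.read_csv(path)
    return [PhonemePair(r.phoneme_a, r.phoneme_b, r.phoneme_type,
                        r.contrast_type) for r in df.itertuples()]


def phoneme_inventory(pairs: list[PhonemePair] | None = None) -> list[str]:
    """Sorted unique phonemes appearing in the pair inventory."""
    pairs = pairs or load_phoneme_pairs()
    seen: dict[str, None] = {}
    for p in pairs:
        seen.setdefault(p.phoneme_a)
        seen.setdefault(p.phoneme_b)
    return sorted(seen)


def generate_trial_list(pairs: list[PhonemePair] | None = None,
                        rng: np.random.Generator | None = None,
                        repeats: int = 2,
                        conditions: tuple[str, ...] = CONDITIONS,
                        talkers: tuple[str, ...] = TALKERS,
                        rove_halfwidth_db: float = 3.0) -> list[TrialRecord]:
    """Generate the per-participant trial schedule.

    Within each repeat, every (condition × pair × talker) cell occurs exactly
    once and the order is shuffled.  Per trial the doubled phoneme, the odd
    interval position, and one corpus token per phoneme are drawn from
    ``rng``; each interval gets an independent level rove.
    """
    if rng is None:
        raise ValueError("a seeded random generator is required")
    pairs = pairs or load_phoneme_pairs()
    trials: list[TrialRecord] = []
    index = 0
    for rep in range(repeats):
        block = [(c, p, t) for c in conditions for p in pairs for t in talkers]
        order = rng.permutation(len(block))
        for k in order:
            cond, pair, talker = block[k]
            doubled, odd = ((pair.phoneme_a, pair.phoneme_b)
                            if rng.integers(2) == 0
                            else (pair.phoneme_b, pair.phoneme_a))
            odd_pos = int(rng.integers(NUM_INTERVALS)) + 1
            phonemes = tuple(odd if i + 1 == odd_pos else doubled
                             for i in range(NUM_INTERVALS))
            tok = {ph: int(rng.integers(NUM_TOKENS)) + 1
                   for ph in (doubled, odd)}
            tokens = tuple(tok[ph] for ph in phonemes)
            rove = tuple(float(rng.uniform(-rove_halfwidth_db,
                                           rove_halfwidth_db))
                         for _ in range(NUM_INTERVALS))
            offsets = None
            if cond.startswith("noise"):
                # Excision offsets resolved against the actual noise length at
                # render time; drawn here so the schedule fixes all randomness.
                offsets = tuple(int(rng.integers(2 ** 31)) for _ in range(3))
            trials.append(TrialRecord(
                trial_index=index, repeat=rep + 1, condition=cond,
                talker=talker, pair=pair, odd_position=odd_pos,
                interval_phonemes=phonemes, interval_tokens=tokens,
                rove_db=rove, noise_offsets=offsets))
            index += 1
    return trials


def trials_to_frame(trials: list[TrialRecord]) -> pd.DataFrame:
    """Long-format table of the schedule (one row per trial)."""
    rows = []
    for t in trials:
        d = asdict(t)
        pair = d.pop("pair")
        d.update(pair)
        d["pair_label"] = t.pair.label
        for i in range(NUM_INTERVALS):
            d[f"interval{i+1}_phoneme"] = t.interval_phonemes[i]
            d[f"interval{i+1}_token"] = t.interval_tokens[i]
            d[f"interval{i+1}_rove_db"] = t.rove_db[i]
        for k in ("interval_phonemes", "interval_tokens", "rove_db",
                  "noise_offsets"):
            d.pop(k)
        d["correct"] = t.correct
        rows.append(d)
    return pd.DataFrame(rows)


def score_responses(trials: list[TrialRecord]) -> pd.DataFrame:
    """Percent correct by condition × phoneme type × talker × contrast type.

    Every trial must carry a response in {1, 2, 3}; otherwise the offending
    trial indices are reported.  Returns a long-format frame with one row per
    (condition, phoneme_type, talker, contrast_type) cell, plus trial counts.
    """
    missing = [t.trial_index for t in trials
               if t.response not in (1, 2, 3)]
    if missing:
        raise ValueError(f"trials without a valid response: {missing}")
    df = pd.DataFrame({
        "condition": [t.condition for t in trials],
        "phoneme_type": [t.pair.phoneme_type for t in trials],
        "talker": [t.talker for t in trials],
        "contrast_type": [t.pair.contrast_type for t in trials],
        "correct": [t.correct for t in trials],
    })
    grouped = (df.groupby(["condition", "phoneme_type", "talker",
                           "contrast_type"], sort=True)["correct"]
               .agg(n_trials="count", n_correct="sum").reset_index())
    grouped["percent_correct"] = 100.0 * grouped.n_correct / grouped.n_trials
    return grouped
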