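"""Block-design auditory stimulation schedule.

The paradigm presents four CV syllables (/ba/ and /ga/, male and female
voice) in trials of four (SOA 600 ms), five trials per block separated by a
1.6 s inter-trial interval, each 20 s stimulation block followed by 40 s of
silence.  Three block types exist (standard, deviant-phoneme, deviant-voice);
deviance structure is generated for realism but the analyses pool all blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SYLLABLES = ("ba_male", "ba_female", "ga_male", "ga_female")
BLOCK_TYPES = ("standard", "deviant_phoneme", "deviant_voice")

#: Stimulus timing constants (seconds).
SYLLABLE_DURATION_S = 0.285
SOA_S = 0.6
ITI_S = 1.6
STIM_DURATION_S = 20.0
SILENCE_DURATION_S = 40.0
N_TRIALS_PER_BLOCK = 5
N_SYLLABLES_PER_TRIAL = 4


@dataclass(frozen=True)
class SyllableEvent:
    """A single syllable presentation."""

    onset_s: float
    duration_s: float
    syllable_id: str
    trial_index: int
    block_index: int
    block_type: str


@dataclass
class StimulusSchedule:
    """Ordered list of syllable events plus the block-design timing constants."""

    events: list[SyllableEvent]
    block_onsets_s: list[float]
    block_types: list[str]
    stim_duration_s: float = STIM_DURATION_S
    silence_duration_s: float = SILENCE_DURATION_S
    soa_s: float = SOA_S
    iti_s: float = ITI_S
    n_trials_per_block: int = N_TRIALS_PER_BLOCK
    n_syllables_per_trial: int = N_SYLLABLES_PER_TRIAL

    @property
    def n_blocks(self) -> int:
        return len(self.block_onsets_s)

    @property
    def block_period_s(self) -> float:
        return self.stim_duration_s + self.silence_duration_s

    @property
    def duration_s(self) -> float:
        """Total schedule duration (last block onset + one full block period)."""
        return self.n_blocks * self.block_period_s

    def trial_onsets_s(self) -> np.ndarray:
        """Onset of the first syllable of every trial, in presentation order."""
        onsets = [ev.onset_s for ev in self.events]
        return np.asarray(onsets[:: self.n_syllables_per_trial])

    def to_frame(self) -> pd.DataFrame:
        """Events as a BIDS-style table (onset/duration/trial_type/...)."""
        return pd.DataFrame(
            {
                "onset": [ev.onset_s for ev in self.events],
                "duration": [ev.duration_s for ev in self.events],
                "trial_type": [ev.block_type for ev in self.events],
                "block_index": [ev.block_index for ev in self.events],
                "trial_index": [ev.trial_index for ev in self.events],
                "syllable_id": [ev.syllable_id for ev in self.events],
            }
        )


def _trial_period_s() -> float:
    """Onset-to-onset spacing of consecutive trials within a block."""
    trial_span = (N_SYLLABLES_PER_TRIAL - 1) * SOA_S + SYLLABLE_DURATION_S
    return trial_span + ITI_S  # ITI measured offset-to-next-onset


def _block_syllables(rng: np.random.Generator, block_type: str) -> list[str]:
    """Syllable identities of one 20-syllable block.

    Standard blocks repeat one syllable.  Deviant blocks replace the last
    syllable of three randomly chosen trials by a voice or phoneme change of
    the base syllable.
    """
    base = SYLLABLES[rng.integers(len(SYLLABLES))]
    ids = [base] * (N_TRIALS_PER_BLOCK * N_SYLLABLES_PER_TRIAL)
    if block_type == "standard":
        return ids
    phoneme, voice = base.split("_")
    if block_type == "deviant_phoneme":
        deviant = ("ga" if phoneme == "ba" else "ba") + "_" + voice
    else:
        deviant = phoneme + "_" + ("female" if voice == "male" else "male")
    trials = rng.choice(N_TRIALS_PER_BLOCK, size=3, replace=False)
    for t in trials:
        pos = int(rng.integers(1, N_SYLLABLES_PER_TRIAL))  # never the trial's S1
        ids[t * N_SYLLABLES_PER_TRIAL + pos] = deviant
    return ids


def build_paradigm(
    n_blocks: int,
    block_type_mix: dict[str, float] | None = None,
    seed: int = 0,
) -> StimulusSchedule:
    """Build a seeded block-design schedule.

    Parameters
    ----------
    n_blocks
        Number of 60-s blocks (20 s stimulation + 40 s silence).
    block_type_mix
        Proportions over block types; must sum to 1.  Default: equal thirds.
    seed
        Seed for block-type and syllable-identity draws.  Timing is
        deterministic and identical for every seed.
    """
    if n_blocks < 1:
        raise ValueError(f"n_blocks must be >= 1, got {n_blocks}")
    if block_type_mix is None:
        block_type_mix = {t: 1 / 3 for t in BLOCK_TYPES}
    unknown = set(block_type_mix) - set(BLOCK_TYPES)
    if unknown:
        raise ValueError(f"unknown block types: {sorted(unknown)}")
    probs = np.array([block_type_mix.get(t, 0.0) for t in BLOCK_TYPES], float)
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError(f"block_type_mix must sum to 1, got {probs.sum()}")

    rng = np.random.default_rng(seed)
    period = STIM_DURATION_S + SILENCE_DURATION_S
    trial_period = _trial_period_s()

    events: list[SyllableEvent] = []
    block_onsets, block_types = [], []
    for b in range(n_blocks):
        block_onset = b * period
        block_type = BLOCK_TYPES[rng.choice(len(BLOCK_TYPES), p=probs)]
        block_onsets.append(block_onset)
        block_types.append(block_type)
        ids = _block_syllables(rng, block_type)
        for t in range(N_TRIALS_PER_BLOCK):
            for s in range(N_SYLLABLES_PER_TRIAL):
                onset = block_onset + t * trial_period + s * SOA_S
                events.append(
                    SyllableEvent(
                        onset_s=onset,
                        duration_s=SYLLABLE_DURATION_S,
                        syllable_id=ids[t * N_SYLLABLES_PER_TRIAL + s],
                        trial_index=t,
                        block_index=b,
                        block_type=block_type,
                    )
                )
    return StimulusSchedule(events=events, block_onsets_s=block_onsets, block_types=block_types)


def write_events(schedule: StimulusSchedule, path) -> None:
    """Serialize events as a tab-separated table at millisecond precision."""
    schedule.to_frame().to_csv(path, sep="\t", index=False, float_format="%.3f")


def read_events(path) -> StimulusSchedule:
    """Read an events table written by :func:`write_events`."""
    df = pd.read_csv(path, sep="\t")
    required = {"onset", "duration", "trial_type", "block_index", "trial_index", "syllable_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"events file missing columns: {sorted(missing)}")
    events = [
        SyllableEvent(
            onset_s=float(r.onset),
            duration_s=float(r.duration),
            syllable_id=str(r.syllable_id),
            trial_index=int(r.trial_index),
            block_index=int(r.block_index),
            block_type=str(r.trial_type),
        )
        for r in df.itertuples()
    ]
    block_onsets, block_types = [], []
    for ev in events:
        if ev.block_index == len(block_onsets):
            block_onsets.append(ev.onset_s)
            block_types.append(ev.block_type)
    return StimulusSchedule(events=events, block_onsets_s=block_onsets, block_types=block_types)
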