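"""Task schedules and trial-level records for the sequential-viewing choice task.

The main task presents two visual objects one after the other.  Each object
carries a slowly varying, uncued reward probability (constant within blocks of
15-40 trials, drawn from an 8-element set) and a trial-specific, transiently
cued reward magnitude (three levels, in mL).  Control variants use four
objects with probability-only values, or two physically different juices whose
object-reward association reverses twice per session.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: reward probabilities available to the block scheduler (main task)
PROBABILITY_SET = (0.0, 0.15, 0.35, 0.5, 0.65, 0.75, 0.85, 1.0)
#: trial-wise cued reward magnitudes, mL
MAGNITUDE_SET = (0.25, 0.4, 0.65)
#: consolation reward delivered on non-rewarded trials, mL
SMALL_REWARD_ML = 0.05

BLOCK_LENGTH_RANGE = (15, 40)

TASK_VARIANTS = ("main", "four_objects", "two_juices")


class ConfigurationError(ValueError):
    """Raised when a schedule/population specification is invalid."""


@dataclass
class SessionSchedule:
    """Per-trial task structure for one session.

    ``trials`` is a DataFrame with one row per trial and columns:
    ``block_id``, ``prob_A``/``prob_B`` (and ``prob_C``/``prob_D`` for the
    four-objects variant), ``mag_A``/``mag_B`` (mL), ``first_object`` (object
    id viewed first), ``a_left`` (1 if object A reappears on the left during
    the choice period), and for ``two_juices``: ``juice_of_A`` (which juice
    object A currently predicts).
    """

    task_variant: str
    trials: pd.DataFrame
    seed: int
    objects: tuple[str, ...] = ("A", "B")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_blocks(self) -> int:
        if self.n_trials == 0:
            return 0
        return int(self.trials["block_id"].nunique())


def _block_lengths(rng: np.random.Generator, n_trials: int) -> list[int]:
    lengths: list[int] = []
    total = 0
    lo, hi = BLOCK_LENGTH_RANGE
    while total < n_trials:
        n = int(rng.integers(lo, hi + 1))
        n = min(n, n_trials - total)
        lengths.append(n)
        total += n
    return lengths


def generate_schedule(task_variant: str, n_trials: int, seed: int) -> SessionSchedule:
    """Generate a reproducible session schedule.

    Parameters
    ----------
    task_variant:
        ``"main"`` (probability x magnitude, two objects), ``"four_objects"``
        (probability only, two object sets of two objects), or ``"two_juices"``
        (reward type x magnitude, association reverses twice).
    n_trials:
        Number of trials (>= 0).
    seed:
        Seed for the dedicated generator; identical seeds give identical
        schedules.
    """
    if task_variant not in TASK_VARIANTS:
        raise ConfigurationError(f"unknown task variant: {task_variant!r}")
    if n_trials < 0:
        raise ConfigurationError("n_trials must be >= 0")
    rng = np.random.default_rng(seed)

    if task_variant == "main":
        return _schedule_main(rng, n_trials, seed)
    if task_variant == "four_objects":
        return _schedule_four_objects(rng, n_trials, seed)
    return _schedule_two_juices(rng, n_trials, seed)


def _empty_trials(columns: list[str]) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=float) for c in columns})


def _schedule_main(rng: np.random.Generator, n_trials: int, seed: int) -> SessionSchedule:
    cols = ["block_id", "prob_A", "prob_B", "mag_A", "mag_B", "first_object", "a_left"]
    if n_trials == 0:
        return SessionSchedule("main", _empty_trials(cols), seed)
    rows = []
    for block_id, length in enumerate(_block_lengths(rng, n_trials)):
        # probabilities pseudorandomly chosen per object, constant within block
        p_a = float(rng.choice(PROBABILITY_SET))
        p_b = float(rng.choice(PROBABILITY_SET))
        for _ in range(length):
            rows.append((block_id, p_a, p_b))
    block_id, prob_a, prob_b = map(np.asarray, zip(*rows))
    trials = pd.DataFrame(
        {
            "block_id": block_id.astype(int),
            "prob_A": prob_a,
            "prob_B": prob_b,
            # magnitudes drawn iid per object per trial; equality allowed
            "mag_A": rng.choice(MAGNITUDE_SET, size=n_trials),
            "mag_B": rng.choice(MAGNITUDE_SET, size=n_trials),
            "first_object": np.where(rng.random(n_trials) < 0.5, "A", "B"),
            "a_left": rng.integers(0, 2, size=n_trials),
        }
    )
    return SessionSchedule("main", trials, seed)


def _schedule_four_objects(rng: np.random.Generator, n_trials: int, seed: int) -> SessionSchedule:
    """Probability-only task: two object sets (A/B then C/D), 0.85/0.15
    probabilities that reverse between objects across blocks of 25-35 trials."""
    cols = [
        "block_id", "prob_A", "prob_B", "prob_C", "prob_D",
        "mag_A", "mag_B", "first_object", "a_left", "object_set",
    ]
    if n_trials == 0:
        return SessionSchedule("four_objects", _empty_trials(cols), seed, ("A", "B", "C", "D"))
    lengths: list[int] = []
    total = 0
    while total < n_trials:
        n = int(rng.integers(25, 36))
        n = min(n, n_trials - total)
        lengths.append(n)
        total += n
    half = n_trials // 2
    rows = []
    trial_idx = 0
    high_first = bool(rng.integers(0, 2))
    for block_id, length in enumerate(lengths):
        p_hi, p_lo = (0.85, 0.15)
        p1, p2 = (p_hi, p_lo) if high_first else (p_lo, p_hi)
        high_first = not high_first  # probabilities reverse between objects per block
        for _ in range(length):
            object_set = 0 if trial_idx < half else 1
            rows.append((block_id, p1, p2, object_set))
            trial_idx += 1
    block_id, p1, p2, object_set = map(np.asarray, zip(*rows))
    pair_first = np.where(object_set == 0, "A", "C")
    pair_second = np.where(object_set == 0, "B", "D")
    first_is_lead = rng.random(n_trials) < 0.5
    trials = pd.DataFrame(
        {
            "block_id": block_id.astype(int),
            "prob_A": np.where(object_set == 0, p1, np.nan),
            "prob_B": np.where(object_set == 0, p2, np.nan),
            "prob_C": np.where(object_set == 1, p1, np.nan),
            "prob_D": np.where(object_set == 1, p2, np.nan),
            # no magnitude cues in this task; fixed reward of 0.8 mL when rewarded
            "mag_A": np.full(n_trials, 0.8),
            "mag_B": np.full(n_trials, 0.8),
            "first_object": np.where(first_is_lead, pair_first, pair_second),
            "a_left": rng.integers(0, 2, size=n_trials),
            "object_set": object_set.astype(int),
        }
    )
    return SessionSchedule("four_objects", trials, seed, ("A", "B", "C", "D"))


def _schedule_two_juices(rng: np.random.Generator, n_trials: int, seed: int) -> SessionSchedule:
    """Magnitude x reward-type task: object-juice association changes twice."""
    cols = [
        "block_id", "prob_A", "prob_B", "mag_A", "mag_B",
        "first_object", "a_left", "juice_of_A",
    ]
    if n_trials == 0:
        return SessionSchedule("two_juices", _empty_trials(cols), seed)
    third = max(n_trials // 3, 1)
    juice_of_a = np.where((np.arange(n_trials) // third) % 2 == 0, "juice1", "juice2")
    trials = pd.DataFrame(
        {
            "block_id": (np.arange(n_trials) // third).astype(int),
            "prob_A": np.ones(n_trials),  # reward always delivered; value from type+magnitude
            "prob_B": np.ones(n_trials),
            "mag_A": rng.choice(MAGNITUDE_SET, size=n_trials),
            "mag_B": rng.choice(MAGNITUDE_SET, size=n_trials),
            "first_object": np.where(rng.random(n_trials) < 0.5, "A", "B"),
            "a_left": rng.integers(0, 2, size=n_trials),
            "juice_of_A": juice_of_a,
        }
    )
    return SessionSchedule("two_juices", trials, seed)


@dataclass
class SessionBehavior:
    """Schedule plus the realized trial-by-trial record of one agent session.

    ``trials`` extends the schedule columns with: ``chosen_object``,
    ``view_choice`` (1 = first-viewed chosen, 0 = second-viewed chosen),
    ``side_chosen`` ("left"/"right"), ``rewarded`` (0/1), ``reward_ml``,
    ``V_A``/``V_B`` (agent values at choice time) and ``pe`` (prediction
    error of the chosen object).
    """

    schedule: SessionSchedule
    trials: pd.DataFrame
    session_id: str
    seed: int
    agent_params: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def to_csv(self, path) -> None:
        self.trials.to_csv(path, index=False)
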