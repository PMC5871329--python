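"""Domain types and block-condition combinatorics for the passive-viewing task.

A session is organized in blocks of trial conditions.  With the standard
five-cue set (0, 1, 2, 4, 8 drops of juice) a block contains 85 conditions:
10 single-cue conditions (each cue on the left or the right), 25 ordered
double-cue conditions, and 50 perturbed double-cue conditions (each ordered
pair with a brief rotation applied to the left or to the right cue).

Time convention: analysis times are milliseconds relative to cue onset
(cue onset = 0); the session clock is stored separately on each trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: Trial epoch durations (ms).
FIXATION_DURATION_MS = 2000
CUE_DURATION_MS = 1000
DELAY_DURATION_MS = 1500

#: Standard visual perturbation: a 100 ms back-and-forth cue rotation
#: starting 200 ms after cue onset.
PERTURBATION_ONSET_MS = 200
PERTURBATION_DURATION_MS = 100

#: Reward sizes (drops of juice) of the standard five-cue set.
STANDARD_VALUES = (0, 1, 2, 4, 8)


class InvalidCueSetError(ValueError):
    """Raised when a cue set contains duplicate cue identifiers."""


@dataclass(frozen=True)
class Cue:
    """A visual shape associated with a fixed reward size.

    Parameters
    ----------
    cue_id
        Symbolic label, unique within a cue set.
    value
        Reward size in drops of juice (integer >= 0).
    """

    cue_id: str
    value: int

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"cue value must be >= 0, got {self.value}")


#: The standard cue set used throughout: cue ids name their value in drops.
STANDARD_CUE_SET: tuple[Cue, ...] = tuple(Cue(f"v{v}", v) for v in STANDARD_VALUES)


@dataclass(frozen=True)
class PerturbationEvent:
    """Timing of the visual perturbation, relative to cue onset."""

    onset_ms: int = PERTURBATION_ONSET_MS
    duration_ms: int = PERTURBATION_DURATION_MS

    @property
    def offset_ms(self) -> int:
        return self.onset_ms + self.duration_ms


@dataclass(frozen=True)
class Condition:
    """One of the per-block trial specifications.

    At least one cue must be present; a perturbation requires both cues.
    ``condition_id`` is a pure function of the other fields, so conditions
    round-trip exactly through serialization.
    """

    left_cue: Optional[Cue]
    right_cue: Optional[Cue]
    perturbed_side: str = "none"  # none | left | right

    def __post_init__(self) -> None:
        if self.left_cue is None and self.right_cue is None:
            raise ValueError("a condition requires at least one cue")
        if self.perturbed_side not in ("none", "left", "right"):
            raise ValueError(f"bad perturbed_side {self.perturbed_side!r}")
        if self.perturbed_side != "none" and (
            self.left_cue is None or self.right_cue is None
        ):
            raise ValueError("perturbation requires both cues present")

    @property
    def condition_id(self) -> str:
        left = self.left_cue.cue_id if self.left_cue else "-"
        right = self.right_cue.cue_id if self.right_cue else "-"
        if self.perturbed_side == "none":
            kind = "S" if self.is_single else "D"
            return f"{kind}:{left}|{right}"
        return f"P:{left}|{right}:{self.perturbed_side}"

    @property
    def is_single(self) -> bool:
        return self.left_cue is None or self.right_cue is None

    @property
    def is_double(self) -> bool:
        return not self.is_single

    @property
    def is_perturbed(self) -> bool:
        return self.perturbed_side != "none"

    @property
    def single_cue(self) -> Cue:
        if not self.is_single:
            raise ValueError("not a single-cue condition")
        return self.left_cue if self.left_cue is not None else self.right_cue

    @property
    def higher_value(self) -> int:
        """Value of the more valuable cue (the only cue if single)."""
        if self.is_single:
            return self.single_cue.value
        return max(self.left_cue.value, self.right_cue.value)

    @property
    def lower_value(self) -> int:
        if self.is_single:
            return self.single_cue.value
        return min(self.left_cue.value, self.right_cue.value)

    @property
    def perturbed_cue(self) -> Optional[Cue]:
        if self.perturbed_side == "left":
            return self.left_cue
        if self.perturbed_side == "right":
            return self.right_cue
        return None

    @property
    def perturbed_target(self) -> str:
        """Which cue of a perturbed pair was rotated: 'higher', 'lower' or 'equal'.

        Returns 'none' for unperturbed conditions.
        """
        cue = self.perturbed_cue
        if cue is None:
            return "none"
        other = self.right_cue if self.perturbed_side == "left" else self.left_cue
        if cue.value > other.value:
            return "higher"
        if cue.value < other.value:
            return "lower"
        return "equal"


@dataclass
class Trial:
    """A single presented trial with its event times on the session clock (ms)."""

    trial_id: int
    block_index: int
    condition_id: str
    completed: bool = True
    rewarded_side: Optional[str] = None  # left | right
    reward_drops: Optional[int] = None
    t_fixation_on_ms: float = 0.0
    t_cue_on_ms: float = field(default=float(FIXATION_DURATION_MS))
    t_cue_off_ms: float = field(
        default=float(FIXATION_DURATION_MS + CUE_DURATION_MS)
    )
    t_reward_ms: float = field(
        default=float(FIXATION_DURATION_MS + CUE_DURATION_MS + DELAY_DURATION_MS)
    )


def enumerate_block_conditions(cue_set: Sequence[Cue]) -> list[Condition]:
    """Enumerate every condition of one block for a given cue set.

    Returns all single-cue conditions (each cue x 2 sides), all ordered
    double-cue conditions (left x right, including same-cue pairs), and both
    perturbed variants of every double-cue condition, in a deterministic
    order: singles, doubles, perturbed.  For n cues this is 2n + n^2 + 2n^2
    conditions (85 for the standard five-cue set).

    Raises
    ------
    InvalidCueSetError
        If the cue set is empty or contains duplicate cue ids.
    """
    cues = list(cue_set)
    if not cues:
        raise InvalidCueSetError("cue set is empty")
    ids = [c.cue_id for c in cues]
    if len(set(ids)) != len(ids):
        raise InvalidCueSetError(f"duplicate cue_id in cue set: {ids}")

    conditions: list[Condition] = []
    for cue in cues:
        conditions.append(Condition(cue, None))
        conditions.append(Condition(None, cue))
    doubles = [Condition(lc, rc) for lc in cues for rc in cues]
    conditions.extend(doubles)
    for d in doubles:
        conditions.append(Condition(d.left_cue, d.right_cue, "left"))
        conditions.append(Condition(d.left_cue, d.right_cue, "right"))
    return conditions


def generate_block_order(
    conditions: Sequence[Condition], rng: np.random.Generator | int
) -> list[str]:
    """Randomly interleave the conditions of one block.

    Returns a permutation of the condition ids; each condition appears
    exactly once.  Reproducible given the same generator state or seed.
    """
    if not conditions:
        raise ValueError("conditions must be nonempty")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    ids = [c.condition_id for c in conditions]
    order = rng.permutation(len(ids))
    return [ids[i] for i in order]


def assign_reward(
    condition: Condition, rng: np.random.Generator
) -> tuple[Optional[str], int]:
    """Select the rewarded cue of a trial and return ``(side, drops)``.

    Single-cue trials deliver that cue's reward.  In double-cue trials each
    side is chosen with probability 0.5, independent of any perturbation.
    """
    if condition.is_single:
        side = "left" if condition.left_cue is not None else "right"
        return side, condition.single_cue.value
    side = "left" if rng.random() < 0.5 else "right"
    cue = condition.left_cue if side == "left" else condition.right_cue
    return side, cue.value


# ---------------------------------------------------------------------------
# Tabular serialization


def conditions_to_frame(conditions: Sequence[Condition]) -> pd.DataFrame:
    """Serialize conditions to the ``conditions.csv`` schema."""
    rows = []
    for c in conditions:
        rows.append(
            {
                "condition_id": c.condition_id,
                "left_cue_id": c.left_cue.cue_id if c.left_cue else "",
                "left_value": c.left_cue.value if c.left_cue else np.nan,
                "right_cue_id": c.right_cue.cue_id if c.right_cue else "",
                "right_value": c.right_cue.value if c.right_cue else np.nan,
                "perturbed_side": c.perturbed_side,
            }
        )
    return pd.DataFrame(rows)


def conditions_from_frame(frame: pd.DataFrame) -> list[Condition]:
    """Inverse of :func:`conditions_to_frame`."""
    out = []
    for row in frame.itertuples(index=False):
        # value columns may arrive as float strings ("4.0") after a CSV round
        # trip because the absent-cue rows force a float dtype
        left = (
            Cue(row.left_cue_id, int(float(row.left_value)))
            if row.left_cue_id
            else None
        )
        right = (
            Cue(row.right_cue_id, int(float(row.right_value)))
            if row.right_cue_id
            else None
        )
        out.append(Condition(left, right, row.perturbed_side))
    return out


def trials_to_frame(trials: Sequence[Trial]) -> pd.DataFrame:
    """Serialize trials to the ``trials.csv`` schema."""
    return pd.DataFrame(
        {
            "trial_id": [t.trial_id for t in trials],
            "block_index": [t.block_index for t in trials],
            "condition_id": [t.condition_id for t in trials],
            "completed": [t.completed for t in trials],
            "rewarded_side": [t.rewarded_side or "" for t in trials],
            "reward_drops": [t.reward_drops for t in trials],
            "t_fixation_on_ms": [t.t_fixation_on_ms for t in trials],
            "t_cue_on_ms": [t.t_cue_on_ms for t in trials],
            "t_cue_off_ms": [t.t_cue_off_ms for t in trials],
            "t_reward_ms": [t.t_reward_ms for t in trials],
        }
    )


def condition_lookup(conditions: Sequence[Condition]) -> dict[str, Condition]:
    """Map condition_id -> Condition."""
    return {c.condition_id: c for c in conditions}
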