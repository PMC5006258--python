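"""Response-adaptive randomization: allocation vector, decision rules, table.

After the burn-in phase the allocation probability of each open arm is
proportional to the information measure

    I_a = sqrt(P_a^max * V(U_a) / (n_a + 1)),

which favours arms likely to be best while still spending patients where
the utility is uncertain: among arms with equal P^max and variance, the
one with fewer patients (higher standard error) receives more allocation.

Decision rules at each interim: the trial succeeds when the most likely
arm's P_a^max reaches the success threshold (0.925 by default, inclusive);
an arm whose P_a^max drops to the loser threshold (0.01, inclusive) is
permanently closed to enrollment.

The allocation table mirrors a central EDC randomization module: an
ordered list of pre-generated arm codes; each new patient takes the next
unassigned slot; at each adaptation the unassigned remainder is deleted
and a freshly sampled block is appended.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .config import TrialConfig
from .errors import ConfigError, InvalidInputError, TableExhaustedError
from .posterior import PosteriorSummary

__all__ = [
    "TrialConfig",
    "RandomizationVector",
    "AllocationSlot",
    "AllocationTable",
    "information_measure",
    "randomization_vector",
    "check_success",
    "check_losers",
    "make_burnin_table",
    "adapt_table",
    "assign_next",
]


@dataclass(frozen=True)
class RandomizationVector:
    """Per-arm allocation probabilities with the permanently closed arms."""

    q: np.ndarray
    losers: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        object.__setattr__(self, "q", q)
        if np.any(q < 0) or abs(q.sum() - 1.0) > 1e-9:
            raise InvalidInputError(f"q must be a probability vector, got {q}")
        for a in self.losers:
            if q[a - 1] != 0.0:
                raise InvalidInputError(f"loser arm {a} must have q = 0")


@dataclass
class AllocationSlot:
    slot_index: int  # 1-based, strictly increasing down the table
    arm: int
    assigned: bool = False
    stratum: str | None = None


@dataclass
class AllocationTable:
    """Ordered randomization slots with assignment status."""

    slots: list[AllocationSlot] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.slots)

    def n_unassigned(self, stratum: str | None = None) -> int:
        return sum(
            1
            for s in self.slots
            if not s.assigned and (stratum is None or s.stratum == stratum)
        )

    def arm_counts(self, n_arms: int, first: int | None = None) -> np.ndarray:
        """Slots per arm over the whole table or its first ``first`` slots."""
        sel = self.slots if first is None else self.slots[:first]
        return np.bincount([s.arm - 1 for s in sel], minlength=n_arms)

    def copy(self) -> "AllocationTable":
        return AllocationTable([replace(s) for s in self.slots])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "slot_index": [s.slot_index for s in self.slots],
                "arm": [s.arm for s in self.slots],
                "assigned": [int(s.assigned) for s in self.slots],
                "stratum": [s.stratum if s.stratum is not None else "" for s in self.slots],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AllocationTable":
        slots = [
            AllocationSlot(
                slot_index=int(r.slot_index),
                arm=int(r.arm),
                assigned=bool(int(r.assigned)),
                stratum=(str(r.stratum) if str(r.stratum) not in ("", "nan") else None),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(slots)


def information_measure(p_max: float, var_utility: float, n: int) -> float:
    """I = sqrt(p_max * var_utility / (n + 1)); zero probability annihilates."""
    if p_max < 0 or var_utility < 0 or n < 0:
        raise InvalidInputError("information_measure inputs must be nonnegative")
    return float(np.sqrt(p_max * var_utility / (n + 1.0)))


def randomization_vector(
    summary: PosteriorSummary, losers: frozenset[int] | set[int] = frozenset()
) -> RandomizationVector:
    """Allocation probabilities proportional to I_a over the open arms.

    Loser arms get probability zero. If every open arm has zero
    information (degenerate posteriors), allocation is equal over the
    open arms.
    """
    A = summary.n_arms
    losers = frozenset(losers)
    open_arms = [a for a in range(1, A + 1) if a not in losers]
    if not open_arms:
        raise InvalidInputError("all arms are losers: allocation undefined")
    info = np.zeros(A)
    for a in open_arms:
        info[a - 1] = information_measure(
            float(summary.p_max[a - 1]),
            float(summary.var_utility[a - 1]),
            int(summary.n_enrolled[a - 1]),
        )
    total = info.sum()
    if total == 0.0:
        q = np.zeros(A)
        q[[a - 1 for a in open_arms]] = 1.0 / len(open_arms)
    else:
        q = info / total
    return RandomizationVector(q=q, losers=losers)


def check_success(summary: PosteriorSummary, threshold: float = 0.925) -> int | None:
    """The winning arm if the largest P_a^max reaches the threshold, else None."""
    best = summary.best_arm()
    if summary.p_max[best - 1] >= threshold:
        return best
    return None


def check_losers(
    summary: PosteriorSummary,
    threshold: float = 0.01,
    existing_losers: frozenset[int] | set[int] = frozenset(),
) -> frozenset[int]:
    """Arms whose P_a^max has fallen to the threshold; loser status is permanent."""
    new = {
        a
        for a in range(1, summary.n_arms + 1)
        if summary.p_max[a - 1] <= threshold
    }
    return frozenset(existing_losers) | new


def make_burnin_table(config: TrialConfig, rng: np.random.Generator) -> AllocationTable:
    """Initial allocation table: balanced burn-in block plus balanced spares.

    The first ``burn_in_n`` slots contain exactly ``burn_in_n / n_arms``
    of each arm in uniformly random order; ``burn_in_spare`` additional
    balanced slots follow so enrollment can continue while the first
    adapted table is being prepared. All slots start unassigned.
    """
    if config.burn_in_n % config.n_arms or config.burn_in_spare % config.n_arms:
        raise ConfigError("burn-in and spare sizes must be divisible by n_arms")
    arms_main = np.repeat(
        np.arange(1, config.n_arms + 1), config.burn_in_n // config.n_arms
    )
    arms_spare = np.repeat(
        np.arange(1, config.n_arms + 1), config.burn_in_spare // config.n_arms
    )
    rng.shuffle(arms_main)
    rng.shuffle(arms_spare)
    codes = np.concatenate([arms_main, arms_spare])
    return AllocationTable(
        [AllocationSlot(slot_index=i + 1, arm=int(a)) for i, a in enumerate(codes)]
    )


def adapt_table(
    table: AllocationTable,
    q: RandomizationVector,
    block_size: int,
    rng: np.random.Generator,
    stratum: str | None = None,
) -> AllocationTable:
    """Delete unassigned slots and append a freshly sampled block.

    Assigned slots are untouched and keep their slot indices; each of the
    ``block_size`` appended slots draws its arm independently with
    probabilities ``q``. Slot numbering continues past the largest index
    ever issued, so indices are never reused.
    """
    if block_size < 1:
        raise InvalidInputError("block_size must be >= 1")
    qv = np.asarray(q.q, dtype=float)
    if qv.sum() == 0.0:
        raise InvalidInputError("q contains only zeros")
    kept = [replace(s) for s in table.slots if s.assigned]
    next_index = max((s.slot_index for s in table.slots), default=0) + 1
    new_arms = rng.choice(len(qv), size=block_size, p=qv) + 1
    appended = [
        AllocationSlot(slot_index=next_index + i, arm=int(a), stratum=stratum)
        for i, a in enumerate(new_arms)
    ]
    return AllocationTable(kept + appended)


def assign_next(
    table: AllocationTable, stratum: str | None = None
) -> tuple[int, AllocationTable]:
    """Assign the next available slot; returns (arm, updated table).

    The table is updated in place (the EDC module's single master table)
    and also returned. Raises :class:`TableExhaustedError` when no
    unassigned slot remains — the signal to regenerate the table.
    """
    for slot in table.slots:
        if not slot.assigned and (stratum is None or slot.stratum == stratum):
            slot.assigned = True
            return slot.arm, table
    raise TableExhaustedError(
        "allocation table exhausted"
        + (f" for stratum {stratum!r}" if stratum is not None else "")
    )
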