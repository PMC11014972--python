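"""ASRT stimulus-sequence design and the triplet probability taxonomy.

The alternating serial reaction time (ASRT) task presents stimuli in one of
four positions. Post warm-up, pattern (P) and random (R) trials strictly
alternate; the pattern cycles through a fixed permutation of the four
positions (e.g. 4-R-2-R-3-R-1-R). Because the pattern is deterministic,
runs of three consecutive stimuli ("triplets") whose last element is the
pattern successor of the first occur five times more often per cell than
the remaining triplets. This module generates trial plans and derives the
64-cell triplet taxonomy analytically.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

POSITIONS = (1, 2, 3, 4)
BLOCK_LENGTH = 85
N_WARMUP = 5
SEQUENCE_REPEATS = 10

__all__ = [
    "PatternSequence",
    "TrialRole",
    "TrialPlan",
    "TripletTaxonomy",
    "ProbabilityClass",
    "ExclusionClass",
    "make_pattern",
    "generate_block",
    "probability_class",
    "exclusion_class",
    "theoretical_frequencies",
    "BLOCK_LENGTH",
    "N_WARMUP",
]


class TrialRole(str, enum.Enum):
    WARMUP = "WARMUP"
    PATTERN = "PATTERN"
    RANDOM = "RANDOM"


class ProbabilityClass(str, enum.Enum):
    HIGH = "HIGH"
    LOW = "LOW"


class ExclusionClass(str, enum.Enum):
    NONE = "NONE"
    TRILL = "TRILL"
    REPETITION = "REPETITION"


def _check_position(value: int, name: str = "position") -> int:
    if value not in POSITIONS:
        raise ValueError(f"{name} must be one of {POSITIONS}, got {value!r}")
    return int(value)


@dataclass(frozen=True)
class PatternSequence:
    """The cyclic pattern of the four pattern-trial positions.

    ``order`` lists the four pattern elements in cyclic order; ``succ`` maps
    each position to the pattern element that follows it one pattern trial
    later. ``succ`` is a 4-cycle and therefore has no fixed point, which is
    what forces high-probability triplets to never be trills or repetitions.
    """

    order: tuple[int, int, int, int]
    succ: Mapping[int, int]

    def __post_init__(self) -> None:
        if sorted(self.order) != list(POSITIONS):
            raise ValueError(
                f"pattern order must be a permutation of {POSITIONS}, got {self.order!r}"
            )
        for x, y in self.succ.items():
            if x == y:
                raise ValueError(f"pattern successor has a fixed point at {x}")


@dataclass(frozen=True)
class TrialPlan:
    block: int
    index_in_block: int
    role: TrialRole
    position: int


def make_pattern(order: Iterable[int]) -> PatternSequence:
    """Build a :class:`PatternSequence` from a permutation of 1..4.

    E.g. ``make_pattern((4, 2, 3, 1))`` encodes the 4-R-2-R-3-R-1-R design
    and yields ``succ = {4: 2, 2: 3, 3: 1, 1: 4}``.
    """
    order = tuple(int(v) for v in order)
    if len(order) != 4 or sorted(order) != list(POSITIONS):
        offending = [v for v in order if v not in POSITIONS]
        detail = f" (offending value(s): {offending})" if offending else " (duplicates present)"
        raise ValueError(f"order must be a permutation of {POSITIONS}, got {order!r}{detail}")
    succ = {order[i]: order[(i + 1) % 4] for i in range(4)}
    return PatternSequence(order=order, succ=succ)


def generate_block(
    pattern: PatternSequence, block_no: int, rng: np.random.Generator
) -> list[TrialPlan]:
    """Generate one 85-trial block: 5 random warm-up trials, then 10
    repetitions of the eight-element P-R alternation."""
    if block_no < 1:
        raise ValueError(f"block_no must be positive, got {block_no}")
    trials: list[TrialPlan] = []
    warm = rng.integers(1, 5, size=N_WARMUP)
    for i, pos in enumerate(warm, start=1):
        trials.append(TrialPlan(block_no, i, TrialRole.WARMUP, int(pos)))
    idx = N_WARMUP + 1
    for _ in range(SEQUENCE_REPEATS):
        for p_pos in pattern.order:
            trials.append(TrialPlan(block_no, idx, TrialRole.PATTERN, p_pos))
            idx += 1
            trials.append(
                TrialPlan(block_no, idx, TrialRole.RANDOM, int(rng.integers(1, 5)))
            )
            idx += 1
    assert len(trials) == BLOCK_LENGTH
    return trials


def probability_class(x: int, y: int, z: int, pattern: PatternSequence) -> ProbabilityClass:
    """HIGH iff the triplet's last element is the pattern successor of its
    first; the middle element is irrelevant."""
    x = _check_position(x, "x")
    _check_position(y, "y")
    z = _check_position(z, "z")
    return ProbabilityClass.HIGH if pattern.succ[x] == z else ProbabilityClass.LOW


def exclusion_class(x: int, y: int, z: int) -> ExclusionClass:
    """Classify a triplet as REPETITION (x-x-x), TRILL (x-y-x) or NONE.

    Repetitions take precedence so the categories partition.
    """
    x = _check_position(x, "x")
    y = _check_position(y, "y")
    z = _check_position(z, "z")
    if x == y == z:
        return ExclusionClass.REPETITION
    if x == z:
        return ExclusionClass.TRILL
    return ExclusionClass.NONE


@dataclass(frozen=True)
class TripletTaxonomy:
    """The 64-cell map from (x, y, z) triplets to probability class,
    exclusion class and long-run frequency."""

    pattern: PatternSequence
    table: pd.DataFrame  # columns: x, y, z, probability_class, exclusion_class, frequency

    @property
    def cells(self) -> dict[tuple[int, int, int], dict]:
        return {
            (r.x, r.y, r.z): {
                "probability_class": ProbabilityClass(r.probability_class),
                "exclusion_class": ExclusionClass(r.exclusion_class),
                "frequency": r.frequency,
            }
            for r in self.table.itertuples()
        }

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def theoretical_frequencies(pattern: PatternSequence) -> TripletTaxonomy:
    """Analytic long-run triplet frequencies over the post-warm-up stream.

    Half of all triplets end on a pattern trial: their (x, y) context is
    uniform (x is a random trial, y a pattern trial determined by the cycle
    position, both uniform over long runs) and z = succ(x) is forced, so
    that mass concentrates on the 16 HIGH cells at (1/2)(1/16) each.
    Triplets ending on random trials spread uniformly over all 64 cells at
    (1/2)(1/64) each. Hence HIGH cells carry 5/128 and LOW cells 1/128: the
    5:1 ratio.
    """
    rows = []
    for x in POSITIONS:
        for y in POSITIONS:
            for z in POSITIONS:
                pc = probability_class(x, y, z, pattern)
                ec = exclusion_class(x, y, z)
                freq = 5.0 / 128.0 if pc is ProbabilityClass.HIGH else 1.0 / 128.0
                rows.append(
                    dict(
                        x=x,
                        y=y,
                        z=z,
                        probability_class=pc.value,
                        exclusion_class=ec.value,
                        frequency=freq,
                    )
                )
    return TripletTaxonomy(pattern=pattern, table=pd.DataFrame(rows))


def plans_to_frame(plans: Iterable[TrialPlan]) -> pd.DataFrame:
    """Tidy trial-plan table: block, index_in_block, role, position."""
    return pd.DataFrame(
        [
            dict(
                block=t.block,
                index_in_block=t.index_in_block,
                role=t.role.value,
                position=t.position,
            )
            for t in plans
        ]
    )
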