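"""CSV schemas, readers/writers and input validation.

All interchange is plain CSV/JSON. Column names are part of the public
contract:

- trial CSV: subject_id, block, index_in_block, role, position, correct, rt_ms
- EF CSV: subject_id plus one column per measure
- block-score CSV: subject_id, block, median_rt_high, median_rt_low,
  learning_score, n_high, n_low
- studies CSV: label, r, n
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .design import BLOCK_LENGTH

TRIAL_COLUMNS = [
    "subject_id", "block", "index_in_block", "role", "position", "correct", "rt_ms",
]
BLOCK_SCORE_COLUMNS = [
    "subject_id", "block", "median_rt_high", "median_rt_low",
    "learning_score", "n_high", "n_low",
]

__all__ = [
    "TRIAL_COLUMNS",
    "BLOCK_SCORE_COLUMNS",
    "read_trials",
    "write_trials",
    "read_ef_scores",
    "write_block_scores",
    "read_block_scores",
    "write_json",
    "ValidationReport",
    "validate_trials",
]


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: trial CSV missing columns {sorted(missing)}")
    df["correct"] = df["correct"].astype(bool)
    return df


def write_trials(trials: pd.DataFrame, path) -> None:
    trials[TRIAL_COLUMNS].to_csv(path, index=False)


def read_ef_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise ValueError(f"{path}: EF CSV must contain a subject_id column")
    return df


def write_block_scores(scores: pd.DataFrame, path) -> None:
    scores[BLOCK_SCORE_COLUMNS].to_csv(path, index=False)


def read_block_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(BLOCK_SCORE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: block-score CSV missing columns {sorted(missing)}")
    return df


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def to_dict(self) -> dict:
        return {"ok": self.ok, "violations": self.violations, "warnings": self.warnings}


def validate_trials(trials: pd.DataFrame, source: str = "trials") -> ValidationReport:
    """Schema and invariant checks with one message per violation."""
    rep = ValidationReport()
    missing = set(TRIAL_COLUMNS) - set(trials.columns)
    if missing:
        rep.violations.append(f"{source}: missing columns {sorted(missing)}")
        return rep
    bad_pos = trials.index[~trials["position"].isin([1, 2, 3, 4])]
    for i in bad_pos[:20]:
        rep.violations.append(
            f"{source}: row {i}, column 'position': value "
            f"{trials.at[i, 'position']!r} outside 1..4"
        )
    bad_rt = trials.index[trials["rt_ms"] <= 0]
    for i in bad_rt[:20]:
        rep.violations.append(
            f"{source}: row {i}, column 'rt_ms': nonpositive RT {trials.at[i, 'rt_ms']!r}"
        )
    sizes = trials.groupby(["subject_id", "block"]).size()
    for (subj, block), size in sizes[sizes != BLOCK_LENGTH].items():
        rep.warnings.append(
            f"{source}: subject {subj} block {block} has {size} trials "
            f"(expected {BLOCK_LENGTH})"
        )
    dup = trials[["subject_id", "block", "index_in_block"]].duplicated()
    if dup.any():
        rep.violations.append(
            f"{source}: {int(dup.sum())} duplicated (subject_id, block, index_in_block) rows"
        )
    roles = set(trials["role"].unique()) - {"WARMUP", "PATTERN", "RANDOM"}
    if roles:
        rep.violations.append(f"{source}: unknown roles {sorted(roles)}")
    return rep
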