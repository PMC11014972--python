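"""Trial annotation, exclusion filters and block-wise learning scores.

A trial is annotated with the triplet formed by the positions at t-2, t-1
and t within the same block (never spanning block boundaries). Warm-up
trials provide context for later triplets but are themselves excluded, as
are trials with no complete triplet, trills (x-y-x), repetitions (x-x-x)
and fast guesses (RT < 100 ms). Block-wise medians of correct, retained
trials are computed separately for high- and low-probability triplet
endings; the learning score is median(low) - median(high), positive under
statistical learning.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .design import PatternSequence

logger = logging.getLogger(__name__)

FAST_RT_THRESHOLD_MS = 100.0
#: Exclusion reasons in precedence order; the first applicable one is kept.
EXCLUSION_PRECEDENCE = ("WARMUP", "NO_TRIPLET", "TRILL", "REPETITION", "FAST_RT")

__all__ = [
    "annotate",
    "exclusion_report",
    "block_medians",
    "subject_learning_score",
    "FAST_RT_THRESHOLD_MS",
]


def annotate(trials: pd.DataFrame, pattern: PatternSequence) -> pd.DataFrame:
    """Annotate a tidy trial table with triplet categories and exclusions.

    ``trials`` must contain subject_id, block, index_in_block, position,
    correct, rt_ms, sorted by (subject_id, block, index_in_block) with no
    duplicates. Returns a copy with columns x, y, z (NaN where no complete
    triplet exists), probability_class, exclusion_class, excluded and
    exclusion_reason.
    """
    required = {"subject_id", "block", "index_in_block", "position", "correct", "rt_ms"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table is missing columns: {sorted(missing)}")
    key = trials[["subject_id", "block", "index_in_block"]]
    if key.duplicated().any():
        dup = key[key.duplicated()].iloc[0]
        raise ValueError(
            "duplicated (subject_id, block, index_in_block): "
            f"({dup.subject_id}, {dup.block}, {dup.index_in_block})"
        )
    sorted_key = key.sort_values(["subject_id", "block", "index_in_block"])
    if not np.array_equal(sorted_key.to_numpy(), key.to_numpy()):
        raise ValueError("trials must be sorted by (subject_id, block, index_in_block)")
    bad_pos = ~trials["position"].isin([1, 2, 3, 4])
    if bad_pos.any():
        raise ValueError(
            f"positions outside 1..4 at rows {trials.index[bad_pos].tolist()[:5]}"
        )

    out = trials.copy()
    grp = out.groupby(["subject_id", "block"], sort=False)["position"]
    out["x"] = grp.shift(2)
    out["y"] = grp.shift(1)
    out["z"] = out["position"].astype(float)

    succ = np.zeros(5, dtype=np.int64)
    for a, b in pattern.succ.items():
        succ[a] = b
    has_triplet = out["x"].notna()
    xi = out["x"].fillna(1).astype(np.int64).to_numpy()
    yi = out["y"].fillna(1).astype(np.int64).to_numpy()
    zi = out["position"].to_numpy()
    high = succ[xi] == zi
    out["probability_class"] = np.where(
        has_triplet, np.where(high, "HIGH", "LOW"), "NONE"
    )
    repetition = has_triplet.to_numpy() & (xi == yi) & (yi == zi)
    trill = has_triplet.to_numpy() & (xi == zi) & ~repetition
    out["exclusion_class"] = np.where(
        repetition, "REPETITION", np.where(trill, "TRILL", "NONE")
    )

    is_warmup = out["index_in_block"] <= 5
    if "role" in out.columns:
        is_warmup = is_warmup | (out["role"] == "WARMUP")
    fast = out["rt_ms"] < FAST_RT_THRESHOLD_MS
    reason = np.full(len(out), "NONE", dtype=object)
    # applied in reverse precedence so earlier reasons overwrite later ones
    reason[fast.to_numpy()] = "FAST_RT"
    reason[repetition] = "REPETITION"
    reason[trill] = "TRILL"
    reason[~has_triplet.to_numpy()] = "NO_TRIPLET"
    reason[is_warmup.to_numpy()] = "WARMUP"
    out["exclusion_reason"] = reason
    out["excluded"] = reason != "NONE"
    return out


def exclusion_report(annotated: pd.DataFrame) -> dict:
    """Counts and percentages of excluded trials, by reason and overall."""
    n = len(annotated)
    counts = annotated["exclusion_reason"].value_counts().to_dict()
    by_reason = {
        r: {"count": int(counts.get(r, 0)), "percent": 100.0 * counts.get(r, 0) / n}
        for r in EXCLUSION_PRECEDENCE
    }
    n_excl = int(annotated["excluded"].sum())
    return {
        "n_trials": n,
        "n_excluded": n_excl,
        "percent_excluded": 100.0 * n_excl / n if n else float("nan"),
        "by_reason": by_reason,
    }


def block_medians(annotated: pd.DataFrame) -> pd.DataFrame:
    """Block-wise median RTs of correct, retained trials per triplet class.

    Returns one row per subject x block with columns median_rt_high,
    median_rt_low, learning_score (= low - high), n_high and n_low. Cells
    with no contributing trials are missing (NaN), never zero.
    """
    keep = annotated[~annotated["excluded"] & annotated["correct"].astype(bool)]
    cells = (
        keep.groupby(["subject_id", "block", "probability_class"])["rt_ms"]
        .agg(median="median", n="size")
        .reset_index()
    )
    all_cells = annotated[["subject_id", "block"]].drop_duplicates().set_index(
        ["subject_id", "block"]
    )
    if len(cells):
        wide = cells.pivot(index=["subject_id", "block"], columns="probability_class")
        frame = pd.DataFrame(index=wide.index)
        for cls, col in (("HIGH", "median_rt_high"), ("LOW", "median_rt_low")):
            frame[col] = wide["median"][cls] if cls in wide["median"] else np.nan
        for cls, col in (("HIGH", "n_high"), ("LOW", "n_low")):
            frame[col] = wide["n"][cls] if cls in wide["n"] else np.nan
    else:
        frame = pd.DataFrame(
            index=all_cells.index,
            columns=["median_rt_high", "median_rt_low", "n_high", "n_low"],
            dtype=float,
        )
    # subject x block cells present in the input but with no usable trials
    frame = frame.reindex(all_cells.index)
    frame[["n_high", "n_low"]] = frame[["n_high", "n_low"]].fillna(0).astype(int)
    frame["learning_score"] = frame["median_rt_low"] - frame["median_rt_high"]
    n_missing = int(frame["learning_score"].isna().sum())
    if n_missing:
        logger.info("block_medians: %d subject-block cells have a missing median", n_missing)
    return frame.reset_index()


def subject_learning_score(block_scores: pd.DataFrame) -> pd.Series:
    """Per-subject unweighted mean learning score over available blocks.

    Blocks with a missing score are skipped, not imputed; subjects with no
    valid block at all are dropped with a warning.
    """
    if len(block_scores) == 0:
        raise ValueError("block_scores is empty")
    means = block_scores.groupby("subject_id")["learning_score"].mean()
    dropped = means.index[means.isna()].tolist()
    if dropped:
        logger.warning(
            "subject_learning_score: dropping %d subject(s) with no valid block: %s",
            len(dropped),
            dropped[:10],
        )
    return means.dropna().rename("learning_score")
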