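"""Trial annotation, exclusion filtering and learning-score computation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from asrtlearn.scoring import (
    annotate,
    block_medians,
    exclusion_report,
    subject_learning_score,
)


def _trials(rows):
    return pd.DataFrame(
        rows,
        columns=["subject_id", "block", "index_in_block", "position", "correct", "rt_ms"],
    )


def toy_block(pattern):
    """A hand-built 12-trial block with known annotation outcomes.

    Positions (pattern succ: 4→2, 2→3, 3→1, 1→4):
    idx:      1  2  3  4  5 | 6  7  8  9  10  11  12
    pos:      1  2  3  4  1 | 4  3  2  1   3   2   4
    Exclusions: idx 1-5 WARMUP. Triplets from idx 6 on:
      6:(4,1,4) trill -> TRILL;      7:(1,4,3) -> keep (LOW)
      8:(4,3,2) -> keep (HIGH);      9:(3,2,1) -> keep (HIGH)
      10:(2,1,3) -> keep (HIGH);     11:(1,3,2) -> keep (LOW)
      12:(3,2,4) rt 90 -> FAST_RT
    => 5 warm-up + TRILL + FAST_RT = 7 excluded, 5 kept.
    """
    rows = []
    positions = [1, 2, 3, 4, 1, 4, 3, 2, 1, 3, 2, 4]
    rts = [300.0] * 11 + [90.0]
    for i, (p, rt) in enumerate(zip(positions, rts), start=1):
        rows.append((1, 1, i, p, True, rt))
    return _trials(rows)


class TestAnnotate:
    def test_hand_built_block_annotation(self, pattern):
        ann = annotate(toy_block(pattern), pattern)
        reasons = ann["exclusion_reason"].tolist()
        assert reasons[:5] == ["WARMUP"] * 5
        assert reasons[5] == "TRILL"
        assert reasons[6:11] == ["NONE"] * 5
        assert reasons[11] == "FAST_RT"
        assert ann["excluded"].sum() == 7
        assert ann.loc[7, "probability_class"] == "HIGH"  # idx 8: (4,3,2)
        rep = exclusion_report(ann)
        assert rep["n_excluded"] == 7
        assert rep["percent_excluded"] == pytest.approx(100 * 7 / 12)

    def test_fast_rt_boundary(self, pattern):
        rows = [(1, 1, i, p, True, rt) for i, (p, rt) in enumerate(
            zip([1, 2, 3, 4, 1, 4, 3, 2], [300] * 6 + [99.0, 100.0]), start=1)]
        ann = annotate(_trials(rows), pattern)
        assert ann.loc[6, "exclusion_reason"] == "FAST_RT"   # rt 99
        assert ann.loc[7, "exclusion_reason"] == "NONE"      # rt 100 kept

    def test_no_triplet_for_short_context(self, pattern):
        # a block starting at index 1 with only 3 trials and no warm-up labels
        rows = [(1, 1, i, p, True, 300.0) for i, p in enumerate([1, 2, 3], 1)]
        df = _trials(rows)
        df["index_in_block"] = [6, 7, 8]  # beyond warm-up range
        ann = annotate(df, pattern)
        assert ann["exclusion_reason"].tolist()[:2] == ["NO_TRIPLET", "NO_TRIPLET"]

    def test_triplets_do_not_span_blocks(self, pattern):
        rows = [(1, b, i, p, True, 300.0)
                for b in (1, 2)
                for i, p in enumerate([1, 2, 3, 4, 1, 4, 3, 2], start=1)]
        ann = annotate(_trials(rows), pattern)
        first_of_block2 = ann[(ann.block == 2)].iloc[0]
        assert np.isnan(first_of_block2["x"])

    def test_unsorted_or_duplicated_input_rejected(self, pattern):
        good = toy_block(pattern)
        with pytest.raises(ValueError, match="sorted"):
            annotate(good.iloc[::-1].reset_index(drop=True), pattern)
        dup = pd.concat([good, good.iloc[[3]]], ignore_index=True).sort_values(
            ["subject_id", "block", "index_in_block"]).reset_index(drop=True)
        with pytest.raises(ValueError, match="duplicated"):
            annotate(dup, pattern)

    def test_filtering_is_idempotent_and_reasons_partition(self, pattern, small_cohort):
        _, _, trials, _ = small_cohort
        ann = annotate(trials, pattern)
        ann2 = annotate(ann[trials.columns], pattern)
        assert ann["exclusion_reason"].equals(ann2["exclusion_reason"])
        assert (ann["excluded"] == (ann["exclusion_reason"] != "NONE")).all()

    def test_trill_repetition_share_converges(self, pattern, small_cohort):
        """Only random-ending triplets can be trills/repetitions: their
        asymptotic share of post-warm-up trials is (1/2)(1/4) = 12.5%."""
        _, _, trials, _ = small_cohort
        ann = annotate(trials, pattern)
        body = ann[ann["exclusion_reason"] != "WARMUP"]
        share = body["exclusion_reason"].isin(["TRILL", "REPETITION"]).mean()
        n = len(body)
        assert share == pytest.approx(0.125, abs=4 * np.sqrt(0.125 * 0.875 / n))


class TestBlockMedians:
    def test_hand_median_example(self, pattern):
        ann = annotate(toy_block(pattern), pattern)
        # surviving: idx 8, 9, 10 HIGH; idx 7, 11 LOW
        ann.loc[ann.index_in_block.isin([8, 9, 10]), "rt_ms"] = [300.0, 310.0, 320.0]
        ann.loc[ann.index_in_block.isin([7, 11]), "rt_ms"] = [330.0, 350.0]
        scores = block_medians(ann)
        row = scores.iloc[0]
        assert row["median_rt_high"] == 310.0
        assert row["median_rt_low"] == 340.0
        assert row["learning_score"] == 30.0
        assert (row["n_high"], row["n_low"]) == (3, 2)

    def test_all_incorrect_block_yields_missing_medians(self, pattern):
        df = toy_block(pattern)
        df["correct"] = False
        scores = block_medians(annotate(df, pattern))
        assert len(scores) == 1
        assert np.isnan(scores.iloc[0]["median_rt_high"])
        assert np.isnan(scores.iloc[0]["learning_score"])
        assert scores.iloc[0]["n_high"] == 0

    def test_learning_score_invariant_to_rt_shift(self, pattern):
        # no fast-guess contaminants, so the RT filter keeps the same trials
        from asrtlearn.cohort import simulate_cohort, study1_config

        cfg = study1_config(
            n_subjects=15, n_blocks=6, fast_guess_rate=0.0, rt_noise_sd=30.0, seed=3
        )
        _, trials, _ = simulate_cohort(cfg)
        base = block_medians(annotate(trials, pattern))
        shifted = trials.copy()
        shifted["rt_ms"] = shifted["rt_ms"] + 250.0
        shift = block_medians(annotate(shifted, pattern))
        pd.testing.assert_series_equal(
            base["learning_score"], shift["learning_score"], atol=1e-9
        )

    def test_learning_score_tracks_simulated_gap(self, pattern):
        from asrtlearn.cohort import simulate_cohort, study1_config

        means = {}
        for gap in (4.0, 8.0):
            cfg = study1_config(
                n_subjects=60, n_blocks=12, sl_effect_mean=gap, sl_effect_sd=0.0,
                sl_block_slope=0.0, seed=77,
            )
            _, trials, _ = simulate_cohort(cfg)
            scores = subject_learning_score(block_medians(annotate(trials, pattern)))
            means[gap] = scores.mean()
        assert means[4.0] == pytest.approx(4.0, abs=1.5)
        assert means[8.0] == pytest.approx(2 * means[4.0], abs=2.0)


class TestSubjectScore:
    def test_unweighted_mean_and_skipped_missing(self):
        scores = pd.DataFrame(
            {"subject_id": [1, 1, 1, 2], "block": [1, 2, 3, 1],
             "learning_score": [2.0, 4.0, np.nan, np.nan]}
        )
        out = subject_learning_score(scores)
        assert out.loc[1] == 3.0
        assert 2 not in out.index  # no valid block: dropped

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            subject_learning_score(pd.DataFrame(columns=["subject_id", "learning_score"]))

    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=8))
    def test_matches_plain_mean(self, vals):
        df = pd.DataFrame(
            {"subject_id": 1, "block": range(1, len(vals) + 1), "learning_score": vals}
        )
        assert subject_learning_score(df).loc[1] == pytest.approx(np.mean(vals))
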