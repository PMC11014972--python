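"""Trajectory mixed model: frame construction, fitting, contrasts."""

import numpy as np
import pandas as pd
import pytest

from asrtlearn.cohort import simulate_cohort, study1_config
from asrtlearn.design import make_pattern
from asrtlearn.scoring import annotate, block_medians
from asrtlearn.trajectories import LearningTrajectoryModel, build_model_frame


def _block_scores(n_subj=12, n_blocks=5, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(1, n_subj + 1):
        for b in range(1, n_blocks + 1):
            hi = 350 + rng.normal(0, 5)
            rows.append((s, b, hi, hi + 3.0))
    return pd.DataFrame(
        rows, columns=["subject_id", "block", "median_rt_high", "median_rt_low"]
    )


@pytest.fixture(scope="module")
def fitted_cohort():
    """One fitted Study-1-style cohort shared by the model tests."""
    pattern = make_pattern((4, 2, 3, 1))
    cfg = study1_config(n_subjects=60, n_blocks=15, seed=202)
    profiles, trials, ef = simulate_cohort(cfg)
    scores = block_medians(annotate(trials, pattern))
    fit = LearningTrajectoryModel.from_scores(scores).fit()
    return cfg, profiles, scores, fit


class TestModelFrame:
    def test_row_count_and_coding(self):
        frame, centring = build_model_frame(_block_scores(12, 5))
        assert len(frame) == 12 * 5 * 2
        assert set(frame["triplet"].unique()) == {-1.0, 1.0}
        assert frame["block_c"].mean() == pytest.approx(0.0, abs=1e-12)
        assert centring["block"] == pytest.approx(3.0)

    def test_ef_columns_centred_and_missing_subjects_dropped(self):
        scores = _block_scores(10, 4)
        factors = pd.DataFrame(
            {"subject_id": range(1, 9), "F1": np.linspace(-1, 1, 8)}
        )  # subjects 9, 10 missing
        frame, centring = build_model_frame(scores, factors)
        assert frame["subject_id"].nunique() == 8
        assert frame["F1"].mean() == pytest.approx(0.0, abs=1e-12)
        assert "F1" in centring

    def test_missing_medians_are_dropped_not_imputed(self):
        scores = _block_scores(4, 3)
        scores.loc[0, "median_rt_high"] = np.nan
        frame, _ = build_model_frame(scores)
        assert len(frame) == 4 * 3 * 2 - 1


class TestFit:
    def test_triplet_coefficient_is_minus_half_gap(self, fitted_cohort):
        cfg, profiles, _, fit = fitted_cohort
        true_b = -np.mean([p.delta_s for p in profiles]) / 2
        row = fit.fixed_effects().loc["triplet"]
        se = (row["ci_high"] - row["ci_low"]) / (2 * 1.959964)
        assert row["b"] == pytest.approx(true_b, abs=4 * se)

    def test_block_slope_recovered(self, fitted_cohort):
        cfg, profiles, _, fit = fitted_cohort
        true_slope = cfg.skill_slope + np.mean([p.u1 for p in profiles])
        row = fit.fixed_effects().loc["block_c"]
        se = (row["ci_high"] - row["ci_low"]) / (2 * 1.959964)
        assert row["b"] == pytest.approx(true_slope, abs=4 * se)

    def test_r2_ordering_and_icc_bounds(self, fitted_cohort):
        *_, fit = fitted_cohort
        assert 0 <= fit.r2_marginal <= fit.r2_conditional <= 1
        assert 0 <= fit.icc_adjusted <= 1
        re = fit.random_effects
        assert re["var_intercept"] >= 0 and re["var_residual"] > 0
        assert abs(re["corr_intercept_slope"]) <= 1

    def test_rt_shift_moves_only_intercept(self, fitted_cohort):
        _, _, scores, fit = fitted_cohort
        shifted = scores.copy()
        shifted[["median_rt_high", "median_rt_low"]] += 100.0
        fit2 = LearningTrajectoryModel.from_scores(shifted).fit()
        b1, b2 = fit.params, fit2.params
        assert b2["Intercept"] - b1["Intercept"] == pytest.approx(100.0, abs=0.2)
        for term in b1.index:
            if term != "Intercept":
                assert b2[term] == pytest.approx(b1[term], abs=0.05)

    def test_summary_mentions_structure_and_sizes(self, fitted_cohort):
        *_, fit = fitted_cohort
        text = fit.summary()
        assert "observations" in text and "subjects" in text
        assert "R2 marginal" in text


class TestInteractionCalibration:
    def test_wald_interaction_calibrated_under_model_assumptions(self):
        """With homogeneous SL gaps (no unmodelled per-subject triplet
        variance) the Triplet x EF Wald test holds its nominal level; the
        companion acceptance check shows it inflates once gaps vary
        between subjects."""
        rejections = 0
        n_reps = 60
        for rep in range(n_reps):
            cfg = study1_config(
                n_subjects=40, n_blocks=10, ef_sl_corr=0.0, sl_effect_sd=0.0,
                seed=70_000 + rep,
            )
            profiles, trials, _ = simulate_cohort(cfg, seed=70_000 + rep)
            scores = block_medians(annotate(trials, make_pattern((4, 2, 3, 1))))
            factors = pd.DataFrame(
                {"subject_id": [p.subject_id for p in profiles],
                 "F1": [p.f[0] for p in profiles]}
            )
            fit = LearningTrajectoryModel.from_scores(scores, factors).fit()
            rejections += fit.fixed_effects().loc["triplet:F1", "p"] < 0.05
        # true rate 0.05 over 60 replicates: binomial SE 0.028
        assert rejections / n_reps <= 0.05 + 3.5 * 0.028


@pytest.fixture(scope="module")
def ef_fit():
    pattern = make_pattern((4, 2, 3, 1))
    cfg = study1_config(n_subjects=50, n_blocks=12, seed=303)
    profiles, trials, ef = simulate_cohort(cfg)
    scores = block_medians(annotate(trials, pattern))
    factors = pd.DataFrame(
        {"subject_id": [p.subject_id for p in profiles],
         "F1": [p.f[0] for p in profiles]}
    )
    return LearningTrajectoryModel.from_scores(scores, factors).fit()


class TestContrasts:
    def test_triplet_slope_contrast_is_twice_interaction(self, ef_fit):
        c = ef_fit.triplet_slope_contrast()
        b = ef_fit.params
        name = "triplet:block_c" if "triplet:block_c" in b.index else "block_c:triplet"
        assert c.estimate == pytest.approx(2 * b[name])
        assert c.ci_low <= c.estimate <= c.ci_high

    def test_simple_slopes_differ_by_interaction_times_gap(self, ef_fit):
        out = ef_fit.simple_slopes("F1", at_quantiles=(0.25, 0.75))
        assert len(out) == 3
        diff = out[1].estimate - out[0].estimate
        assert out[2].estimate == pytest.approx(diff, abs=1e-10)

    def test_unknown_term_is_named_in_error(self, ef_fit):
        with pytest.raises(ValueError, match="F1"):
            ef_fit.simple_slopes("F9")

    def test_zero_interaction_gives_identical_slopes(self):
        # pure additive data: no triplet x block or EF effects
        scores = _block_scores(30, 8, seed=9)
        factors = pd.DataFrame(
            {"subject_id": range(1, 31),
             "F1": np.random.default_rng(5).standard_normal(30)}
        )
        fit = LearningTrajectoryModel.from_scores(scores, factors).fit()
        out = fit.simple_slopes("F1", at_quantiles=(0.25, 0.75))
        # interaction is pure noise, so slope difference is tiny and n.s.
        assert abs(out[2].estimate) < 0.5
        assert out[2].p > 0.01
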