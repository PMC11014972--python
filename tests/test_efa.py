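"""Factorability diagnostics, parallel analysis, ML EFA and factor scores."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from asrtlearn.cohort import LOADING_TEMPLATES, simulate_ef_scores, simulate_profiles, study1_config
from asrtlearn.efa import (
    ExploratoryFactorModel,
    factorability,
    ml_efa,
    parallel_analysis,
    thomson_scores,
    varimax,
)


def _one_factor_data(lam, p, n, seed=0):
    rng = np.random.default_rng(seed)
    L = np.full(p, lam)
    f = rng.standard_normal(n)
    X = np.outer(f, L) + rng.standard_normal((n, p)) * np.sqrt(1 - lam**2)
    return pd.DataFrame(X, columns=[f"m{i}" for i in range(p)])


def _align(L, target):
    """Permute/sign-flip columns of L to best match target (small k)."""
    import itertools

    k = L.shape[1]
    best, best_err = None, np.inf
    for perm in itertools.permutations(range(k)):
        for signs in itertools.product([1, -1], repeat=k):
            cand = L[:, perm] * np.array(signs)
            err = np.abs(cand - target).max()
            if err < best_err:
                best, best_err = cand, err
    return best


class TestFactorability:
    def test_independent_data_has_small_bartlett_chi2(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.standard_normal((4000, 6)))
        rep = factorability(X)
        assert rep.bartlett_df == 15
        assert rep.bartlett_p > 0.01  # no evidence against sphericity

    def test_one_factor_data_is_factorable(self):
        X = _one_factor_data(0.8, 6, 5000)
        rep = factorability(X)
        assert rep.kmo_overall > 0.85
        assert all(v > 0.5 for v in rep.msa_per_item.values())
        assert rep.bartlett_p < 1e-10

    def test_nine_measures_give_df_36(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.standard_normal((200, 9)))
        assert factorability(X).bartlett_df == 36


class TestParallelAnalysis:
    def test_pure_noise_retains_no_factors(self):
        rng = np.random.default_rng(3)
        hits = 0
        for i in range(25):
            X = pd.DataFrame(rng.standard_normal((186, 9)))
            res = parallel_analysis(X, n_sims=200, rng=np.random.default_rng(100 + i))
            hits += res.n_factors == 0
        assert hits >= 22  # ~95% by construction of the 95th-percentile rule

    def test_one_factor_structure_detected(self):
        X = _one_factor_data(0.6, 9, 186, seed=4)
        res = parallel_analysis(X, n_sims=500, seed=5)
        assert res.n_factors == 1

    def test_count_monotone_in_percentile(self):
        X = _one_factor_data(0.45, 9, 150, seed=6)
        counts = [
            parallel_analysis(X, n_sims=300, percentile=q, seed=7).n_factors
            for q in (50, 75, 95, 99)
        ]
        assert counts == sorted(counts, reverse=True)


class TestVarimax:
    def test_preserves_communalities_and_orders_columns(self):
        rng = np.random.default_rng(8)
        L = rng.normal(0, 0.4, size=(7, 3))
        R = varimax(L)
        np.testing.assert_allclose((R**2).sum(1), (L**2).sum(1), atol=1e-8)
        ssq = (R**2).sum(0)
        assert np.all(np.diff(ssq) <= 1e-9)
        # each factor's largest-|loading| entry is positive
        assert all(R[np.abs(R[:, j]).argmax(), j] > 0 for j in range(3))


class TestMLEFA:
    def test_perfect_fit_recovers_structure(self):
        L = LOADING_TEMPLATES["STUDY2"].to_numpy()
        R = L @ L.T + np.diag(1 - (L**2).sum(1))
        model = ExploratoryFactorModel.from_correlation(R, n_obs=157)
        res = model.fit(2)
        assert res.discrepancy == pytest.approx(0.0, abs=1e-8)
        assert res.chi2 == pytest.approx(0.0, abs=1e-5)
        assert res.rmsea == pytest.approx(0.0, abs=1e-6)
        assert res.srmr == pytest.approx(0.0, abs=1e-5)
        # varimax optimum can differ from the template by a tiny rotation
        aligned = _align(res.loadings.to_numpy(), L)
        np.testing.assert_allclose(aligned, L, atol=5e-3)

    def test_template_recovery_on_large_cohort(self):
        """ML EFA on a 10,000-subject synthetic cohort recovers the
        one-factor template loadings within +/-0.05."""
        cfg = study1_config(n_subjects=10_000)
        profiles = simulate_profiles(cfg, np.random.default_rng(9))
        ef = simulate_ef_scores(profiles, "STUDY1", np.random.default_rng(10))
        res = ml_efa(ef.drop(columns="subject_id"), 1)
        template = LOADING_TEMPLATES["STUDY1"].to_numpy().ravel()
        got = _align(res.loadings.to_numpy(), template[:, None]).ravel()
        np.testing.assert_allclose(got, template, atol=0.05)
        np.testing.assert_allclose(
            res.communalities.to_numpy(), template**2, atol=0.06
        )
        np.testing.assert_allclose(
            (res.uniquenesses + res.communalities).to_numpy(), 1.0, atol=1e-8
        )

    def test_too_many_factors_rejected(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.standard_normal((100, 5)))
        with pytest.raises(ValueError, match="degrees of freedom"):
            ml_efa(X, 3)  # df = ((5-3)^2 - 8)/2 < 0

    def test_matches_r_factanal_on_fixture(self, tmp_path):
        """Independent oracle: R's factanal on the same sample correlation
        matrix gives the same loadings, uniquenesses and chi-square."""
        L = LOADING_TEMPLATES["STUDY2"].to_numpy()
        rng = np.random.default_rng(12)
        f = rng.standard_normal((400, 2))
        X = f @ L.T + rng.standard_normal((400, 5)) * np.sqrt(1 - (L**2).sum(1))
        df = pd.DataFrame(X, columns=list("abcde"))
        res = ml_efa(df, 2)
        csv = tmp_path / "x.csv"
        df.to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            X <- as.matrix(read.csv("{csv}"))
            f <- factanal(X, factors = 2, rotation = "varimax")
            cat(unclass(f$loadings), f$uniquenesses, f$STATISTIC, sep = ",")
        """)
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        vals = np.array([float(v) for v in out.stdout.strip().split(",")])
        r_load = vals[:10].reshape(2, 5).T
        r_uniq = vals[10:15]
        r_chi2 = vals[15]
        aligned = _align(res.loadings.to_numpy(), r_load)
        np.testing.assert_allclose(aligned, r_load, atol=2e-3)
        np.testing.assert_allclose(res.uniquenesses.to_numpy(), r_uniq, atol=2e-3)
        assert res.chi2 == pytest.approx(r_chi2, abs=0.05)


class TestFitIndices:
    def test_rmsea_closed_form(self):
        """RMSEA = sqrt((chi2 - df) / (df (n-1))) on the printed-scale case
        chi2 = 36.87, df = 27, n = 186 gives 0.044."""
        from asrtlearn.efa import _rmsea

        point, ci = _rmsea(36.87, 27, 186)
        assert point == pytest.approx(0.0444, abs=5e-4)
        assert ci[0] == pytest.approx(0.0, abs=1e-6)
        assert 0.05 < ci[1] < 0.10

    def test_chi2_equal_df_gives_zero_rmsea(self):
        from asrtlearn.efa import _rmsea

        point, _ = _rmsea(27.0, 27, 186)
        assert point == 0.0


class TestThomsonScores:
    def test_identity_loadings_reproduce_standardized_data(self):
        rng = np.random.default_rng(13)
        X = pd.DataFrame(rng.standard_normal((500, 3)), columns=list("abc"))
        # algebra limit: with Lambda = R (k = p), the weights R^-1 Lambda = I
        model = ExploratoryFactorModel(X)
        from asrtlearn.efa import EFAResults

        fake_res = EFAResults.__new__(EFAResults)
        fake_res.model = model
        fake_res.loadings = pd.DataFrame(
            model.corr, index=list("abc"), columns=["F1", "F2", "F3"]
        )
        scores = thomson_scores(X, fake_res)
        Z = (X - X.mean()) / X.std(ddof=1)
        np.testing.assert_allclose(scores.to_numpy(), Z.to_numpy(), atol=1e-10)

    def test_scores_track_latent_factor(self):
        X = _one_factor_data(0.6, 9, 4000, seed=14)
        rng = np.random.default_rng(14)
        f = rng.standard_normal(4000)  # same stream order as _one_factor_data
        res = ml_efa(X, 1)
        scores = res.factor_scores()
        assert abs(np.corrcoef(scores["F1"], f)[0, 1]) > 0.85

    def test_missing_measure_subject_dropped(self):
        X = _one_factor_data(0.7, 5, 300, seed=15)
        res = ml_efa(X, 1)
        X2 = X.copy()
        X2.iloc[0, 0] = np.nan
        scores = res.factor_scores(X2)
        assert len(scores) == len(X2) - 1
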