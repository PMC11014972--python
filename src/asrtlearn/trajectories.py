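"""Linear mixed models for ASRT learning trajectories.

The outcome is the block-wise median RT, one row per subject x block x
triplet type. Fixed effects are Triplet Type (sum-coded: low = -1,
high = +1, so the coefficient equals minus half the low-high gap), Block
and the EF factor score(s) (both mean-centred continuous), with all
interactions; random effects are correlated subject-specific intercepts
and Block slopes. Numerical REML optimisation is delegated to
``statsmodels`` MixedLM; this module owns coding, centring, contrasts,
variance decomposition (Nakagawa marginal/conditional R2, adjusted ICC)
and the output schema.

Wald tests are used for fixed effects: the reference distribution is
normal (F = z^2 on 1 numerator df), a large-sample approximation reported
in place of Satterthwaite denominator degrees of freedom, which the
backend does not provide.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

logger = logging.getLogger(__name__)

__all__ = [
    "build_model_frame",
    "LearningTrajectoryModel",
    "TrajectoryResults",
    "Contrast",
]


def build_model_frame(
    block_scores: pd.DataFrame,
    factor_scores: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Long model table: one row per subject x block x triplet type.

    ``block_scores`` needs subject_id, block, median_rt_high and
    median_rt_low; ``factor_scores`` (optional) is indexed or keyed by
    subject_id with one column per EF factor. Triplet type is coded
    low = -1, high = +1; block and EF columns are mean-centred (constants
    returned in the second element for reporting). Subjects without factor
    scores are dropped with a warning.
    """
    long = block_scores.melt(
        id_vars=["subject_id", "block"],
        value_vars=["median_rt_high", "median_rt_low"],
        var_name="triplet_type",
        value_name="rt",
    )
    long["triplet"] = np.where(long["triplet_type"] == "median_rt_high", 1.0, -1.0)
    long = long.drop(columns="triplet_type").dropna(subset=["rt"])

    ef_names: list[str] = []
    if factor_scores is not None:
        fs = factor_scores.copy()
        if "subject_id" not in fs.columns:
            fs = fs.reset_index().rename(columns={fs.index.name or "index": "subject_id"})
        ef_names = [c for c in fs.columns if c != "subject_id"]
        before = long["subject_id"].nunique()
        long = long.merge(fs, on="subject_id", how="inner")
        dropped = before - long["subject_id"].nunique()
        if dropped:
            logger.warning(
                "build_model_frame: dropped %d subject(s) without factor scores",
                dropped,
            )

    centring = {"block": float(long["block"].mean())}
    long["block_c"] = long["block"] - centring["block"]
    for name in ef_names:
        centring[name] = float(long[name].mean())
        long[name] = long[name] - centring[name]
    return long, centring


@dataclass(frozen=True)
class Contrast:
    description: str
    estimate: float
    ci_low: float
    ci_high: float
    p: float


class LearningTrajectoryModel:
    """Trajectory LMM specification bound to a prepared model frame."""

    def __init__(self, frame: pd.DataFrame, ef_names: list[str] | None = None):
        self.frame = frame
        self.ef_names = ef_names if ef_names is not None else [
            c
            for c in frame.columns
            if c not in {"subject_id", "block", "block_c", "rt", "triplet"}
        ]
        terms = ["triplet", "block_c", *self.ef_names]
        self.formula = "rt ~ " + " * ".join(terms)

    @classmethod
    def from_scores(
        cls,
        block_scores: pd.DataFrame,
        factor_scores: pd.DataFrame | None = None,
    ) -> "LearningTrajectoryModel":
        frame, centring = build_model_frame(block_scores, factor_scores)
        model = cls(frame)
        model.centring = centring
        return model

    def fit(self, reml: bool = True) -> "TrajectoryResults":
        """REML fit with a logged simplification ladder on non-convergence:
        correlated intercept+slope, then uncorrelated, then intercept-only.

        Within each structure several optimizers are tried and the
        converged fit with the highest restricted likelihood is kept; the
        default gradient optimizer can stall on a poor local mode for this
        outcome scale.
        """
        attempts = [
            ("correlated intercept + block slope", dict(re_formula="~block_c")),
            (
                "uncorrelated intercept + block slope",
                dict(re_formula="~1", vc_formula={"blockslope": "0 + block_c"}),
            ),
            ("intercept only", dict(re_formula="~1")),
        ]
        last_exc: Exception | None = None
        for label, kwargs in attempts:
            best = None
            for method in ("lbfgs", "powell"):
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", ConvergenceWarning)
                        warnings.simplefilter("ignore", UserWarning)
                        warnings.simplefilter("ignore", RuntimeWarning)
                        fit = smf.mixedlm(
                            self.formula,
                            self.frame,
                            groups=self.frame["subject_id"],
                            **kwargs,
                        ).fit(reml=reml, method=method, maxiter=2000)
                    ok = (
                        fit.converged
                        and np.all(np.isfinite(fit.params))
                        and np.all(np.isfinite(fit.bse_fe))
                    )
                    if ok and (best is None or fit.llf > best.llf + 1e-6):
                        best = fit
                except Exception as exc:  # noqa: BLE001 - refit ladder
                    logger.warning(
                        "fit_trajectory: '%s' with %s failed (%s)", label, method, exc
                    )
                    last_exc = exc
            if best is not None:
                if label != attempts[0][0]:
                    logger.warning(
                        "fit_trajectory: simplified random structure to '%s'", label
                    )
                return TrajectoryResults(self, best, structure=label)
        raise RuntimeError(f"all random-effect structures failed: {last_exc}")


class TrajectoryResults:
    """Fitted trajectory LMM with effect tables and variance decomposition."""

    def __init__(self, model: LearningTrajectoryModel, fit, structure: str):
        self.model = model
        self._fit = fit
        self.structure = structure
        self.n_obs = int(fit.nobs)
        self.n_subjects = int(model.frame["subject_id"].nunique())

    @property
    def params(self) -> pd.Series:
        return self._fit.fe_params

    def fixed_effects(self, alpha: float = 0.05) -> pd.DataFrame:
        """Per-term table: b, CI, Wald F (= z^2), df and p."""
        fe = self._fit.fe_params
        se = self._fit.bse_fe
        z = fe / se
        crit = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {
                "b": fe,
                "ci_low": fe - crit * se,
                "ci_high": fe + crit * se,
                "F": z**2,
                "df_num": 1,
                "df_den": np.inf,
                "p": 2 * stats.norm.sf(np.abs(z)),
            }
        )

    @property
    def random_effects(self) -> dict:
        """Random-effect variances, intercept-slope correlation, residual."""
        cov_re = self._fit.cov_re
        out = {
            "var_intercept": float(cov_re.iloc[0, 0]) if len(cov_re) else 0.0,
            "var_slope": 0.0,
            "corr_intercept_slope": float("nan"),
            "var_residual": float(self._fit.scale),
        }
        if len(cov_re) > 1:
            out["var_slope"] = float(cov_re.iloc[1, 1])
            denom = np.sqrt(cov_re.iloc[0, 0] * cov_re.iloc[1, 1])
            if denom > 0:
                out["corr_intercept_slope"] = float(cov_re.iloc[0, 1] / denom)
        elif getattr(self._fit, "vcomp", None) is not None and len(self._fit.vcomp):
            out["var_slope"] = float(self._fit.vcomp[0])
            out["corr_intercept_slope"] = 0.0
        return out

    def _variance_components(self) -> dict:
        exog = pd.DataFrame(self._fit.model.exog, columns=self._fit.model.exog_names)
        var_fixed = float(np.var(exog.to_numpy() @ self.params.to_numpy()))
        re = self.random_effects
        bc = self.model.frame["block_c"].to_numpy()
        cov01 = 0.0
        if np.isfinite(re["corr_intercept_slope"]):
            cov01 = re["corr_intercept_slope"] * np.sqrt(
                re["var_intercept"] * re["var_slope"]
            )
        var_random = float(
            re["var_intercept"]
            + 2 * cov01 * bc.mean()
            + re["var_slope"] * np.mean(bc**2)
        )
        return {
            "var_fixed": var_fixed,
            "var_random": var_random,
            "var_residual": re["var_residual"],
        }

    @property
    def r2_marginal(self) -> float:
        v = self._variance_components()
        return v["var_fixed"] / sum(v.values())

    @property
    def r2_conditional(self) -> float:
        v = self._variance_components()
        return (v["var_fixed"] + v["var_random"]) / sum(v.values())

    @property
    def icc_adjusted(self) -> float:
        v = self._variance_components()
        return v["var_random"] / (v["var_random"] + v["var_residual"])

    # -- contrasts ---------------------------------------------------------

    def _linear_combo(self, weights: pd.Series, description: str, alpha: float) -> Contrast:
        fe = self.params
        w = np.array([weights.get(name, 0.0) for name in fe.index])
        est = float(w @ fe.to_numpy())
        cov = self._fit.cov_params().iloc[: len(fe), : len(fe)].to_numpy()
        se = float(np.sqrt(w @ cov @ w))
        crit = stats.norm.ppf(1 - alpha / 2)
        z = est / se if se > 0 else np.inf
        return Contrast(
            description=description,
            estimate=est,
            ci_low=est - crit * se,
            ci_high=est + crit * se,
            p=float(2 * stats.norm.sf(abs(z))),
        )

    def block_slope_at(
        self,
        ef_values: dict[str, float] | None = None,
        triplet: float = 0.0,
        alpha: float = 0.05,
    ) -> Contrast:
        """Model-implied Block slope at given (centred) EF values.

        ``triplet`` may be +1 (high), -1 (low) or 0 (average over types).
        """
        ef_values = ef_values or {}
        unknown = set(ef_values) - set(self.model.ef_names)
        if unknown:
            raise ValueError(
                f"unknown EF term(s) {sorted(unknown)}; available: {self.model.ef_names}"
            )
        weights: dict[str, float] = {}
        for name in self.params.index:
            parts = name.split(":")
            if "block_c" not in parts:
                continue
            others = [t for t in parts if t != "block_c"]
            w = 1.0
            for t in others:
                if t == "triplet":
                    w *= triplet
                else:
                    w *= ef_values.get(t, 0.0)
            weights[name] = w
        desc = (
            f"Block slope at triplet={triplet:+.0f}, "
            + ", ".join(f"{k}={v:.3g}" for k, v in ef_values.items() or {"EF": 0}.items())
        )
        return self._linear_combo(pd.Series(weights), desc, alpha)

    def simple_slopes(
        self,
        ef_name: str,
        at_quantiles: tuple[float, ...] = (0.25, 0.75),
        alpha: float = 0.05,
    ) -> list[Contrast]:
        """Block slopes at sample quantiles of an EF score, plus their
        difference; mirrors percentile-based simple-slope reporting."""
        if ef_name not in self.model.ef_names:
            raise ValueError(
                f"'{ef_name}' not in model; available: {self.model.ef_names}"
            )
        vals = self.model.frame.drop_duplicates("subject_id")[ef_name]
        out = []
        qs = [float(vals.quantile(q)) for q in at_quantiles]
        for q, v in zip(at_quantiles, qs):
            c = self.block_slope_at({ef_name: v}, alpha=alpha)
            out.append(
                Contrast(
                    f"Block slope at {q:.0%} of {ef_name}",
                    c.estimate,
                    c.ci_low,
                    c.ci_high,
                    c.p,
                )
            )
        if len(qs) == 2:
            w = {
                name: ef_coeff
                for name, ef_coeff in (
                    (f"block_c:{ef_name}", qs[1] - qs[0]),
                    (f"{ef_name}:block_c", qs[1] - qs[0]),
                )
                if name in self.params.index
            }
            out.append(
                self._linear_combo(
                    pd.Series(w),
                    f"Block-slope difference between {at_quantiles[1]:.0%} and "
                    f"{at_quantiles[0]:.0%} of {ef_name}",
                    alpha,
                )
            )
        return out

    def triplet_slope_contrast(self, alpha: float = 0.05) -> Contrast:
        """High-vs-low difference in Block slopes (= 2x the
        triplet:block coefficient under +/-1 coding)."""
        name = (
            "triplet:block_c"
            if "triplet:block_c" in self.params.index
            else "block_c:triplet"
        )
        return self._linear_combo(
            pd.Series({name: 2.0}), "Block-slope difference, high - low", alpha
        )

    def summary(self) -> str:
        re = self.random_effects
        lines = [
            f"Learning-trajectory LMM ({self.structure}); "
            f"{self.n_obs} observations, {self.n_subjects} subjects",
            "",
            self.fixed_effects().round(4).to_string(),
            "",
            (
                f"Random effects: var(intercept) = {re['var_intercept']:.2f}, "
                f"var(slope) = {re['var_slope']:.4f}, "
                f"corr = {re['corr_intercept_slope']:.3f}, "
                f"residual = {re['var_residual']:.2f}"
            ),
            (
                f"R2 marginal = {self.r2_marginal:.4f}, "
                f"conditional = {self.r2_conditional:.4f}, "
                f"adjusted ICC = {self.icc_adjusted:.4f}"
            ),
        ]
        return "\n".join(lines)
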