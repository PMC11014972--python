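"""Fixed-effect cumulative meta-analysis of correlation coefficients.

Correlations are pooled on the Fisher-z scale with inverse-variance
weights w_i = n_i - 3. Heterogeneity is summarised by Cochran's Q, I^2 and
a REML estimate of the between-study variance tau^2 (also on the z scale,
floored at zero). The pooled estimate, its confidence interval and the
two-sided normal p value are back-transformed to the r scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["StudyEffect", "MetaResult", "pool_fixed", "heterogeneity", "reml_tau2", "forest_plot"]


@dataclass(frozen=True)
class StudyEffect:
    label: str
    r: float
    n: int

    def __post_init__(self) -> None:
        if not abs(self.r) < 1:
            raise ValueError(f"|r| must be < 1, got {self.r} for {self.label!r}")
        if self.n <= 3:
            raise ValueError(f"need n > 3, got {self.n} for {self.label!r}")

    @property
    def z(self) -> float:
        return float(np.arctanh(self.r))

    @property
    def var_z(self) -> float:
        return 1.0 / (self.n - 3)


@dataclass(frozen=True)
class MetaResult:
    pooled_r: float
    ci_low: float
    ci_high: float
    z_pooled: float
    p: float
    weights_pct: dict[str, float]
    q: float
    df_q: int
    p_q: float
    tau2: float
    i2_pct: float
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return {
            "pooled_r": self.pooled_r,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "z_pooled": self.z_pooled,
            "p": self.p,
            "weights_pct": self.weights_pct,
            "Q": self.q,
            "df_Q": self.df_q,
            "p_Q": self.p_q,
            "tau2": self.tau2,
            "i2_pct": self.i2_pct,
            "alpha": self.alpha,
        }


def _restricted_loglik(tau2: float, z: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / (v + tau2)
    mu = np.sum(w * z) / np.sum(w)
    return float(
        -0.5 * np.sum(np.log(v + tau2))
        - 0.5 * np.log(np.sum(w))
        - 0.5 * np.sum(w * (z - mu) ** 2)
    )


def reml_tau2(effects: list[StudyEffect], max_tau2: float | None = None) -> float:
    """REML estimate of tau^2 on the Fisher-z scale, floored at zero.

    With very few studies the restricted likelihood is often monotone
    decreasing in tau^2; the boundary estimate 0 is then returned.
    """
    if len(effects) < 2:
        raise ValueError("tau^2 requires at least 2 studies")
    z = np.array([e.z for e in effects])
    v = np.array([e.var_z for e in effects])
    hi = max_tau2 if max_tau2 is not None else max(10 * z.var(ddof=0), 10 * v.max(), 1.0)
    res = optimize.minimize_scalar(
        lambda t: -_restricted_loglik(t, z, v), bounds=(0.0, hi), method="bounded",
        options=dict(xatol=1e-12, maxiter=500),
    )
    tau2 = float(res.x)
    # prefer the boundary when the profile is flat/monotone near zero
    if _restricted_loglik(0.0, z, v) >= _restricted_loglik(tau2, z, v) - 1e-12:
        return 0.0
    return tau2


def heterogeneity(effects: list[StudyEffect]) -> dict:
    """Cochran's Q, its df and p, REML tau^2 and I^2 (percent)."""
    if len(effects) < 2:
        return {
            "Q": float("nan"),
            "df": 0,
            "p_Q": float("nan"),
            "tau2": float("nan"),
            "i2_pct": float("nan"),
        }
    z = np.array([e.z for e in effects])
    w = np.array([1.0 / e.var_z for e in effects])
    zbar = np.sum(w * z) / np.sum(w)
    q = float(np.sum(w * (z - zbar) ** 2))
    df = len(effects) - 1
    p_q = float(stats.chi2.sf(q, df))
    i2 = float(max(0.0, (q - df) / q) * 100.0) if q > 0 else 0.0
    return {"Q": q, "df": df, "p_Q": p_q, "tau2": reml_tau2(effects), "i2_pct": i2}


def pool_fixed(effects: list[StudyEffect], alpha: float = 0.05) -> MetaResult:
    """Inverse-variance fixed-effect pooling on the Fisher-z scale."""
    if not effects:
        raise ValueError("no study effects supplied")
    z = np.array([e.z for e in effects])
    w = np.array([1.0 / e.var_z for e in effects])
    z_pooled = float(np.sum(w * z) / np.sum(w))
    se = 1.0 / np.sqrt(np.sum(w))
    crit = stats.norm.ppf(1 - alpha / 2)
    het = heterogeneity(effects)
    return MetaResult(
        pooled_r=float(np.tanh(z_pooled)),
        ci_low=float(np.tanh(z_pooled - crit * se)),
        ci_high=float(np.tanh(z_pooled + crit * se)),
        z_pooled=z_pooled,
        p=float(2 * stats.norm.sf(abs(z_pooled) / se)),
        weights_pct={e.label: float(100.0 * wi / np.sum(w)) for e, wi in zip(effects, w)},
        q=het["Q"],
        df_q=het["df"],
        p_q=het["p_Q"],
        tau2=het["tau2"],
        i2_pct=het["i2_pct"],
        alpha=alpha,
    )


def read_studies_csv(path) -> list[StudyEffect]:
    df = pd.read_csv(path)
    return [StudyEffect(str(r.label), float(r.r), int(r.n)) for r in df.itertuples()]


def forest_plot(effects: list[StudyEffect], result: MetaResult, path) -> None:
    """Minimal forest plot: per-study r with Fisher CIs plus the pooled
    effect as a diamond."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 1.2 + 0.6 * len(effects)))
    crit = stats.norm.ppf(1 - result.alpha / 2)
    for i, e in enumerate(effects):
        half = crit * np.sqrt(e.var_z)
        lo, hi = np.tanh(e.z - half), np.tanh(e.z + half)
        y = len(effects) - i
        ax.plot([lo, hi], [y, y], color="k")
        ax.plot(
            e.r, y, "s", color="k",
            markersize=4 + 8 * result.weights_pct[e.label] / 100.0,
        )
        ax.text(
            1.02, y,
            f"{e.label}: r = {e.r:.3f}, n = {e.n}, w = {result.weights_pct[e.label]:.1f}%",
            transform=ax.get_yaxis_transform(), va="center", fontsize=8,
        )
    ax.fill(
        [result.ci_low, result.pooled_r, result.ci_high, result.pooled_r],
        [0, 0.25, 0, -0.25],
        color="steelblue",
    )
    ax.text(
        1.02, 0,
        f"pooled: r = {result.pooled_r:.3f} [{result.ci_low:.3f}, {result.ci_high:.3f}]",
        transform=ax.get_yaxis_transform(), va="center", fontsize=8,
    )
    ax.axvline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_yticks([])
    ax.set_xlabel("Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
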