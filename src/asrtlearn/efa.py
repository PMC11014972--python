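"""Maximum-likelihood exploratory factor analysis with diagnostics.

Implements the full EFA workflow for a subject-by-measure score table:
factorability diagnostics (per-item MSA, overall KMO, Bartlett's test of
sphericity), factor-count selection by Horn's parallel analysis against a
percentile of eigenvalues from random normal data, ML factor extraction by
profiling the uniquenesses out of the normal-theory discrepancy, varimax
rotation with Kaiser row normalization, chi-square sufficiency test with
Bartlett's correction, RMSEA (with a noncentral chi-square confidence
interval) and SRMR fit indices, and Thomson regression factor scores.

The modelling surface follows the Model/Results idiom:

>>> model = ExploratoryFactorModel(scores)           # doctest: +SKIP
>>> res = model.fit(n_factors=1)                     # doctest: +SKIP
>>> res.loadings, res.rmsea, res.factor_scores()     # doctest: +SKIP
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

PSI_FLOOR = 0.005  # lower bound on uniquenesses; hitting it flags a Heywood case

__all__ = [
    "FactorabilityReport",
    "ParallelAnalysisResult",
    "ExploratoryFactorModel",
    "EFAResults",
    "factorability",
    "parallel_analysis",
    "ml_efa",
    "varimax",
    "thomson_scores",
]


# ---------------------------------------------------------------------------
# factorability diagnostics


@dataclass(frozen=True)
class FactorabilityReport:
    msa_per_item: dict[str, float]
    kmo_overall: float
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float


def _correlation(X: pd.DataFrame) -> tuple[np.ndarray, int]:
    Xc = X.dropna()
    R = np.corrcoef(Xc.to_numpy(dtype=float).T)
    return R, len(Xc)


def factorability(X: pd.DataFrame) -> FactorabilityReport:
    """Per-item MSA, overall KMO and Bartlett's sphericity test.

    The measures of sampling adequacy contrast zero-order correlations r
    with partial correlations q obtained from the inverse correlation
    matrix: MSA_j = sum r^2 / (sum r^2 + sum q^2) over pairs involving j,
    and the overall KMO is the same ratio over all pairs. Bartlett's
    statistic is -(n - 1 - (2p + 5)/6) ln|R| on p(p-1)/2 df.
    """
    R, n = _correlation(X)
    p = R.shape[0]
    if n <= p:
        raise ValueError(f"need more observations ({n}) than measures ({p})")
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0 or not np.isfinite(logdet):
        raise ValueError(
            "correlation matrix is singular; consider removing collinear "
            "measures or adding a small ridge"
        )
    Rinv = np.linalg.inv(R)
    d = 1.0 / np.sqrt(np.diag(Rinv))
    Q = -Rinv * np.outer(d, d)  # partial correlations (off-diagonal)
    off = ~np.eye(p, dtype=bool)
    r2 = (R**2)[off].reshape(p, p - 1)
    q2 = (Q**2)[off].reshape(p, p - 1)
    msa = r2.sum(axis=1) / (r2.sum(axis=1) + q2.sum(axis=1))
    kmo = r2.sum() / (r2.sum() + q2.sum())
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    pval = float(stats.chi2.sf(chi2, df))
    return FactorabilityReport(
        msa_per_item=dict(zip(X.columns, msa.astype(float))),
        kmo_overall=float(kmo),
        bartlett_chi2=float(chi2),
        bartlett_df=df,
        bartlett_p=pval,
    )


# ---------------------------------------------------------------------------
# parallel analysis


@dataclass(frozen=True)
class ParallelAnalysisResult:
    observed_eigenvalues: np.ndarray
    simulated_percentiles: np.ndarray
    percentile: float
    n_sims: int
    n_factors: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": np.arange(1, len(self.observed_eigenvalues) + 1),
                "observed_eigenvalue": self.observed_eigenvalues,
                "simulated_percentile": self.simulated_percentiles,
                "retained": np.arange(len(self.observed_eigenvalues)) < self.n_factors,
            }
        )


def parallel_analysis(
    X: pd.DataFrame,
    n_sims: int = 1000,
    percentile: float = 95.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> ParallelAnalysisResult:
    """Horn's parallel analysis with a percentile criterion.

    Eigenvalues of the Pearson correlation matrix of the observed data are
    compared position-by-position with the chosen percentile of eigenvalues
    from ``n_sims`` standard-normal datasets of identical shape; the number
    of factors retained is the longest prefix of observed eigenvalues that
    exceed their simulated percentile.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    Xc = X.dropna()
    n, p = Xc.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than measures ({p})")
    obs = np.sort(np.linalg.eigvalsh(np.corrcoef(Xc.to_numpy(dtype=float).T)))[::-1]
    sims = np.empty((n_sims, p))
    for s in range(n_sims):
        Z = rng.standard_normal((n, p))
        sims[s] = np.sort(np.linalg.eigvalsh(np.corrcoef(Z.T)))[::-1]
    thresholds = np.percentile(sims, percentile, axis=0)
    k = 0
    for o, t in zip(obs, thresholds):
        if o > t:
            k += 1
        else:
            break
    return ParallelAnalysisResult(
        observed_eigenvalues=obs,
        simulated_percentiles=thresholds,
        percentile=percentile,
        n_sims=n_sims,
        n_factors=k,
    )


# ---------------------------------------------------------------------------
# varimax rotation


def varimax(
    loadings: np.ndarray,
    normalize: bool = True,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> np.ndarray:
    """Orthogonal varimax rotation (Kaiser row-normalized by default).

    Communalities are preserved exactly. Column signs are fixed so that
    each factor's largest-|loading| entry is positive, and columns are
    ordered by explained variance.
    """
    L = np.asarray(loadings, dtype=float)
    p, k = L.shape
    if k > 1:
        h = np.sqrt((L**2).sum(axis=1)) if normalize else np.ones(p)
        h = np.where(h == 0, 1.0, h)
        A = L / h[:, None]
        T = np.eye(k)
        var_old = 0.0
        for _ in range(max_iter):
            B = A @ T
            U, s, Vt = np.linalg.svd(
                A.T @ (B**3 - B @ np.diag((B**2).sum(axis=0)) / p)
            )
            T = U @ Vt
            var_new = s.sum()
            if var_new - var_old < tol:
                break
            var_old = var_new
        L = (A @ T) * h[:, None]
    # canonical column order and signs
    order = np.argsort(-(L**2).sum(axis=0), kind="stable")
    L = L[:, order]
    signs = np.sign(L[np.abs(L).argmax(axis=0), np.arange(L.shape[1])])
    signs = np.where(signs == 0, 1.0, signs)
    return L * signs


# ---------------------------------------------------------------------------
# ML EFA


def _ml_discrepancy(logpsi: np.ndarray, R: np.ndarray, k: int) -> float:
    """Profile ML discrepancy as a function of log-uniquenesses.

    With loadings profiled out, F(psi) = sum over the p-k smallest
    eigenvalues theta_j of psi^-1/2 R psi^-1/2 of (theta_j - ln theta_j - 1),
    which equals ln|Sigma| + tr(R Sigma^-1) - ln|R| - p at the conditional
    optimum (Lawley-Maxwell).
    """
    psi = np.exp(logpsi)
    d = 1.0 / np.sqrt(psi)
    Rs = R * np.outer(d, d)
    vals = np.sort(np.linalg.eigvalsh(Rs))[::-1]
    tail = np.maximum(vals[k:], 1e-12)
    return float(np.sum(tail - np.log(tail) - 1.0))


@dataclass
class EFAResults:
    """Fitted ML EFA: loadings, uniquenesses and fit statistics."""

    model: "ExploratoryFactorModel"
    n_factors: int
    loadings: pd.DataFrame
    uniquenesses: pd.Series
    discrepancy: float
    converged: bool
    heywood: bool
    n_obs: int

    chi2: float = field(init=False)
    df: int = field(init=False)
    p_value: float = field(init=False)
    rmsea: float = field(init=False)
    rmsea_ci: tuple[float, float] = field(init=False)
    srmr: float = field(init=False)

    def __post_init__(self) -> None:
        p, k, n = len(self.uniquenesses), self.n_factors, self.n_obs
        self.df = ((p - k) ** 2 - (p + k)) // 2
        correction = n - 1 - (2 * p + 5) / 6.0 - 2 * k / 3.0
        self.chi2 = float(max(correction * self.discrepancy, 0.0))
        self.p_value = (
            float(stats.chi2.sf(self.chi2, self.df)) if self.df > 0 else float("nan")
        )
        self.rmsea, self.rmsea_ci = _rmsea(self.chi2, self.df, n)
        self.srmr = _srmr(self.model.corr, self.sigma_hat)

    @property
    def communalities(self) -> pd.Series:
        return (self.loadings**2).sum(axis=1).rename("communality")

    @property
    def variance_explained(self) -> pd.Series:
        """Proportion of total variance explained per factor."""
        p = self.loadings.shape[0]
        return ((self.loadings**2).sum(axis=0) / p).rename("variance_explained")

    @property
    def sigma_hat(self) -> np.ndarray:
        L = self.loadings.to_numpy()
        return L @ L.T + np.diag(self.uniquenesses.to_numpy())

    def factor_scores(self, X: pd.DataFrame | None = None) -> pd.DataFrame:
        """Thomson regression factor scores (weights R^-1 Lambda)."""
        X = self.model.data if X is None else X
        return thomson_scores(X, self)

    def summary(self) -> str:
        lines = [
            f"ML exploratory factor analysis ({self.n_factors} factor(s), "
            f"n = {self.n_obs})",
            "",
            pd.concat([self.loadings, self.communalities], axis=1).round(3).to_string(),
            "",
            "Variance explained: "
            + ", ".join(
                f"{k}: {v:.1%}" for k, v in self.variance_explained.items()
            ),
            f"Sufficiency test: chi2({self.df}) = {self.chi2:.3f}, p = {self.p_value:.3g}",
            f"RMSEA = {self.rmsea:.3f}, 90% CI = [{self.rmsea_ci[0]:.3f}, "
            f"{self.rmsea_ci[1]:.3f}]; SRMR = {self.srmr:.3f}",
        ]
        if self.heywood:
            lines.append(f"Warning: Heywood case (uniqueness at floor {PSI_FLOOR})")
        return "\n".join(lines)


class ExploratoryFactorModel:
    """ML EFA model for a subject-by-measure table.

    Accepts either raw data (``ExploratoryFactorModel(X)``) or a
    correlation matrix with an explicit sample size
    (``ExploratoryFactorModel.from_correlation(R, n_obs, names)``).
    """

    def __init__(self, data: pd.DataFrame):
        data = data.dropna()
        if data.shape[0] <= data.shape[1]:
            raise ValueError(
                f"need more observations ({data.shape[0]}) than measures "
                f"({data.shape[1]})"
            )
        self.data = data
        self.names = list(data.columns)
        self.corr = np.corrcoef(data.to_numpy(dtype=float).T)
        self.n_obs = len(data)

    @classmethod
    def from_correlation(
        cls, R: np.ndarray, n_obs: int, names: list[str] | None = None
    ) -> "ExploratoryFactorModel":
        obj = cls.__new__(cls)
        obj.data = None
        obj.corr = np.asarray(R, dtype=float)
        obj.n_obs = int(n_obs)
        obj.names = names or [f"x{i+1}" for i in range(obj.corr.shape[0])]
        return obj

    def fit(
        self,
        n_factors: int,
        rotate: bool = True,
        max_iter: int = 2000,
    ) -> EFAResults:
        """Fit the k-factor model by profile maximum likelihood."""
        R, p, k = self.corr, self.corr.shape[0], int(n_factors)
        if k < 1:
            raise ValueError("n_factors must be >= 1")
        df = ((p - k) ** 2 - (p + k)) // 2
        if df < 0:
            raise ValueError(
                f"{k} factors for {p} measures gives negative degrees of "
                f"freedom ({df}); reduce n_factors"
            )
        smc = 1.0 - 1.0 / np.diag(np.linalg.inv(R))
        x0 = np.log(np.clip(1.0 - smc, 2 * PSI_FLOOR, 1.0))
        res = optimize.minimize(
            _ml_discrepancy,
            x0,
            args=(R, k),
            method="L-BFGS-B",
            bounds=[(np.log(PSI_FLOOR), 0.0)] * p,
            options=dict(maxiter=max_iter, ftol=1e-14, gtol=1e-10),
        )
        if not res.success and res.fun > 1e-8:
            # line-search failures happen near the uniqueness bounds on
            # ill-conditioned small-sample matrices; retry derivative-free
            retry = optimize.minimize(
                _ml_discrepancy,
                res.x,
                args=(R, k),
                method="Powell",
                bounds=[(np.log(PSI_FLOOR), 0.0)] * p,
                options=dict(maxiter=20 * max_iter, xtol=1e-10, ftol=1e-12),
            )
            if retry.fun <= res.fun:
                res = retry
            if not res.success and res.fun > 1e-8:
                raise RuntimeError(
                    f"ML EFA did not converge after {res.nit} iterations: {res.message}"
                )
        psi = np.exp(res.x)
        heywood = bool(np.any(psi <= PSI_FLOOR * (1 + 1e-6)))
        if heywood:
            logger.warning(
                "Heywood case: %d uniqueness(es) bounded at %.3f",
                int(np.sum(psi <= PSI_FLOOR * (1 + 1e-6))),
                PSI_FLOOR,
            )
        d = 1.0 / np.sqrt(psi)
        vals, vecs = np.linalg.eigh(R * np.outer(d, d))
        idx = np.argsort(vals)[::-1][:k]
        theta, V = vals[idx], vecs[:, idx]
        L = np.sqrt(psi)[:, None] * V * np.sqrt(np.maximum(theta - 1.0, 0.0))
        L = varimax(L) if (rotate and k > 1) else varimax(L, normalize=False, max_iter=0)
        return EFAResults(
            model=self,
            n_factors=k,
            loadings=pd.DataFrame(
                L, index=self.names, columns=[f"F{i+1}" for i in range(k)]
            ),
            uniquenesses=pd.Series(psi, index=self.names, name="uniqueness"),
            discrepancy=float(res.fun),
            converged=bool(res.success),
            heywood=heywood,
            n_obs=self.n_obs,
        )


def ml_efa(X: pd.DataFrame, n_factors: int, rotate: bool = True) -> EFAResults:
    """Functional wrapper around :class:`ExploratoryFactorModel`."""
    return ExploratoryFactorModel(X).fit(n_factors, rotate=rotate)


# ---------------------------------------------------------------------------
# fit indices


def _rmsea(
    chi2: float, df: int, n: int, level: float = 0.90
) -> tuple[float, tuple[float, float]]:
    """RMSEA point estimate and noncentral-chi-square confidence interval."""
    if df <= 0:
        return float("nan"), (float("nan"), float("nan"))
    point = float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))))
    lo_q, hi_q = (1 + level) / 2.0, (1 - level) / 2.0

    def bound(target: float) -> float:
        # noncentrality nc with P(X2_{df,nc} <= chi2) = target
        f = lambda nc: stats.ncx2.cdf(chi2, df, nc) - target
        if f(0.0) < 0:
            return 0.0
        hi = max(chi2, 1.0)
        while f(hi) > 0:
            hi *= 2
            if hi > 1e8:
                break
        nc = optimize.brentq(f, 0.0, hi)
        return float(np.sqrt(nc / (df * (n - 1))))

    return point, (bound(lo_q), bound(hi_q))


def _srmr(R: np.ndarray, sigma_hat: np.ndarray) -> float:
    """Root mean square of the off-diagonal standardized residuals."""
    p = R.shape[0]
    off = np.triu_indices(p, k=1)
    resid = (R - sigma_hat)[off]
    return float(np.sqrt(np.mean(resid**2)))


# ---------------------------------------------------------------------------
# factor scores


def thomson_scores(X: pd.DataFrame, results: EFAResults) -> pd.DataFrame:
    """Thomson (regression-method) factor scores: Z R^-1 Lambda.

    Subjects with any missing measure are dropped with a warning. Scores
    are computed on data standardized with the sample mean and SD.
    """
    cols = list(results.loadings.index)
    missing = [c for c in cols if c not in X.columns]
    if missing:
        raise ValueError(f"data lacks measures: {missing}")
    Xs = X[cols]
    complete = Xs.dropna()
    if len(complete) < len(Xs):
        logger.warning(
            "thomson_scores: dropping %d subject(s) with missing measures",
            len(Xs) - len(complete),
        )
    Z = (complete - complete.mean()) / complete.std(ddof=1)
    R = results.model.corr
    W = np.linalg.solve(R, results.loadings.to_numpy())
    scores = Z.to_numpy() @ W
    return pd.DataFrame(scores, index=complete.index, columns=results.loadings.columns)
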