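"""Synthetic ASRT cohorts with known ground-truth effects.

Generates trial-level ASRT performance and per-subject executive-function
(EF) score tables whose generating parameters mirror the structure of a
two-study design: block-wise general skill learning (overall RT decrease),
a statistical-learning (SL) gap between high- and low-probability triplets
that grows over blocks, correlated subject-specific intercepts and block
slopes, a latent factor structure over EF measures, and a configurable
negative correlation between the latent EF factor and the subject SL
effect. Everything is reproducible under a single seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .design import (
    BLOCK_LENGTH,
    N_WARMUP,
    PatternSequence,
    make_pattern,
)

__all__ = [
    "CohortConfig",
    "SubjectProfile",
    "LOADING_TEMPLATES",
    "MEASURE_SCALES",
    "study1_config",
    "study2_config",
    "simulate_profiles",
    "simulate_trials",
    "simulate_ef_scores",
    "simulate_cohort",
]

# Varimax loading templates for the two EF batteries. Rows are measures,
# columns latent factors. Study-1-like: nine measures, one factor dominated
# by verbal fluency and counting span. Study-2-like: five measures, two
# factors separating fluency from short-term memory span.
LOADING_TEMPLATES: dict[str, pd.DataFrame] = {
    "STUDY1": pd.DataFrame(
        {"F1": [-0.03, 0.01, -0.11, 0.08, 0.31, 0.01, 0.60, 0.54, 0.82]},
        index=[
            "ant_alerting",
            "ant_orienting",
            "ant_executive",
            "bcst",
            "cspan",
            "gng",
            "lexical_fluency",
            "semantic_fluency",
            "action_fluency",
        ],
    ),
    "STUDY2": pd.DataFrame(
        {
            "F1": [0.03, 0.28, 0.08, 0.33, 0.88],
            "F2": [0.32, 0.52, 0.54, 0.23, 0.03],
        },
        index=["cspan", "dspan", "corsi", "lexical_fluency", "semantic_fluency"],
    ),
}

# Plausible task units (mean, sd) used to rescale standardized EF scores.
MEASURE_SCALES: dict[str, tuple[float, float]] = {
    "ant_alerting": (40.0, 25.0),
    "ant_orienting": (45.0, 28.0),
    "ant_executive": (100.0, 40.0),
    "bcst": (85.0, 8.0),
    "cspan": (4.2, 0.9),
    "gng": (2.8, 0.8),
    "lexical_fluency": (21.0, 6.0),
    "semantic_fluency": (31.0, 7.5),
    "action_fluency": (23.0, 6.5),
    "dspan": (6.1, 1.1),
    "corsi": (5.8, 1.0),
}


@dataclass
class CohortConfig:
    """Generating parameters for one synthetic study cohort.

    The SL gap enters symmetrically: the expected RT on a trial ending a
    high-probability triplet is the grand trajectory minus half the current
    gap, and plus half the gap for low-probability endings, so a trajectory
    mixed model with ±1 triplet coding recovers −gap/2 as the triplet
    coefficient.
    """

    n_subjects: int = 186
    n_blocks: int = 25
    base_rt: float = 366.0          # ms, grand mean RT at the centred block
    skill_slope: float = -0.31      # ms per block, general skill learning
    sl_effect_mean: float = 3.0     # ms, mean low-high gap at the centred block
    sl_effect_sd: float = 10.0      # ms, between-subject SD of the gap
    sl_block_slope: float = 0.14    # ms per block, growth of the gap
    ef_sl_corr: float = -0.15       # latent EF factor <-> subject SL effect
    loading_template: str = "STUDY1"
    rt_noise_sd: float = 80.0       # ms, trial-level residual SD
    error_rate: float = 0.05        # probability a response is incorrect
    fast_guess_rate: float = 0.002  # probability of an RT < 100 ms contaminant
    sd_intercept: float = 40.0      # ms, random intercept SD
    sd_slope: float = 0.5           # ms/block, random block-slope SD
    intercept_slope_corr: float = -0.3
    pattern_order: tuple[int, int, int, int] = (4, 2, 3, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("error_rate", "fast_guess_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_blocks < 1:
            raise ValueError(f"n_blocks must be >= 1, got {self.n_blocks}")
        if self.n_subjects < 1:
            raise ValueError(f"n_subjects must be >= 1, got {self.n_subjects}")
        if not abs(self.ef_sl_corr) < 1:
            raise ValueError(f"|ef_sl_corr| must be < 1, got {self.ef_sl_corr}")
        if not abs(self.intercept_slope_corr) < 1:
            raise ValueError(
                f"|intercept_slope_corr| must be < 1, got {self.intercept_slope_corr}"
            )
        if self.loading_template not in LOADING_TEMPLATES:
            raise ValueError(
                f"loading_template must be one of {sorted(LOADING_TEMPLATES)}, "
                f"got {self.loading_template!r}"
            )

    def to_dict(self) -> dict:
        return asdict(self)


def study1_config(**overrides) -> CohortConfig:
    """Study-1-like conditions: 186 subjects, 25 blocks, ~3 ms gap."""
    base = dict(
        n_subjects=186, n_blocks=25, base_rt=366.0, skill_slope=-0.31,
        sl_effect_mean=3.0, sl_block_slope=0.14, loading_template="STUDY1",
    )
    base.update(overrides)
    return CohortConfig(**base)


def study2_config(**overrides) -> CohortConfig:
    """Study-2-like conditions: 157 subjects, 45 blocks, ~12.5 ms gap."""
    base = dict(
        n_subjects=157, n_blocks=45, base_rt=378.0, skill_slope=-1.12,
        sl_effect_mean=12.5, sl_block_slope=0.33, loading_template="STUDY2",
    )
    base.update(overrides)
    return CohortConfig(**base)


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: int
    u0: float       # intercept deviation, ms
    u1: float       # block-slope deviation, ms/block
    delta_s: float  # subject SL effect (low-high gap), ms
    f: np.ndarray   # latent EF factor value(s), z-units


def simulate_profiles(
    config: CohortConfig, rng: np.random.Generator
) -> list[SubjectProfile]:
    """Draw subject profiles.

    The first latent factor and the subject SL effect are jointly Gaussian
    with population correlation ``ef_sl_corr`` by construction; any further
    factors are independent standard normal.
    """
    n = config.n_subjects
    k = LOADING_TEMPLATES[config.loading_template].shape[1]
    f = rng.standard_normal((n, k))
    rho = config.ef_sl_corr
    eps = rng.standard_normal(n)
    delta_s = (
        config.sl_effect_mean
        + rho * config.sl_effect_sd * f[:, 0]
        + np.sqrt(1.0 - rho**2) * config.sl_effect_sd * eps
    )
    r = config.intercept_slope_corr
    cov = np.array(
        [
            [config.sd_intercept**2, r * config.sd_intercept * config.sd_slope],
            [r * config.sd_intercept * config.sd_slope, config.sd_slope**2],
        ]
    )
    if np.linalg.eigvalsh(cov).min() < 0:
        raise ValueError("random-effect covariance is not positive semidefinite")
    u = rng.multivariate_normal(np.zeros(2), cov, size=n)
    return [
        SubjectProfile(subject_id=i + 1, u0=u[i, 0], u1=u[i, 1], delta_s=delta_s[i], f=f[i])
        for i in range(n)
    ]


def _block_positions(
    pattern: PatternSequence, n_blocks: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised positions and roles for ``n_blocks`` consecutive blocks.

    Returns (positions, is_warmup) each of shape (n_blocks, BLOCK_LENGTH).
    """
    pos = np.empty((n_blocks, BLOCK_LENGTH), dtype=np.int64)
    pos[:, :N_WARMUP] = rng.integers(1, 5, size=(n_blocks, N_WARMUP))
    n_pairs = (BLOCK_LENGTH - N_WARMUP) // 2
    pattern_stream = np.tile(np.asarray(pattern.order), n_pairs // 4 + 1)[:n_pairs]
    pos[:, N_WARMUP::2] = pattern_stream[None, :]
    pos[:, N_WARMUP + 1 :: 2] = rng.integers(1, 5, size=(n_blocks, n_pairs))
    warm = np.zeros((n_blocks, BLOCK_LENGTH), dtype=bool)
    warm[:, :N_WARMUP] = True
    return pos, warm


def simulate_trials(
    profiles: list[SubjectProfile],
    config: CohortConfig,
    rng: np.random.Generator,
    pattern: PatternSequence | None = None,
) -> pd.DataFrame:
    """Simulate the trial-level RT stream for every subject.

    The expected RT of a trial that completes a triplet is::

        base_rt + u0 + (skill_slope + u1) * (block - centre)
                -/+ [delta_s + sl_block_slope * (block - centre)] / 2

    with ``-`` for high-probability and ``+`` for low-probability triplet
    endings; trials with no complete triplet sit on the grand trajectory.
    Gaussian trial noise is added, a fraction ``error_rate`` of trials is
    marked incorrect, and a fraction ``fast_guess_rate`` has its RT replaced
    by a Uniform(30, 99) ms fast guess.
    """
    if pattern is None:
        pattern = make_pattern(config.pattern_order)
    succ = np.zeros(5, dtype=np.int64)
    for a, b in pattern.succ.items():
        succ[a] = b

    n_blocks = config.n_blocks
    centre = (1 + n_blocks) / 2.0
    frames = []
    for prof in profiles:
        pos, warm = _block_positions(pattern, n_blocks, rng)
        x = np.full_like(pos, -1)
        y = np.full_like(pos, -1)
        x[:, 2:] = pos[:, :-2]
        y[:, 2:] = pos[:, 1:-1]
        has_triplet = x > 0
        is_high = has_triplet & (succ[np.where(x > 0, x, 1)] == pos)

        blocks = np.arange(1, n_blocks + 1)[:, None]
        bc = blocks - centre
        gap = prof.delta_s + config.sl_block_slope * bc
        mean_rt = (
            config.base_rt
            + prof.u0
            + (config.skill_slope + prof.u1) * bc
            + np.where(has_triplet, np.where(is_high, -gap / 2.0, gap / 2.0), 0.0)
        )
        rt = mean_rt + rng.normal(0.0, config.rt_noise_sd, size=pos.shape)
        rt = np.maximum(rt, 1.0)
        correct = rng.random(pos.shape) >= config.error_rate
        fast = rng.random(pos.shape) < config.fast_guess_rate
        rt = np.where(fast, rng.uniform(30.0, 99.0, size=pos.shape), rt)

        frames.append(
            pd.DataFrame(
                {
                    "subject_id": prof.subject_id,
                    "block": np.repeat(blocks.ravel(), BLOCK_LENGTH),
                    "index_in_block": np.tile(
                        np.arange(1, BLOCK_LENGTH + 1), n_blocks
                    ),
                    "role": np.where(
                        warm.ravel(),
                        "WARMUP",
                        np.where(
                            np.tile(np.arange(BLOCK_LENGTH) % 2 == 1, n_blocks),
                            "PATTERN",
                            "RANDOM",
                        ),
                    ),
                    "position": pos.ravel(),
                    "correct": correct.ravel(),
                    "rt_ms": rt.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_ef_scores(
    profiles: list[SubjectProfile],
    loading_template: str | pd.DataFrame,
    rng: np.random.Generator,
    scales: Mapping[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """EF score table (one column per measure) from the latent factors.

    Standardized measure j is ``x_j = sum_k lambda_jk f_k + sqrt(1 - sum_k
    lambda_jk^2) eps``, then affinely rescaled to plausible task units.
    """
    if isinstance(loading_template, str):
        L = LOADING_TEMPLATES[loading_template]
    else:
        L = loading_template
    lam = L.to_numpy(dtype=float)
    if np.any(np.abs(lam) >= 1):
        raise ValueError("template loadings must lie in (-1, 1)")
    uniq = 1.0 - (lam**2).sum(axis=1)
    if np.any(uniq <= 0):
        bad = L.index[uniq <= 0].tolist()
        raise ValueError(f"rows with sum of squared loadings >= 1: {bad}")
    scales = MEASURE_SCALES if scales is None else scales
    f = np.vstack([p.f for p in profiles])
    if f.shape[1] != lam.shape[1]:
        raise ValueError(
            f"profiles carry {f.shape[1]} factor(s) but template has {lam.shape[1]}"
        )
    z = f @ lam.T + rng.standard_normal((len(profiles), lam.shape[0])) * np.sqrt(uniq)
    data = {"subject_id": [p.subject_id for p in profiles]}
    for j, name in enumerate(L.index):
        mu, sd = scales.get(name, (0.0, 1.0))
        data[name] = mu + sd * z[:, j]
    return pd.DataFrame(data)


def simulate_cohort(
    config: CohortConfig, seed: int | None = None
) -> tuple[list[SubjectProfile], pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: profiles, trial table and EF table in one call."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    profiles = simulate_profiles(config, rng)
    trials = simulate_trials(profiles, config, rng)
    ef = simulate_ef_scores(profiles, config.loading_template, rng)
    return profiles, trials, ef
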