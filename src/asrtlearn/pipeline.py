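"""End-to-end orchestration: simulate -> score -> EFA -> LMM -> correlations
-> meta-analysis, with per-stage artifacts and a reproduction report.

Stages run in dependency order and any failure halts with a stage-tagged
error. All randomness derives from one global seed; a rerun with the same
configuration writes byte-identical JSON artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import correlation, efa, io, meta, scoring, trajectories
from .cohort import (
    CohortConfig,
    simulate_cohort,
    study1_config,
    study2_config,
)
from .design import make_pattern

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "StageError", "run_all", "run_study", "load_config"]

DEFAULT_KAPPA_GRID = (0.25, 0.5, 0.75, 1.0, 1.5, 2.0)


class StageError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class RunConfig:
    studies: dict[str, CohortConfig] = field(
        default_factory=lambda: {"study1": study1_config(), "study2": study2_config()}
    )
    stages: tuple[str, ...] = ("simulate", "score", "efa", "lmm", "correlate", "meta")
    alpha: float = 0.05
    pa_sims: int = 1000
    kappa_grid: tuple[float, ...] = DEFAULT_KAPPA_GRID
    out_dir: str = "asrtlearn_run"
    seed: int = 0
    make_plots: bool = True


_COHORT_FIELDS = {f.name: f.type for f in dataclasses.fields(CohortConfig)}


def load_config(path) -> RunConfig:
    """Parse a key/value text config.

    Lines are ``key = value``; keys of the form ``study1.n_blocks`` set
    cohort fields, bare keys set run-level fields. '#' starts a comment.
    """
    run_kwargs: dict = {}
    study_over: dict[str, dict] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"config line is not 'key = value': {raw!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        if "." in key:
            study, fieldname = key.split(".", 1)
            if fieldname not in _COHORT_FIELDS:
                raise ValueError(f"unknown cohort field {fieldname!r} in {raw!r}")
            study_over.setdefault(study, {})[fieldname] = _coerce(value)
        else:
            run_kwargs[key] = _coerce(value)
    cfg = RunConfig(**{k: v for k, v in run_kwargs.items() if k in RunConfig.__dataclass_fields__})
    for study, over in study_over.items():
        base = study2_config if study == "study2" else study1_config
        cfg.studies[study] = base(**over)
    return cfg


def _coerce(value: str):
    text = value.strip().strip("\"'")
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            pass
    if text.lower() in {"true", "false"}:
        return text.lower() == "true"
    if "," in text:
        return tuple(_coerce(v) for v in text.split(","))
    return text


def run_study(
    name: str,
    config: CohortConfig,
    run: RunConfig,
    out: Path,
    seed: int,
) -> dict:
    """Run the full chain on one synthetic cohort; returns the stage summary."""
    report: dict = {"name": name, "seed": seed, "config": config.to_dict()}
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    def stage_enabled(s: str) -> bool:
        return s in run.stages

    def require(s: str) -> None:
        if not stage_enabled(s):
            raise StageError(s, RuntimeError(f"stage '{s}' is disabled but required downstream"))

    # simulate ------------------------------------------------------------
    require("simulate")
    try:
        profiles, trials, ef_table = simulate_cohort(config, seed=seed)
        io.write_trials(trials, out / "trials.csv")
        ef_table.to_csv(out / "ef_scores.csv", index=False)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("simulate", exc) from exc
    report["simulate"] = {
        "n_subjects": len(profiles),
        "n_trials": int(len(trials)),
        "true_mean_gap_ms": float(np.mean([p.delta_s for p in profiles])),
    }

    # score ---------------------------------------------------------------
    require("score")
    try:
        pattern = make_pattern(config.pattern_order)
        annotated = scoring.annotate(trials, pattern)
        excl = scoring.exclusion_report(annotated)
        block_scores = scoring.block_medians(annotated)
        io.write_block_scores(block_scores, out / "block_scores.csv")
        io.write_json(excl, out / "exclusion_report.json")
        subject_scores = scoring.subject_learning_score(block_scores)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("score", exc) from exc
    report["score"] = {
        "percent_excluded": excl["percent_excluded"],
        "mean_learning_score_ms": float(subject_scores.mean()),
    }

    # efa -----------------------------------------------------------------
    if stage_enabled("efa"):
        try:
            measures = ef_table.drop(columns="subject_id")
            fact = efa.factorability(measures)
            pa = efa.parallel_analysis(
                measures, n_sims=run.pa_sims, rng=np.random.default_rng(seed + 1)
            )
            k = max(pa.n_factors, 1)
            res = efa.ml_efa(measures, k)
            fscores = res.factor_scores(measures)
            fscores.insert(0, "subject_id", ef_table["subject_id"].to_numpy()[fscores.index])
            pd.concat([res.loadings, res.communalities], axis=1).to_csv(out / "loadings.csv")
            io.write_json(dataclasses.asdict(fact), out / "factorability.json")
            pa.to_frame().to_csv(out / "parallel_analysis.csv", index=False)
            fscores.to_csv(out / "factor_scores.csv", index=False)
        except StageError:
            raise
        except Exception as exc:
            raise StageError("efa", exc) from exc
        report["efa"] = {
            "kmo": fact.kmo_overall,
            "bartlett_chi2": fact.bartlett_chi2,
            "bartlett_df": fact.bartlett_df,
            "n_factors_parallel": pa.n_factors,
            "n_factors_fit": k,
            "chi2": res.chi2,
            "df": res.df,
            "p": res.p_value,
            "rmsea": res.rmsea,
            "srmr": res.srmr,
        }
    else:
        fscores = None

    # lmm -----------------------------------------------------------------
    if stage_enabled("lmm"):
        require("efa")
        try:
            model = trajectories.LearningTrajectoryModel.from_scores(
                block_scores, fscores
            )
            fit = model.fit()
            fe = fit.fixed_effects(alpha=run.alpha)
            fe.to_csv(out / "fixed_effects.csv")
            io.write_json(
                {
                    "random_effects": fit.random_effects,
                    "r2_marginal": fit.r2_marginal,
                    "r2_conditional": fit.r2_conditional,
                    "icc_adjusted": fit.icc_adjusted,
                    "structure": fit.structure,
                    "n_obs": fit.n_obs,
                    "n_subjects": fit.n_subjects,
                },
                out / "lmm_random_effects.json",
            )
        except StageError:
            raise
        except Exception as exc:
            raise StageError("lmm", exc) from exc
        report["lmm"] = {
            "b_triplet": float(fe.loc["triplet", "b"]),
            "b_block": float(fe.loc["block_c", "b"]),
            "r2_marginal": fit.r2_marginal,
            "r2_conditional": fit.r2_conditional,
        }

    # correlate -----------------------------------------------------------
    if stage_enabled("correlate"):
        require("efa")
        try:
            merged = fscores.merge(
                subject_scores.reset_index(), on="subject_id", how="inner"
            )
            corr_report = {}
            for factor in [c for c in fscores.columns if c != "subject_id"]:
                pear = correlation.correlate(
                    merged[factor], merged["learning_score"], "pearson", run.alpha
                )
                spear = correlation.correlate(
                    merged[factor], merged["learning_score"], "spearman", run.alpha
                )
                bf = correlation.bf_correlation(pear.r, pear.n, kappa=1.0, side="negative")
                curve = correlation.robustness_curve(
                    pear.r, pear.n, run.kappa_grid, side="negative"
                )
                curve.to_csv(out / f"bf_robustness_{factor}.csv", index=False)
                corr_report[factor] = {
                    "pearson": dataclasses.asdict(pear),
                    "spearman": dataclasses.asdict(spear),
                    "bf_negative": dataclasses.asdict(bf),
                }
            io.write_json(corr_report, out / "correlations.json")
        except StageError:
            raise
        except Exception as exc:
            raise StageError("correlate", exc) from exc
        first = corr_report[sorted(corr_report)[0]]
        report["correlate"] = {
            "r_f1": first["pearson"]["r"],
            "p_f1": first["pearson"]["p"],
            "bf_f1": first["bf_negative"]["bf"],
        }
        report["_effect"] = {
            "r": first["pearson"]["r"],
            "n": first["pearson"]["n"],
        }

    report["_wall_clock_s"] = time.time() - t0
    return report


def run_all(config: RunConfig) -> dict:
    """Execute all configured stages for every study, then pool."""
    out_root = Path(config.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "seed": config.seed,
        "stages": list(config.stages),
        "studies": {},
    }
    effects = []
    timings: dict[str, float] = {}
    for i, (name, cohort_cfg) in enumerate(sorted(config.studies.items())):
        study_report = run_study(
            name, cohort_cfg, config, out_root / name, seed=config.seed + 1000 * i
        )
        eff = study_report.pop("_effect", None)
        timings[name] = study_report.pop("_wall_clock_s", float("nan"))
        report["studies"][name] = study_report
        if eff is not None:
            effects.append(meta.StudyEffect(label=name, r=eff["r"], n=eff["n"]))

    if "meta" in config.stages:
        if "correlate" not in config.stages:
            raise StageError(
                "meta", RuntimeError("stage 'correlate' is disabled but required")
            )
        try:
            pooled = meta.pool_fixed(effects, alpha=config.alpha)
            io.write_json(pooled.to_dict(), out_root / "meta_result.json")
            if config.make_plots:
                meta.forest_plot(effects, pooled, out_root / "forest.png")
        except StageError:
            raise
        except Exception as exc:
            raise StageError("meta", exc) from exc
        report["meta"] = pooled.to_dict()

    # timings are the one nondeterministic quantity: kept out of the report
    io.write_json(timings, out_root / "timings.json")
    io.write_json(report, out_root / "run_report.json")
    return report
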