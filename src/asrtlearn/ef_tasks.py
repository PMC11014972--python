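"""Executive-function task score formulas.

Pure score arithmetic for the neuropsychological battery: attentional
network test (ANT) subtraction scores, go/no-go d' by signal detection,
verbal fluency (words minus errors) and span tasks (mean of run maxima).
These document the semantics the synthetic EF tables emulate and can score
real per-condition inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import norm

__all__ = [
    "ANTConditionMeans",
    "DPrimeInput",
    "ant_scores",
    "gng_dprime",
    "dprime_from_rates",
    "fluency_score",
    "span_score_cspan",
    "score_table",
]


@dataclass(frozen=True)
class ANTConditionMeans:
    no_cue: float
    center_cue: float
    spatial_cue: float
    congruent: float
    incongruent: float

    def __post_init__(self) -> None:
        for name in ("no_cue", "center_cue", "spatial_cue", "congruent", "incongruent"):
            v = getattr(self, name)
            if v is None or not v > 0:
                raise ValueError(f"ANT condition mean {name} must be positive, got {v!r}")


@dataclass(frozen=True)
class DPrimeInput:
    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int

    def __post_init__(self) -> None:
        for name in ("hits", "misses", "false_alarms", "correct_rejections"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.hits + self.misses <= 0:
            raise ValueError("hits + misses must be positive")
        if self.false_alarms + self.correct_rejections <= 0:
            raise ValueError("false_alarms + correct_rejections must be positive")


def ant_scores(m: ANTConditionMeans) -> dict[str, float]:
    """Alerting, orienting and executive network scores (ms).

    alerting = no-cue - center-cue; orienting = center-cue - spatial-cue;
    executive = incongruent - congruent. All are differences of condition
    mean RTs and hence invariant to overall speed.
    """
    return {
        "alerting": m.no_cue - m.center_cue,
        "orienting": m.center_cue - m.spatial_cue,
        "executive": m.incongruent - m.congruent,
    }


def dprime_from_rates(hit_rate: float, fa_rate: float) -> float:
    """d' = Phi^-1(hit rate) - Phi^-1(false-alarm rate)."""
    if not 0 < hit_rate < 1 or not 0 < fa_rate < 1:
        raise ValueError("rates must lie strictly in (0, 1); correct boundary counts first")
    return float(norm.ppf(hit_rate) - norm.ppf(fa_rate))


def gng_dprime(x: DPrimeInput, correction: str = "loglinear") -> float:
    """Go/no-go sensitivity d' from response counts.

    ``correction='loglinear'`` adds 0.5 to every cell before forming rates,
    which keeps d' finite when the hit or false-alarm rate would be 0 or 1;
    ``'none'`` uses raw rates and fails on boundary values.
    """
    if correction == "loglinear":
        hit = (x.hits + 0.5) / (x.hits + x.misses + 1.0)
        fa = (x.false_alarms + 0.5) / (x.false_alarms + x.correct_rejections + 1.0)
    elif correction == "none":
        hit = x.hits / (x.hits + x.misses)
        fa = x.false_alarms / (x.false_alarms + x.correct_rejections)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return dprime_from_rates(hit, fa)


def fluency_score(n_words: int, n_errors: int) -> int:
    """Verbal fluency: words produced in one minute minus rule violations."""
    if n_words < 0 or n_errors < 0:
        raise ValueError("word and error counts must be nonnegative")
    return n_words - n_errors


def span_score_cspan(run_maxima) -> float:
    """Counting span: mean of the highest set size recalled in three runs."""
    vals = list(run_maxima)
    if len(vals) != 3:
        raise ValueError(f"expected 3 run maxima, got {len(vals)}")
    if any(v < 0 for v in vals):
        raise ValueError("run maxima must be nonnegative")
    return sum(vals) / 3.0


def score_table(raw: pd.DataFrame) -> pd.DataFrame:
    """Score a per-participant CSV of raw task summaries.

    Recognised column groups (all optional): ANT condition means
    (ant_no_cue, ant_center_cue, ant_spatial_cue, ant_congruent,
    ant_incongruent), GNG counts (gng_hits, gng_misses, gng_false_alarms,
    gng_correct_rejections), fluency pairs (<name>_words, <name>_errors)
    and span run maxima (cspan_run1..3).
    """
    out = pd.DataFrame({"subject_id": raw["subject_id"]})
    ant_cols = ["ant_no_cue", "ant_center_cue", "ant_spatial_cue", "ant_congruent", "ant_incongruent"]
    if set(ant_cols) <= set(raw.columns):
        for i, row in raw.iterrows():
            scores = ant_scores(ANTConditionMeans(*[row[c] for c in ant_cols]))
            for k, v in scores.items():
                out.loc[i, f"ant_{k}"] = v
    gng_cols = ["gng_hits", "gng_misses", "gng_false_alarms", "gng_correct_rejections"]
    if set(gng_cols) <= set(raw.columns):
        out["gng"] = [
            gng_dprime(DPrimeInput(*[int(row[c]) for c in gng_cols]))
            for _, row in raw.iterrows()
        ]
    for col in raw.columns:
        if col.endswith("_words"):
            stem = col[: -len("_words")]
            if f"{stem}_errors" in raw.columns:
                out[stem] = raw[col] - raw[f"{stem}_errors"]
    span_cols = ["cspan_run1", "cspan_run2", "cspan_run3"]
    if set(span_cols) <= set(raw.columns):
        out["cspan"] = raw[span_cols].mean(axis=1)
    return out
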