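"""Forced-choice scoring, discrimination curves, A′/d′ and cue benefit.

The task is two-alternative forced choice: every trial is answered
``happy`` or ``sad``, so the guess rate is 0.5.  A trial is scored against
the label its cue carries — the TFS source's emotion when scoring the
fine-structure cue, the ENV source's emotion when scoring the envelope cue
(for a chimera these are complementary).

Signal-detection mapping: *happy* is the signal class, so the hit rate is
P(respond happy | true happy) and the false-alarm rate is
P(respond happy | true sad).  A′ is Grier's non-parametric discriminability
(0.5 = chance, 1 = perfect); d′ is z(H) − z(F) with the log-linear count
correction applied throughout.  The TFS benefit (TFS − ENV)/(1 − ENV) and
its ENV mirror normalize one cue's advantage by the headroom the other cue
leaves, on a nominal ±1 scale.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import norm

from .chimera_synth import CONDITION_ORDER

logger = logging.getLogger("emochimera")

GROUPS = ("poor", "good", "first_year", "last_year")
SEXES = ("male", "female")
CUES = ("tfs", "env")
RESPONSES = ("happy", "sad")

RESPONSE_COLUMNS = (
    "participant_id", "group", "sex", "stimulus_id",
    "condition", "cue", "true_label", "response",
)


class SchemaError(ValueError):
    """Raised when a response table violates the expected schema."""


def condition_categorical(values) -> pd.Categorical:
    """Order conditions org → nb64."""
    return pd.Categorical(values, categories=list(CONDITION_ORDER), ordered=True)


def validate_response_table(rt: pd.DataFrame) -> pd.DataFrame:
    """Check schema, label alphabet and trial uniqueness of a response table."""
    missing = [c for c in RESPONSE_COLUMNS if c not in rt.columns]
    if missing:
        raise SchemaError(f"response table missing columns {missing}")
    for col, allowed in (("true_label", RESPONSES), ("response", RESPONSES),
                         ("cue", CUES), ("condition", CONDITION_ORDER)):
        bad = set(rt[col].unique()) - set(allowed)
        if bad:
            raise SchemaError(f"unknown values {sorted(bad)} in column {col!r}")
    key = ["participant_id", "stimulus_id", "condition", "cue"]
    if rt.duplicated(subset=key).any():
        raise SchemaError("duplicate (participant, stimulus, condition, cue) trials")
    return rt


def score_responses(rt: pd.DataFrame) -> pd.DataFrame:
    """Append a boolean ``correct`` column (response vs the row's cue label)."""
    validate_response_table(rt)
    out = rt.copy()
    out["correct"] = out["response"].to_numpy() == out["true_label"].to_numpy()
    return out


def discrimination_curve(rt: pd.DataFrame, by: tuple = ()) -> pd.DataFrame:
    """Percent-correct per condition, optionally stratified.

    Aggregation is participant-first: the participant's percent correct is
    computed per condition, then participants are averaged, so each listener
    carries equal weight (the mean-of-means behind a mean ± SD table).
    Returns columns ``[*by, condition, percent_correct, sd, n_trials]``;
    strata with no trials in some condition appear with NaN, never a silent
    zero.
    """
    scored = rt if "correct" in rt.columns else score_responses(rt)
    by = list(by)
    per_part = (
        scored.groupby(by + ["condition", "participant_id"], observed=True)["correct"]
        .agg(["mean", "size"])
        .reset_index()
    )
    agg = (
        per_part.groupby(by + ["condition"], observed=True)
        .agg(percent_correct=("mean", "mean"), sd=("mean", "std"), n_trials=("size", "sum"))
        .reset_index()
    )
    agg["percent_correct"] *= 100.0
    agg["sd"] *= 100.0
    agg["condition"] = condition_categorical(agg["condition"])
    return agg.sort_values(by + ["condition"]).reset_index(drop=True)


def participant_totals(rt: pd.DataFrame, condition: str = "org") -> pd.DataFrame:
    """Per-participant correct totals and percent for one condition.

    ``percent_correct = 100 × total_correct / n_stimuli`` reproduces the
    mean-total ↔ percent correspondence of a summary table (e.g. a mean
    total of 31.25 correct out of 32 originals is 97.66%).
    """
    scored = rt if "correct" in rt.columns else score_responses(rt)
    sub = scored[scored["condition"] == condition]
    out = (
        sub.groupby(["participant_id", "group", "sex"], observed=True)["correct"]
        .agg(total_correct="sum", n_stimuli="size")
        .reset_index()
    )
    out["percent_correct"] = 100.0 * out["total_correct"] / out["n_stimuli"]
    return out


def percent_from_mean_total(mean_total: float, n_stimuli: int) -> float:
    """Percent correct implied by a mean correct total out of ``n_stimuli``."""
    return 100.0 * mean_total / n_stimuli


def normalized_ratio(curve_num, curve_den):
    """Elementwise ratio of two discrimination curves (e.g. happy / sad).

    Zero denominators yield NaN (undefined-value marker), never an error.
    """
    num = np.asarray(curve_num, dtype=float)
    den = np.asarray(curve_den, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den != 0, num / np.where(den != 0, den, 1.0), np.nan)
    return out


def a_prime(hit_rate, fa_rate):
    """Grier's non-parametric discriminability A′ ∈ [0, 1].

    For H ≥ F: 0.5 + (H−F)(1+H−F) / (4H(1−F)); for H < F the complementary
    branch 0.5 − (F−H)(1+F−H)/(4F(1−H)).  H = F gives 0.5 (chance); the 0/0
    corner cases resolve to 0.5 as well.  Vectorized over array inputs.
    """
    h = np.asarray(hit_rate, dtype=float)
    f = np.asarray(fa_rate, dtype=float)
    if np.any((h < 0) | (h > 1) | (f < 0) | (f > 1)):
        raise ValueError("rates must lie in [0, 1]")
    # factored form (d/x)·((1+d)/(1-y))/4 stays bounded for tiny rates;
    # the final clip resolves the overflowing corner at rates within one
    # ulp of the boundary
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        hs = np.where(h > 0, h, 1.0)
        upper = np.where((h > 0) & (f < 1),
                         0.5 + ((h - f) / hs) * ((1 + h - f) / (1 - np.minimum(f, 1 - 1e-300))) / 4,
                         0.5)
        fs = np.where(f > 0, f, 1.0)
        lower = np.where((f > 0) & (h < 1),
                         0.5 - ((f - h) / fs) * ((1 + f - h) / (1 - np.minimum(h, 1 - 1e-300))) / 4,
                         0.5)
    out = np.clip(np.where(h >= f, upper, lower), 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def d_prime(hit_rate, fa_rate, n_signal: int, n_noise: int):
    """d′ = z(H′) − z(F′) with the log-linear correction applied always.

    Counts are recovered from the rates, then corrected as
    H′ = (hits + 0.5)/(n + 1) so the statistic stays finite at observed
    rates of 0 or 1.
    """
    if n_signal < 1 or n_noise < 1:
        raise ValueError("trial counts must be >= 1")
    h = np.asarray(hit_rate, dtype=float)
    f = np.asarray(fa_rate, dtype=float)
    h_adj = (h * n_signal + 0.5) / (n_signal + 1.0)
    f_adj = (f * n_noise + 0.5) / (n_noise + 1.0)
    out = norm.ppf(h_adj) - norm.ppf(f_adj)
    return float(out) if np.ndim(out) == 0 else out


def sdt_table(rt: pd.DataFrame, by: tuple = ("group",), pooled: bool = True) -> pd.DataFrame:
    """Hit/FA rates, A′ and d′ per condition within each stratum.

    ``pooled=True`` pools trials within a stratum before computing rates;
    ``pooled=False`` computes per-participant A′/d′ and averages them.
    """
    scored = rt if "correct" in rt.columns else score_responses(rt)
    unit = list(by) + ["condition"] + ([] if pooled else ["participant_id"])

    def rates(g: pd.DataFrame) -> pd.Series:
        happy = g[g["true_label"] == "happy"]
        sad = g[g["true_label"] == "sad"]
        n_sig, n_noise = len(happy), len(sad)
        h = (happy["response"] == "happy").mean() if n_sig else np.nan
        f = (sad["response"] == "happy").mean() if n_noise else np.nan
        return pd.Series({
            "hit_rate": h, "fa_rate": f,
            "a_prime": a_prime(h, f) if n_sig and n_noise else np.nan,
            "d_prime": d_prime(h, f, n_sig, n_noise) if n_sig and n_noise else np.nan,
            "n_signal": n_sig, "n_noise": n_noise,
        })

    out = scored.groupby(unit, observed=True).apply(rates, include_groups=False).reset_index()
    if not pooled:
        out = (out.groupby(list(by) + ["condition"], observed=True)
               [["hit_rate", "fa_rate", "a_prime", "d_prime"]].mean().reset_index())
    out["condition"] = condition_categorical(out["condition"])
    return out.sort_values(list(by) + ["condition"]).reset_index(drop=True)


def benefit(cue_curve, other_curve, which: str = "tfs"):
    """Normalized benefit of one cue over the other, per condition.

    ``which='tfs'`` computes (TFS − ENV)/(1 − ENV) with ``cue_curve`` as the
    TFS proportions; ``which='env'`` mirrors it.  Inputs are proportions in
    [0, 1].  Conditions where the normalizing curve equals 1 yield NaN; values
    escaping the nominal ±1 scale (possible when the denominator is small)
    are reported raw with a logged warning.
    """
    if which not in CUES:
        raise ValueError(f"which must be one of {CUES}")
    cue = np.asarray(cue_curve, dtype=float)
    other = np.asarray(other_curve, dtype=float)
    if np.any((cue < 0) | (cue > 1)) or np.any((other < 0) | (other > 1)):
        raise ValueError("benefit inputs are proportions in [0, 1]")
    den = 1.0 - other
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den != 0, (cue - other) / np.where(den != 0, den, 1.0), np.nan)
    if np.any(np.abs(out[np.isfinite(out)]) > 1):
        logger.warning("benefit values escape the nominal [-1, 1] scale; reported raw")
    return out


def condition_pivot(rt: pd.DataFrame, cue: str = "tfs", emotion: str | None = None):
    """Participant × condition accuracy matrix for group-level modelling.

    Filters to one cue (and optionally one stimulus emotion), pivots to one
    row per participant with a proportion-correct column per condition in
    org → nb64 order, and returns ``(matrix, groups)`` where ``groups`` is
    the participant's group label aligned with the matrix rows.
    """
    scored = rt if "correct" in rt.columns else score_responses(rt)
    sub = scored[scored["cue"] == cue]
    if emotion is not None:
        sub = sub[sub["true_label"] == emotion]
    wide = (
        sub.groupby(["participant_id", "group", "condition"], observed=True)["correct"]
        .mean()
        .unstack("condition")
        .reindex(columns=list(CONDITION_ORDER))
    )
    groups = wide.index.get_level_values("group").to_numpy()
    wide.index = wide.index.get_level_values("participant_id")
    return wide, groups


def a_prime_relative_difference(a_happy: float, a_sad: float) -> float:
    """Relative A′ difference 100 × (A′_happy − A′_sad)/A′_happy, in percent.

    Reported to two decimals; returns NaN when A′_happy is zero.
    """
    if a_happy == 0:
        return float("nan")
    return round(100.0 * (a_happy - a_sad) / a_happy, 2)
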