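"""Model checking and behavioral summaries, plus two baseline formalisms.

Includes posterior re-simulation (simulating fresh sessions from
posterior draws and aggregating predictions by cue-validity level),
trailing moving-average smoothing of learning curves, the standard
summary tables (mean correct RT by number of cues; RT and accuracy by
validity level), the lens model equation relating achievement to
matching, environmental predictability and response consistency, and a
take-the-best predictor over the cue-validity hierarchy.

Accuracy is scored as choice = feedback outcome of that trial
(feedback-consistent scoring, appropriate for probabilistic feedback);
scoring against the more likely outcome given the pattern is available
as an option.
"""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .environment import (
    NEGATIVE,
    POSITIVE,
    CuePattern,
    Environment,
    marginal_cue_validity,
    round_half_away,
)
from .inference import PosteriorSamples
from .simulate import simulate_participant

__all__ = [
    "LensComponents",
    "posterior_resimulate",
    "moving_average",
    "rt_accuracy_by_validity",
    "correct_rt_by_ncues",
    "lens_model_equation",
    "take_the_best_predict",
    "accuracy_column",
]

from dataclasses import dataclass


@dataclass(frozen=True)
class LensComponents:
    """Components of the lens model equation: matching correlation G,
    environmental predictability Re, response consistency Ri, and the
    error-term correlation C."""

    G: float
    Re: float
    Ri: float
    C: float

    def __post_init__(self) -> None:
        for name in ("G", "Re", "Ri", "C"):
            val = getattr(self, name)
            if not -1.0 <= val <= 1.0:
                raise ValueError(f"{name} must lie in [-1, 1], got {val}")
        if self.Re < 0 or self.Ri < 0:
            raise ValueError("Re and Ri are multiple correlations, must be >= 0")


def lens_model_equation(c: LensComponents) -> float:
    """Achievement r_a = G*Re*Ri + C*sqrt((1-Re^2)(1-Ri^2))."""
    return c.G * c.Re * c.Ri + c.C * np.sqrt(
        (1.0 - c.Re**2) * (1.0 - c.Ri**2)
    )


def take_the_best_predict(
    pattern: CuePattern,
    env: Environment,
    rng: np.random.Generator,
    tol: float = 1e-6,
    tie_tol: float = 0.01,
) -> str:
    """Predict the outcome with a take-the-best cue hierarchy.

    Present cues are examined in descending order of |marginal validity
    - 0.5|; the first cue whose marginal validity differs from 0.5 by
    more than ``tol`` decides (positive side if validity > 0.5).  Cues
    of opposing direction whose extremities differ by at most
    ``tie_tol`` cancel and fall through (in the canonical environment
    the strongest positive and negative cues land at 0.805 and 0.203
    only because realized counts are integers — they implement one
    designed validity level); if no cue discriminates, the prediction
    is a uniform guess.

    This adapts the paired-comparison heuristic to single-profile binary
    prediction: "discriminates" means the present cue's marginal
    validity departs from chance.
    """
    present = [i + 1 for i, b in enumerate(pattern.bits) if b == 1]
    margins = {i: marginal_cue_validity(env, i) for i in present}
    by_extremity = sorted(present, key=lambda i: abs(margins[i] - 0.5), reverse=True)
    k = 0
    while k < len(by_extremity):
        top = by_extremity[k]
        ext = abs(margins[top] - 0.5)
        if ext <= tol:
            break  # nothing below this discriminates either
        tied = [
            i for i in by_extremity if abs(abs(margins[i] - 0.5) - ext) <= tie_tol
        ]
        signs = {np.sign(margins[i] - 0.5) for i in tied}
        if len(signs) == 1:
            return POSITIVE if margins[top] > 0.5 else NEGATIVE
        k += len(tied)  # opposing equally-extreme cues cancel; fall through
    return POSITIVE if rng.random() < 0.5 else NEGATIVE


def moving_average(series, lag: int = 20) -> np.ndarray:
    """Trailing moving average with window ``lag``.

    The window is truncated at the start of the series: element i is the
    mean of the last min(i+1, lag) values.  A centered window is
    available via ``center=True`` in :func:`smoothed_series`.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("series must be non-empty")
    if lag < 1:
        raise ValueError("lag must be >= 1")
    return (
        pd.Series(x).rolling(window=lag, min_periods=1).mean().to_numpy()
    )


def smoothed_series(series, lag: int = 20, center: bool = False) -> np.ndarray:
    """Moving average with either the trailing (default) or a centered window."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("series must be non-empty")
    return (
        pd.Series(x)
        .rolling(window=lag, min_periods=1, center=center)
        .mean()
        .to_numpy()
    )


def accuracy_column(
    dataset: pd.DataFrame,
    env: Optional[Environment] = None,
    scoring: str = "feedback",
) -> pd.Series:
    """Per-trial accuracy indicator.

    ``feedback`` scores choice against the trial's realized outcome;
    ``designed`` scores it against the more likely outcome given the
    pattern (ties count as 0.5).
    """
    if scoring == "feedback":
        return (dataset["choice"] == dataset["outcome"]).astype(float)
    if scoring == "designed":
        if env is None:
            raise ValueError("designed scoring requires the environment")
        p = {r.pattern.bits_string(): r.p_positive_designed for r in env.rows}
        pr = dataset["bits"].astype(str).map(p)
        best = np.where(pr > 0.5, POSITIVE, NEGATIVE)
        acc = (dataset["choice"].to_numpy() == best).astype(float)
        acc[np.isclose(pr.to_numpy(dtype=float), 0.5)] = 0.5
        return pd.Series(acc, index=dataset.index)
    raise ValueError(f"unknown scoring {scoring!r}")


def _validity_levels(env: Environment) -> dict[str, float]:
    return {
        r.pattern.bits_string(): round_half_away(abs(r.p_positive_designed - 0.5), 3)
        for r in env.rows
    }


def rt_accuracy_by_validity(
    dataset: pd.DataFrame,
    env: Environment,
    rt_correct_only: bool = True,
    scoring: str = "feedback",
) -> pd.DataFrame:
    """Mean and SD (across participants) of RT and accuracy per
    ecological-validity level |P(positive|pattern) - 0.5|.

    Validity-level keys are rounded to 3 decimals before grouping.  RT
    summaries default to correct trials only (matching the correct-RT
    convention of the task's summary tables); accuracy always uses all
    trials.
    """
    levels = _validity_levels(env)
    bits = dataset["bits"].astype(str)
    unknown = sorted(set(bits) - set(levels))
    if unknown:
        raise KeyError(f"patterns not in environment: {unknown}")
    df = dataset.copy()
    df["level"] = bits.map(levels)
    df["accuracy"] = accuracy_column(df, env, scoring)

    per_part_acc = (
        df.groupby(["participant", "level"])["accuracy"].mean().reset_index()
    )
    rt_src = df[df["accuracy"] > 0.5] if rt_correct_only else df
    per_part_rt = rt_src.groupby(["participant", "level"])["rt"].mean().reset_index()

    acc = per_part_acc.groupby("level")["accuracy"].agg(["mean", "std"])
    rt = per_part_rt.groupby("level")["rt"].agg(["mean", "std"])
    out = pd.DataFrame(
        {
            "mean_rt": rt["mean"],
            "sd_rt": rt["std"],
            "mean_accuracy": acc["mean"],
            "sd_accuracy": acc["std"],
        }
    ).reset_index()
    return out.sort_values("level").reset_index(drop=True)


def correct_rt_by_ncues(dataset: pd.DataFrame) -> pd.DataFrame:
    """Mean (SD) correct-trial RT per condition and number of cues.

    Only trials where the choice matched the feedback outcome enter.
    Values are reported in seconds rounded to 3 decimals (millisecond
    precision).  Cells with no correct trials are flagged missing (NaN
    mean/SD, n = 0) rather than reported as zero.
    """
    if len(dataset) == 0:
        raise ValueError("dataset must be non-empty")
    correct = dataset[dataset["choice"] == dataset["outcome"]]
    cells = []
    for cond in sorted(dataset["condition"].unique()):
        for n in sorted(dataset["n_cues"].unique()):
            sub = correct[(correct["condition"] == cond) & (correct["n_cues"] == n)]
            if len(sub):
                cells.append(
                    {
                        "condition": cond,
                        "n_cues": int(n),
                        "mean_rt": round_half_away(float(sub["rt"].mean()), 3),
                        "sd_rt": round_half_away(float(sub["rt"].std(ddof=1)), 3)
                        if len(sub) > 1
                        else np.nan,
                        "n": len(sub),
                        "missing": False,
                    }
                )
            else:
                cells.append(
                    {
                        "condition": cond,
                        "n_cues": int(n),
                        "mean_rt": np.nan,
                        "sd_rt": np.nan,
                        "n": 0,
                        "missing": True,
                    }
                )
    return pd.DataFrame(cells)


def posterior_resimulate(
    samples_by_participant: Mapping[str, PosteriorSamples],
    env: Environment,
    n_draws: int = 500,
    rng: Optional[np.random.Generator] = None,
    conditions: Optional[Mapping[str, str]] = None,
    mode: str = "exact_counts",
    n_trials: int = 246,
    dt: float = 1e-3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Posterior predictive re-simulation.

    For each participant, ``n_draws`` posterior draws (with replacement)
    each generate one fresh simulated session using that draw's static
    parameters and latent trajectory.  Returns the predicted dataset
    (same schema as observed data, with a ``draw`` column) and a summary
    table per condition and validity level: the median across
    draw-level means, plus their mean and SD, for RT and accuracy.
    """
    if not samples_by_participant:
        raise ValueError("no posterior samples supplied")
    rng = rng if rng is not None else np.random.default_rng()
    conditions = conditions or {p: "all" for p in samples_by_participant}

    frames = []
    for pid, samples in samples_by_participant.items():
        if len(samples) == 0:
            raise ValueError(f"participant {pid}: empty sample set")
        idx = rng.integers(0, len(samples), size=n_draws)
        for d, i in enumerate(idx):
            sim = simulate_participant(
                env,
                samples.static_params(int(i)),
                samples.trajectory(int(i)),
                rng,
                participant=pid,
                condition=conditions[pid],
                mode=mode,
                n_trials=n_trials,
                dt=dt,
            )
            sim["draw"] = d
            frames.append(sim)
    predicted = pd.concat(frames, ignore_index=True)

    levels = _validity_levels(env)
    df = predicted.copy()
    df["level"] = df["bits"].astype(str).map(levels)
    df["accuracy"] = (df["choice"] == df["outcome"]).astype(float)
    per_draw = (
        df.groupby(["condition", "participant", "draw", "level"])[["rt", "accuracy"]]
        .mean()
        .reset_index()
    )
    summary = (
        per_draw.groupby(["condition", "level"])[["rt", "accuracy"]]
        .agg(["median", "mean", "std"])
        .reset_index()
    )
    summary.columns = [
        "_".join(c) if c[1] else c[0] for c in summary.columns.to_flat_index()
    ]
    return predicted, summary
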