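"""Multiple-cue probability-learning (MCPL) environment.

The task is a modified weather prediction task: on each trial the
participant sees one, two, or three of four probabilistic cues (a 4-bit
presence pattern) and predicts a binary outcome (positive = truth/win,
negative = lie/loss), receiving trial-by-trial feedback.  The canonical
environment consists of the 14 admissible patterns (all-present and
all-absent excluded), their per-session frequencies over 246 trials,
the designed conditional probability of the positive outcome given each
pattern, and the realized outcome counts.

The marginal validities of the four cues are approximately 0.8, 0.6,
0.4, and 0.2 (cue 1 is the strongest positive predictor, cue 4 the
strongest negative predictor).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "POSITIVE",
    "NEGATIVE",
    "CuePattern",
    "PatternRow",
    "Environment",
    "UnknownPatternError",
    "canonical_environment",
    "admissible_patterns",
    "validity_regressor",
    "marginal_cue_validity",
    "make_session_sequence",
    "round_half_away",
]

POSITIVE = "positive"
NEGATIVE = "negative"

SESSION_LENGTH = 246


def round_half_away(x: float, decimals: int = 3) -> float:
    """Round with ties going away from zero (the convention used for
    all printed-value comparisons and serialized response times)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True, order=True)
class CuePattern:
    """An ordered tuple of cue-presence flags (1 = present)."""

    bits: tuple[int, ...]
    label: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.bits or any(b not in (0, 1) for b in self.bits):
            raise ValueError(f"bits must be 0/1 flags, got {self.bits!r}")
        n = sum(self.bits)
        if n == 0 or n == len(self.bits):
            raise ValueError(
                f"pattern {self.bits_string()} inadmissible: all-absent and "
                "all-present patterns are excluded from the task"
            )

    @property
    def n_cues(self) -> int:
        return sum(self.bits)

    def bits_string(self) -> str:
        return "".join(str(b) for b in self.bits)

    @classmethod
    def from_string(cls, s: str, label: str = "") -> "CuePattern":
        if not s or any(c not in "01" for c in s):
            raise ValueError(f"invalid bit string {s!r}")
        return cls(bits=tuple(int(c) for c in s), label=label)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.bits_string()


@dataclass(frozen=True)
class PatternRow:
    """One environment row: a pattern with its session frequency,
    designed conditional outcome probability, and realized counts."""

    pattern: CuePattern
    session_count: int
    p_pattern: float
    count_positive: int
    count_negative: int
    p_positive_designed: float

    def __post_init__(self) -> None:
        if self.session_count < 0:
            raise ValueError("session_count must be >= 0")
        if self.count_positive + self.count_negative != self.session_count:
            raise ValueError(
                f"row {self.pattern.label or self.pattern.bits_string()}: "
                f"a + b = {self.count_positive + self.count_negative} "
                f"!= session_count = {self.session_count}"
            )
        if not 0.0 <= self.p_positive_designed <= 1.0:
            raise ValueError("p_positive_designed must lie in [0, 1]")


class UnknownPatternError(KeyError):
    """Raised when a cue pattern is not part of the environment."""


@dataclass(frozen=True)
class Environment:
    rows: tuple[PatternRow, ...]
    session_length: int
    cue_count: int

    def __post_init__(self) -> None:
        if sum(r.session_count for r in self.rows) != self.session_length:
            raise ValueError("session counts do not sum to session_length")

    def row_for(self, pattern: CuePattern) -> PatternRow:
        for row in self.rows:
            if row.pattern.bits == pattern.bits:
                return row
        raise UnknownPatternError(
            f"pattern {pattern.bits_string()} not in environment"
        )

    def row_by_bits(self, bits: str) -> PatternRow:
        return self.row_for(CuePattern.from_string(bits))

    @property
    def patterns(self) -> tuple[CuePattern, ...]:
        return tuple(r.pattern for r in self.rows)

    # -- serialization -------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": [r.pattern.label for r in self.rows],
                "bits": [r.pattern.bits_string() for r in self.rows],
                "total": [r.session_count for r in self.rows],
                "p_pattern": [r.p_pattern for r in self.rows],
                "a": [r.count_positive for r in self.rows],
                "b": [r.count_negative for r in self.rows],
                "p_designed": [r.p_positive_designed for r in self.rows],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Environment":
        rows = tuple(
            PatternRow(
                pattern=CuePattern.from_string(str(rec.bits), label=str(rec.label)),
                session_count=int(rec.total),
                p_pattern=float(rec.p_pattern),
                count_positive=int(rec.a),
                count_negative=int(rec.b),
                p_positive_designed=float(rec.p_designed),
            )
            for rec in df.itertuples()
        )
        cue_count = len(rows[0].pattern.bits)
        return cls(
            rows=rows,
            session_length=sum(r.session_count for r in rows),
            cue_count=cue_count,
        )

    @classmethod
    def from_csv(cls, path) -> "Environment":
        return cls.from_frame(pd.read_csv(path, dtype={"bits": str}))


# Canonical 14-row environment: label, bits, session total, P(pattern),
# realized positive count a, realized negative count b, designed P(a|pattern).
_CANONICAL_TABLE = (
    ("A", "1110", 23, 0.093, 21, 2, 0.913),
    ("B", "1101", 11, 0.045, 9, 2, 0.773),
    ("C", "1100", 32, 0.130, 29, 3, 0.906),
    ("D", "1011", 11, 0.045, 3, 8, 0.227),
    ("E", "1010", 15, 0.061, 12, 3, 0.800),
    ("F", "1001", 8, 0.033, 4, 4, 0.500),
    ("G", "1000", 23, 0.093, 21, 2, 0.913),
    ("H", "0111", 23, 0.093, 2, 21, 0.087),
    ("I", "0110", 8, 0.033, 4, 4, 0.500),
    ("J", "0101", 15, 0.061, 3, 12, 0.200),
    ("K", "0100", 11, 0.045, 6, 5, 0.546),
    ("L", "0011", 32, 0.130, 2, 30, 0.063),
    ("M", "0010", 11, 0.045, 5, 6, 0.454),
    ("N", "0001", 23, 0.093, 2, 21, 0.087),
)


def canonical_environment() -> Environment:
    """The canonical 4-cue environment: 14 patterns, 246 trials per
    session, 123 positive and 123 negative outcomes.

    Printed designed probabilities and realized counts are stored
    separately: for four patterns (B, D, K, M) the designed generative
    probability differs from the realized relative frequency a/(a+b)
    because the frequency distribution was fixed by design beforehand.
    """
    rows = tuple(
        PatternRow(
            pattern=CuePattern.from_string(bits, label=label),
            session_count=total,
            p_pattern=p_pat,
            count_positive=a,
            count_negative=b,
            p_positive_designed=p_designed,
        )
        for label, bits, total, p_pat, a, b, p_designed in _CANONICAL_TABLE
    )
    return Environment(rows=rows, session_length=SESSION_LENGTH, cue_count=4)


def admissible_patterns(cue_count: int) -> set[CuePattern]:
    """All presence patterns over ``cue_count`` positions except
    all-absent and all-present; there are 2**cue_count - 2 of them."""
    if cue_count < 2:
        raise ValueError("cue_count must be >= 2")
    out: set[CuePattern] = set()
    for bits in itertools.product((0, 1), repeat=cue_count):
        n = sum(bits)
        if 0 < n < cue_count:
            s = "".join(map(str, bits))
            out.add(CuePattern(bits=bits, label=s))
    return out


def validity_regressor(
    pattern: CuePattern,
    env: Environment,
    coding: Literal["signed", "absolute"] = "signed",
) -> float:
    """Ecological validity of a cue pattern as a drift regressor.

    ``signed`` returns P(positive | pattern) - 0.5 in [-0.5, 0.5] and is
    what the drift-rate map uses; ``absolute`` returns |P - 0.5| and is
    used only for grouping and plotting.
    """
    row = env.row_for(pattern)
    signed = row.p_positive_designed - 0.5
    if coding == "signed":
        return signed
    if coding == "absolute":
        return abs(signed)
    raise ValueError(f"unknown coding {coding!r}")


def marginal_cue_validity(env: Environment, cue_index: int) -> float:
    """Marginal P(positive outcome | cue present), from realized counts."""
    if not 1 <= cue_index <= env.cue_count:
        raise ValueError(f"cue_index must be in 1..{env.cue_count}")
    i = cue_index - 1
    pos = sum(r.count_positive for r in env.rows if r.pattern.bits[i] == 1)
    tot = sum(r.session_count for r in env.rows if r.pattern.bits[i] == 1)
    if tot == 0:
        raise ValueError(f"cue {cue_index} never present in environment")
    return pos / tot


def make_session_sequence(
    env: Environment,
    mode: Literal["exact_counts", "iid"],
    n_trials: int,
    rng: np.random.Generator,
) -> list[tuple[CuePattern, str]]:
    """Generate a trial sequence of (pattern, outcome) pairs.

    ``exact_counts`` reproduces the designed session exactly: each
    pattern appears its session_count times with exactly its realized
    positive/negative outcome counts, in uniformly random order
    (requires n_trials == session_length).  ``iid`` draws patterns with
    probability p_pattern and outcomes Bernoulli(p_positive_designed).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if mode == "exact_counts":
        if n_trials != env.session_length:
            raise ValueError(
                f"exact_counts mode requires n_trials == {env.session_length}"
            )
        trials: list[tuple[CuePattern, str]] = []
        for row in env.rows:
            trials.extend((row.pattern, POSITIVE) for _ in range(row.count_positive))
            trials.extend((row.pattern, NEGATIVE) for _ in range(row.count_negative))
        order = rng.permutation(len(trials))
        return [trials[i] for i in order]
    if mode == "iid":
        p = np.array([r.p_pattern for r in env.rows], dtype=float)
        p = p / p.sum()  # printed probabilities are rounded to 3 decimals
        idx = rng.choice(len(env.rows), size=n_trials, p=p)
        u = rng.random(n_trials)
        out = []
        for k, i in enumerate(idx):
            row = env.rows[i]
            outcome = POSITIVE if u[k] < row.p_positive_designed else NEGATIVE
            out.append((row.pattern, outcome))
        return out
    raise ValueError(f"unknown mode {mode!r}")
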