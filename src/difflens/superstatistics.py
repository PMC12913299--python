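"""High-level model: Gaussian random walks on the trial-wise parameters.

Three low-level parameters evolve across trials as independent Gaussian
random walks — the drift sensitivity to cue validity b_v, the boundary
separation a, and the base non-decision time tau0:

    b_v[t]  = b_v[t-1]  + sigma_v  * xi,   xi ~ N(0, 1)
    a[t]    = a[t-1]    + sigma_a  * xi
    tau0[t] = tau0[t-1] + sigma_tau * xi

The walk scales (sigma_v, sigma_a, sigma_tau) quantify how much the
decision process itself fluctuates from trial to trial.  b_v is
unbounded (it may be negative early in learning, capturing utilization
of invalid cues); a is kept >= A_MIN and tau0 >= TAU0_MIN by reflection
at the bound, which — unlike clipping — does not create sticky
boundaries that deflate the walk's variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "A_MIN",
    "TAU0_MIN",
    "LatentState",
    "Trajectory",
    "NoiseScales",
    "InitPrior",
    "reflect_lower",
    "step",
    "simulate_trajectory",
    "sample_init",
]

A_MIN = 0.1
TAU0_MIN = 0.0


@dataclass(frozen=True)
class LatentState:
    """The three trial-varying parameters at one trial."""

    b_v: float
    a: float
    tau0: float

    def __post_init__(self) -> None:
        if self.a < A_MIN:
            raise ValueError(f"a must be >= {A_MIN}")
        if self.tau0 < TAU0_MIN:
            raise ValueError(f"tau0 must be >= {TAU0_MIN}")

    def as_array(self) -> np.ndarray:
        return np.array([self.b_v, self.a, self.tau0])


@dataclass(frozen=True)
class NoiseScales:
    """Innovation SDs of the three random walks (per-trial units)."""

    sigma_v: float
    sigma_a: float
    sigma_tau: float

    def __post_init__(self) -> None:
        if min(self.sigma_v, self.sigma_a, self.sigma_tau) < 0:
            raise ValueError("noise scales must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.sigma_v, self.sigma_a, self.sigma_tau])


@dataclass(frozen=True)
class Trajectory:
    """Latent states over a session, stored as parallel arrays."""

    b_v: np.ndarray
    a: np.ndarray
    tau0: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.b_v) == len(self.a) == len(self.tau0)):
            raise ValueError("trajectory components must have equal length")

    def __len__(self) -> int:
        return len(self.b_v)

    def state(self, t: int) -> LatentState:
        """State at trial index t (0-based)."""
        return LatentState(
            b_v=float(self.b_v[t]), a=float(self.a[t]), tau0=float(self.tau0[t])
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(1, len(self) + 1),
                "b_v": self.b_v,
                "a": self.a,
                "tau0": self.tau0,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Trajectory":
        df = df.sort_values("trial")
        return cls(
            b_v=df["b_v"].to_numpy(float),
            a=df["a"].to_numpy(float),
            tau0=df["tau0"].to_numpy(float),
        )

    @classmethod
    def constant(cls, state: LatentState, T: int) -> "Trajectory":
        return cls(
            b_v=np.full(T, state.b_v),
            a=np.full(T, state.a),
            tau0=np.full(T, state.tau0),
        )


@dataclass(frozen=True)
class InitPrior:
    """Truncated-normal prior for the trial-1 latent state.

    Defaults encode an initial absence of cue knowledge (b_v centred at
    zero) and typical speeded-decision values for boundary separation
    and base non-decision time.
    """

    b_v_loc: float = 0.0
    b_v_scale: float = 0.5
    a_loc: float = 1.5
    a_scale: float = 0.5
    tau0_loc: float = 0.3
    tau0_scale: float = 0.1
    a_min: float = A_MIN
    tau0_min: float = TAU0_MIN

    def __post_init__(self) -> None:
        if self.a_min < A_MIN - 1e-12 or self.tau0_min < TAU0_MIN - 1e-12:
            raise ValueError("prior support must respect latent-state bounds")
        if min(self.b_v_scale, self.a_scale, self.tau0_scale) < 0:
            raise ValueError("prior scales must be non-negative")


def reflect_lower(x, lower):
    """Reflect values below a lower bound back into [lower, inf).

    Preserves the innovation magnitude: |reflected - lower| equals
    |proposed - lower|.
    """
    return lower + np.abs(np.asarray(x, dtype=float) - lower)


def step(
    state: LatentState, scales: NoiseScales, rng: np.random.Generator
) -> LatentState:
    """One random-walk transition with independent innovations per component."""
    xi = rng.standard_normal(3)
    b_v = state.b_v + scales.sigma_v * xi[0]
    a = reflect_lower(state.a + scales.sigma_a * xi[1], A_MIN)
    tau0 = reflect_lower(state.tau0 + scales.sigma_tau * xi[2], TAU0_MIN)
    return LatentState(b_v=float(b_v), a=float(a), tau0=float(tau0))


def simulate_trajectory(
    init: LatentState, scales: NoiseScales, T: int, rng: np.random.Generator
) -> Trajectory:
    """Simulate a T-trial latent trajectory; states[0] is the init state."""
    if T < 1:
        raise ValueError("T must be >= 1")
    xi = rng.standard_normal((T - 1, 3)) if T > 1 else np.empty((0, 3))
    b_v = np.empty(T)
    a = np.empty(T)
    tau0 = np.empty(T)
    b_v[0], a[0], tau0[0] = init.b_v, init.a, init.tau0
    for t in range(1, T):
        b_v[t] = b_v[t - 1] + scales.sigma_v * xi[t - 1, 0]
        a[t] = reflect_lower(a[t - 1] + scales.sigma_a * xi[t - 1, 1], A_MIN)
        tau0[t] = reflect_lower(
            tau0[t - 1] + scales.sigma_tau * xi[t - 1, 2], TAU0_MIN
        )
    return Trajectory(b_v=b_v, a=a, tau0=tau0)


def _truncnorm_rvs(loc, scale, lower, size, rng):
    if scale == 0:
        return np.full(size, max(loc, lower))
    a_std = (lower - loc) / scale
    return stats.truncnorm.rvs(
        a_std, np.inf, loc=loc, scale=scale, size=size, random_state=rng
    )


def sample_init(
    prior: InitPrior, rng: np.random.Generator, size: Optional[int] = None
):
    """Draw trial-1 latent state(s) from the init prior.

    With size=None returns a LatentState; otherwise an (size, 3) array
    of [b_v, a, tau0] columns for vectorized consumers (particle filters).
    """
    n = 1 if size is None else size
    if prior.b_v_scale == 0:
        b_v = np.full(n, prior.b_v_loc)
    else:
        b_v = rng.normal(prior.b_v_loc, prior.b_v_scale, size=n)
    a = _truncnorm_rvs(prior.a_loc, prior.a_scale, prior.a_min, n, rng)
    tau0 = _truncnorm_rvs(prior.tau0_loc, prior.tau0_scale, prior.tau0_min, n, rng)
    if size is None:
        return LatentState(b_v=float(b_v[0]), a=float(a[0]), tau0=float(tau0[0]))
    return np.column_stack([b_v, a, tau0])
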