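"""Forward simulation of participants and whole experiments.

Each simulated participant experiences one session of the MCPL task:
a trial sequence drawn from the environment, a latent parameter
trajectory (random walk or a fixed preset), and per-trial choices and
response times generated by the Wiener process.  Condition presets
produce deterministic learning-curve shapes — rising drift sensitivity
with a higher asymptote in the congruent condition, and boundary
separation and base non-decision time decaying toward floors — and are
integration-test fixtures, not empirical claims.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .ddm import (
    CHOICE_UPPER,
    StaticParams,
    drift_for_trial,
    ndt_for_trial,
    simulate_first_passage_batch,
)
from .environment import (
    NEGATIVE,
    POSITIVE,
    CuePattern,
    Environment,
    make_session_sequence,
    validity_regressor,
)
from .superstatistics import (
    A_MIN,
    TAU0_MIN,
    InitPrior,
    NoiseScales,
    Trajectory,
    sample_init,
    simulate_trajectory,
)

__all__ = [
    "TrialRecord",
    "SyntheticConfig",
    "DATASET_COLUMNS",
    "simulate_participant",
    "simulate_experiment",
    "preset_trajectory",
]

DATASET_COLUMNS = [
    "participant",
    "trial",
    "bits",
    "n_cues",
    "outcome",
    "choice",
    "rt",
    "condition",
]


@dataclass(frozen=True)
class TrialRecord:
    """One observed or simulated trial."""

    participant: str
    trial: int
    pattern: CuePattern
    n_cues: int
    outcome: str
    choice: str
    rt: float
    condition: str

    def __post_init__(self) -> None:
        if self.rt <= 0:
            raise ValueError("rt must be > 0")
        if self.n_cues != self.pattern.n_cues:
            raise ValueError("n_cues inconsistent with pattern")
        if self.outcome not in (POSITIVE, NEGATIVE):
            raise ValueError(f"bad outcome {self.outcome!r}")
        if self.choice not in (POSITIVE, NEGATIVE):
            raise ValueError(f"bad choice {self.choice!r}")


@dataclass
class SyntheticConfig:
    """Configuration for a full synthetic experiment.

    Latent dynamics come either from Gaussian random walks (init_prior +
    scales) or from a fixed condition preset trajectory shared by all
    participants of that condition.
    """

    n_participants: int = 20
    n_trials: int = 246
    mode: str = "exact_counts"
    statics: StaticParams = field(
        default_factory=lambda: StaticParams(v0=0.0, b_tau=0.15, beta=0.5)
    )
    init_prior: InitPrior = field(default_factory=InitPrior)
    scales: Optional[NoiseScales] = field(
        default_factory=lambda: NoiseScales(sigma_v=0.05, sigma_a=0.01, sigma_tau=0.005)
    )
    preset: Optional[str] = None  # "congruent" / "incongruent" overrides walks
    condition: str = "congruent"
    seed: int = 0
    dt: float = 1e-3

    def __post_init__(self) -> None:
        if self.mode == "exact_counts" and self.n_trials != 246:
            raise ValueError("exact_counts mode requires n_trials = 246")
        if self.preset is None and self.scales is None:
            raise ValueError("need either noise scales or a preset trajectory")


def simulate_participant(
    env: Environment,
    statics: StaticParams,
    latents: Union[Trajectory, tuple[NoiseScales, InitPrior]],
    rng: np.random.Generator,
    participant: str = "p01",
    condition: str = "congruent",
    mode: str = "exact_counts",
    n_trials: int = 246,
    dt: float = 1e-3,
) -> pd.DataFrame:
    """Simulate one participant's session.

    ``latents`` is either a fixed Trajectory of length n_trials, or a
    (NoiseScales, InitPrior) pair from which a fresh random-walk
    trajectory is drawn.  Returns one row per trial with the interchange
    schema (participant, trial, bits, n_cues, outcome, choice, rt,
    condition).
    """
    sequence = make_session_sequence(env, mode, n_trials, rng)
    if isinstance(latents, Trajectory):
        traj = latents
        if len(traj) != n_trials:
            raise ValueError(
                f"fixed trajectory length {len(traj)} != n_trials {n_trials}"
            )
    else:
        scales, init_prior = latents
        init = sample_init(init_prior, rng)
        traj = simulate_trajectory(init, scales, n_trials, rng)

    validity = np.array(
        [validity_regressor(pat, env, "signed") for pat, _ in sequence]
    )
    n_cues = np.array([pat.n_cues for pat, _ in sequence])
    v = drift_for_trial(statics.v0, traj.b_v, validity)
    tau = ndt_for_trial(traj.tau0, statics.b_tau, n_cues)
    choice_code, rt = simulate_first_passage_batch(
        v, traj.a, tau, statics.beta, rng, dt=dt
    )
    return pd.DataFrame(
        {
            "participant": participant,
            "trial": np.arange(1, n_trials + 1),
            "bits": [pat.bits_string() for pat, _ in sequence],
            "n_cues": n_cues,
            "outcome": [out for _, out in sequence],
            "choice": np.where(choice_code == CHOICE_UPPER, POSITIVE, NEGATIVE),
            "rt": rt,
            "condition": condition,
        }
    )[DATASET_COLUMNS]


def simulate_experiment(
    config: SyntheticConfig, env: Optional[Environment] = None
) -> pd.DataFrame:
    """Simulate a whole experiment; fully reproducible from config.seed.

    Each participant gets an independent RNG substream spawned from the
    master seed, so participants can be re-simulated independently.
    """
    from .environment import canonical_environment

    env = env or canonical_environment()
    master = np.random.SeedSequence(config.seed)
    substreams = master.spawn(config.n_participants)
    frames = []
    preset_traj = (
        preset_trajectory(config.preset, config.n_trials)
        if config.preset is not None
        else None
    )
    for i, ss in enumerate(substreams):
        rng = np.random.default_rng(ss)
        latents: Union[Trajectory, tuple[NoiseScales, InitPrior]]
        if preset_traj is not None:
            latents = preset_traj
        else:
            latents = (config.scales, config.init_prior)
        frames.append(
            simulate_participant(
                env,
                config.statics,
                latents,
                rng,
                participant=f"p{i + 1:02d}",
                condition=config.condition,
                mode=config.mode,
                n_trials=config.n_trials,
                dt=config.dt,
            )
        )
    return pd.concat(frames, ignore_index=True)


def preset_trajectory(
    condition: str,
    T: int,
    b_v_asymptote: Optional[float] = None,
    b_v_rate: Optional[float] = None,
    a_start: float = 1.8,
    a_floor: float = 1.2,
    a_rate: float = 0.01,
    tau0_start: float = 0.4,
    tau0_floor: float = 0.28,
    tau0_rate: float = 0.01,
) -> Trajectory:
    """Deterministic learning-curve trajectory for a condition preset.

    Drift sensitivity b_v rises as a saturating exponential toward an
    asymptote (higher and faster for the congruent condition, where cue
    salience supports learning the validities); boundary separation and
    base non-decision time decay exponentially toward floors, mirroring
    practice effects.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    defaults = {
        "congruent": (6.0, 1.0 / 60.0),
        "incongruent": (3.5, 1.0 / 100.0),
    }
    if condition not in defaults:
        raise ValueError(f"unknown condition {condition!r}")
    asym, rate = defaults[condition]
    if b_v_asymptote is not None:
        asym = b_v_asymptote
    if b_v_rate is not None:
        rate = b_v_rate
    t = np.arange(T, dtype=float)
    b_v = asym * (1.0 - np.exp(-rate * t))
    a = np.maximum(a_floor + (a_start - a_floor) * np.exp(-a_rate * t), A_MIN)
    tau0 = np.maximum(
        tau0_floor + (tau0_start - tau0_floor) * np.exp(-tau0_rate * t), TAU0_MIN
    )
    return Trajectory(b_v=b_v, a=a, tau0=tau0)
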