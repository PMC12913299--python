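"""Likelihood-based inference for the two-level model.

The latent trajectory (b_v, a, tau0) is integrated out with a bootstrap
particle filter whose proposal is the random-walk transition itself;
the filter's log marginal-likelihood estimate is unbiased in
expectation, which makes it a valid plug-in for particle-marginal
Metropolis–Hastings (PMMH) over the static parameters (v0, b_tau, beta)
and the walk scales (sigma_v, sigma_a, sigma_tau).

In the limit of zero walk scales and a degenerate initial state the
model collapses to a static four-parameter Wiener model, for which
``static_loglik_oracle`` provides the exact log-likelihood — the filter
must reproduce it exactly in that limit, which anchors the stochastic
machinery to a closed-form oracle.

Trajectory estimates come from ancestral-path samples of the accepted
filters.  Paths near t = 1 are degenerate (few surviving ancestral
lines), so the first few trials of estimated trajectories should not be
over-interpreted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .ddm import LOG_FLOOR, StaticParams, wfpt_logpdf, wfpt_logpdf_particles
from .environment import POSITIVE, Environment
from .superstatistics import (
    A_MIN,
    TAU0_MIN,
    InitPrior,
    LatentState,
    NoiseScales,
    Trajectory,
    reflect_lower,
    sample_init,
)

__all__ = [
    "FilterResult",
    "PosteriorSamples",
    "FitConfig",
    "Priors",
    "InitializationError",
    "design_arrays",
    "static_loglik_oracle",
    "particle_filter",
    "pmmh",
    "posterior_summaries",
]

_PARAM_NAMES = ["v0", "b_tau", "beta", "sigma_v", "sigma_a", "sigma_tau"]


class InitializationError(RuntimeError):
    """Raised when no finite-likelihood starting point can be found."""


def design_arrays(records: pd.DataFrame, env: Environment):
    """Extract per-trial arrays (validity, n_cues, rt, choice_code) from a
    dataset, ordered by trial."""
    records = records.sort_values("trial")
    validity_by_bits = {
        r.pattern.bits_string(): r.p_positive_designed - 0.5 for r in env.rows
    }
    bits = records["bits"].astype(str)
    try:
        validity = bits.map(validity_by_bits).to_numpy(dtype=float)
    except (TypeError, ValueError):
        validity = None
    if validity is None or np.any(np.isnan(validity)):
        unknown = sorted(set(bits) - set(validity_by_bits))
        raise KeyError(f"patterns not in environment: {unknown}")
    n_cues = np.array([sum(int(c) for c in b) for b in bits], dtype=float)
    rt = records["rt"].to_numpy(dtype=float)
    choice = (records["choice"] == POSITIVE).to_numpy(dtype=float)
    return validity, n_cues, rt, choice


def static_loglik_oracle(
    records: pd.DataFrame,
    statics: StaticParams,
    state: LatentState,
    env: Environment,
) -> float:
    """Exact log-likelihood when the latent state is constant over trials
    (the zero-walk-scale limit).  No Monte Carlo is involved."""
    if len(records) == 0:
        return 0.0
    validity, n_cues, rt, choice = design_arrays(records, env)
    v = statics.v0 + state.b_v * validity
    tau = state.tau0 + statics.b_tau * n_cues
    lp = wfpt_logpdf(rt, choice, v, state.a, tau, statics.beta)
    # compensated summation so the zero-noise particle filter can match
    # this value to full float precision
    return float(math.fsum(lp))


@dataclass
class FilterResult:
    """Output of one particle-filter pass."""

    loglik: float
    ess: np.ndarray
    filtered_mean: Optional[np.ndarray]  # (T, 3) columns [b_v, a, tau0]
    filtered_median: Optional[np.ndarray]
    filtered_q05: Optional[np.ndarray]
    filtered_q95: Optional[np.ndarray]
    degenerate: bool
    n_particles: int
    _states_hist: Optional[np.ndarray] = field(default=None, repr=False)
    _ancestors: Optional[np.ndarray] = field(default=None, repr=False)
    _final_weights: Optional[np.ndarray] = field(default=None, repr=False)

    def sample_path(self, rng: np.random.Generator) -> Trajectory:
        """Draw one latent trajectory from the filter's ancestral paths."""
        if self._states_hist is None:
            raise ValueError("filter was run without path storage")
        T = self._states_hist.shape[0]
        j = rng.choice(self.n_particles, p=self._final_weights)
        path = np.empty((T, 3))
        path[T - 1] = self._states_hist[T - 1, j]
        for t in range(T - 2, -1, -1):
            j = self._ancestors[t + 1, j]
            path[t] = self._states_hist[t, j]
        return Trajectory(b_v=path[:, 0], a=path[:, 1], tau0=path[:, 2])


def _systematic_resample(weights: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = weights.size
    positions = (rng.random() + np.arange(n)) / n
    return np.searchsorted(np.cumsum(weights), positions).clip(0, n - 1)


def _weighted_quantiles(x: np.ndarray, w: np.ndarray, qs) -> np.ndarray:
    order = np.argsort(x)
    cw = np.cumsum(w[order])
    cw /= cw[-1]
    return np.interp(qs, cw, x[order])


def particle_filter(
    records: pd.DataFrame,
    statics: StaticParams,
    scales: NoiseScales,
    init: InitPrior,
    env: Environment,
    n_particles: int = 1024,
    rng: Optional[np.random.Generator] = None,
    store_paths: bool = True,
    summarize: bool = True,
    ess_threshold: float = 0.5,
) -> FilterResult:
    """Bootstrap particle filter over the latent random-walk trajectory.

    Systematic resampling is triggered when the effective sample size
    falls below ``ess_threshold * n_particles``.  Total weight collapse
    (all particles at the density floor) is flagged as a degenerate
    result rather than raising.
    """
    if n_particles < 2:
        raise ValueError("n_particles must be >= 2")
    rng = rng if rng is not None else np.random.default_rng()
    validity, n_cues, rt, choice = design_arrays(records, env)
    T = len(rt)
    sig = scales.as_array()

    states = sample_init(init, rng, size=n_particles)  # (N, 3)
    log_w = np.full(n_particles, -np.log(n_particles))
    loglik_terms: list[float] = []
    degenerate = False
    ess = np.empty(T)
    states_hist = np.empty((T, n_particles, 3)) if store_paths else None
    ancestors = np.empty((T, n_particles), dtype=np.int64) if store_paths else None
    qs = (0.05, 0.5, 0.95)
    summ = np.empty((T, 3, 4)) if summarize else None  # mean, q05, q50, q95

    weights = np.exp(log_w)
    for t in range(T):
        if t > 0:
            cur_ess = 1.0 / np.sum(weights**2)
            if cur_ess < ess_threshold * n_particles:
                anc = _systematic_resample(weights, rng)
                states = states[anc]
                log_w = np.full(n_particles, -np.log(n_particles))
            else:
                anc = np.arange(n_particles)
            xi = rng.standard_normal((n_particles, 3))
            states = states + xi * sig
            states[:, 1] = reflect_lower(states[:, 1], A_MIN)
            states[:, 2] = reflect_lower(states[:, 2], TAU0_MIN)
        else:
            anc = np.arange(n_particles)

        v = statics.v0 + states[:, 0] * validity[t]
        tau = states[:, 2] + statics.b_tau * n_cues[t]
        lp = wfpt_logpdf_particles(
            rt[t], choice[t], v, states[:, 1], tau, statics.beta
        )

        lw = log_w + lp
        m = lw.max()
        if m <= LOG_FLOOR + 1.0:
            # weight collapse: observation impossible under all particles
            degenerate = True
            loglik_terms.append(LOG_FLOOR)
            log_w = np.full(n_particles, -np.log(n_particles))
        else:
            log_norm = m + np.log(np.exp(lw - m).sum())
            loglik_terms.append(log_norm)
            log_w = lw - log_norm
        weights = np.exp(log_w)
        ess[t] = 1.0 / np.sum(weights**2)

        if store_paths:
            states_hist[t] = states
            ancestors[t] = anc
        if summarize:
            for c in range(3):
                x = states[:, c]
                summ[t, c, 0] = np.sum(weights * x)
                summ[t, c, 1:] = _weighted_quantiles(x, weights, qs)

    return FilterResult(
        loglik=float(math.fsum(loglik_terms)),
        ess=ess,
        filtered_mean=summ[:, :, 0] if summarize else None,
        filtered_q05=summ[:, :, 1] if summarize else None,
        filtered_median=summ[:, :, 2] if summarize else None,
        filtered_q95=summ[:, :, 3] if summarize else None,
        degenerate=degenerate,
        n_particles=n_particles,
        _states_hist=states_hist,
        _ancestors=ancestors,
        _final_weights=weights / weights.sum(),
    )


@dataclass(frozen=True)
class Priors:
    """Priors for the static parameters and walk scales.

    v0 ~ Normal(0, 1); beta ~ Beta(5, 5); b_tau ~ half-Normal(0.3 s);
    sigma_* ~ half-Normal(0.1).  The init prior for the trial-1 latent
    state is shared with the generative model.
    """

    v0_loc: float = 0.0
    v0_scale: float = 1.0
    beta_a: float = 5.0
    beta_b: float = 5.0
    b_tau_scale: float = 0.3
    sigma_scale: float = 0.1
    init: InitPrior = field(default_factory=InitPrior)

    def log_density(self, theta: np.ndarray) -> float:
        """Log prior density in natural parameter space."""
        v0, b_tau, beta, s_v, s_a, s_t = theta
        if b_tau <= 0 or not 0 < beta < 1 or min(s_v, s_a, s_t) <= 0:
            return -np.inf
        lp = stats.norm.logpdf(v0, self.v0_loc, self.v0_scale)
        lp += stats.halfnorm.logpdf(b_tau, scale=self.b_tau_scale)
        lp += stats.beta.logpdf(beta, self.beta_a, self.beta_b)
        for s in (s_v, s_a, s_t):
            lp += stats.halfnorm.logpdf(s, scale=self.sigma_scale)
        return float(lp)

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        return np.array(
            [
                rng.normal(self.v0_loc, self.v0_scale),
                np.abs(rng.normal(0, self.b_tau_scale)),
                rng.beta(self.beta_a, self.beta_b),
                np.abs(rng.normal(0, self.sigma_scale)),
                np.abs(rng.normal(0, self.sigma_scale)),
                np.abs(rng.normal(0, self.sigma_scale)),
            ]
        )


@dataclass
class FitConfig:
    """PMMH settings.

    Defaults keep 2000 post-burn-in draws — a reporting-granularity
    choice, not an equivalence claim with any other sampler.
    """

    n_particles: int = 512
    n_iter: int = 2500
    burn_in: int = 500
    proposal_scales: np.ndarray = field(
        default_factory=lambda: np.array([0.08, 0.08, 0.15, 0.25, 0.25, 0.25])
    )
    adapt: bool = True
    adapt_interval: int = 50
    target_accept: float = 0.3
    thin: int = 1
    max_init_tries: int = 100

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("n_particles must be >= 2")
        if self.n_iter <= self.burn_in:
            raise ValueError("n_iter must exceed burn_in")


@dataclass
class PosteriorSamples:
    """PMMH output for one participant: static-parameter draws, one
    latent trajectory per kept draw, and chain diagnostics."""

    statics: pd.DataFrame  # columns _PARAM_NAMES, one row per kept draw
    trajectories: np.ndarray  # (n_kept, T, 3) columns [b_v, a, tau0]
    loglik: np.ndarray
    accept_rate: float
    mean_ess: float = float("nan")  # mean filter ESS over accepted runs

    def __len__(self) -> int:
        return len(self.statics)

    def static_params(self, i: int) -> StaticParams:
        row = self.statics.iloc[i]
        return StaticParams(v0=row["v0"], b_tau=row["b_tau"], beta=row["beta"])

    def trajectory(self, i: int) -> Trajectory:
        p = self.trajectories[i]
        return Trajectory(b_v=p[:, 0], a=p[:, 1], tau0=p[:, 2])


def _to_unconstrained(theta: np.ndarray) -> np.ndarray:
    z = theta.copy()
    z[1] = np.log(theta[1])
    z[2] = np.log(theta[2] / (1.0 - theta[2]))
    z[3:] = np.log(theta[3:])
    return z


def _to_natural(z: np.ndarray) -> np.ndarray:
    theta = z.copy()
    theta[1] = np.exp(z[1])
    theta[2] = expit(z[2])
    theta[3:] = np.exp(z[3:])
    return theta


def _log_jacobian(z: np.ndarray) -> float:
    # d(natural)/d(unconstrained): exp for log-scale, p(1-p) for logit
    p = expit(z[2])
    return float(z[1] + np.log(p) + np.log1p(-p) + z[3:].sum())


def moment_theta0(records: pd.DataFrame) -> np.ndarray:
    """Cheap data-driven starting point for PMMH.

    b_tau starts at the OLS slope of rt on n_cues (the decision-time
    component is roughly unrelated to cue count, so the slope mainly
    reflects per-cue encoding time); v0 and beta start neutral and the
    walk scales start small.  Starting in a plausible region avoids the
    pseudo-marginal chain sticking at a prior draw whose likelihood
    estimate happened to be lucky.
    """
    n = records["n_cues"].to_numpy(dtype=float)
    rt = records["rt"].to_numpy(dtype=float)
    slope = np.polyfit(n, rt, 1)[0] if len(records) > 2 and np.ptp(n) > 0 else 0.15
    b_tau = float(np.clip(slope, 0.02, 0.8))
    return np.array([0.0, b_tau, 0.5, 0.05, 0.02, 0.01])


def pmmh(
    records: pd.DataFrame,
    env: Environment,
    priors: Priors,
    config: FitConfig,
    rng: np.random.Generator,
    theta0: Optional[np.ndarray] = None,
) -> PosteriorSamples:
    """Particle-marginal Metropolis–Hastings over statics and walk scales.

    Proposals are independent Gaussian random walks on transformed
    parameters (log for b_tau and the sigmas, logit for beta), with a
    global scale factor adapted during burn-in toward the target
    acceptance rate.  The latent trajectory reported with each draw is
    an ancestral-path sample from the accepted filter run.
    """

    def loglik_and_filter(theta: np.ndarray) -> tuple[float, FilterResult]:
        statics = StaticParams(v0=theta[0], b_tau=theta[1], beta=theta[2])
        scales = NoiseScales(sigma_v=theta[3], sigma_a=theta[4], sigma_tau=theta[5])
        res = particle_filter(
            records,
            statics,
            scales,
            priors.init,
            env,
            n_particles=config.n_particles,
            rng=rng,
            store_paths=True,
            summarize=False,
        )
        return res.loglik, res

    # initialization: data moments first, then prior draws as fallback
    theta = None
    cand = np.asarray(
        theta0 if theta0 is not None else moment_theta0(records), dtype=float
    )
    if np.isfinite(priors.log_density(cand)):
        ll, fres = loglik_and_filter(cand)
        if np.isfinite(ll) and ll > len(records) * LOG_FLOOR / 2:
            theta = cand
    tries = 0
    while theta is None:
        tries += 1
        if tries > config.max_init_tries:
            raise InitializationError(
                "no finite-likelihood initialization found; check data scale"
            )
        cand = priors.sample(rng)
        if not np.isfinite(priors.log_density(cand)):
            continue
        ll, fres = loglik_and_filter(cand)
        if np.isfinite(ll) and ll > len(records) * LOG_FLOOR / 2:
            theta = cand

    z = _to_unconstrained(theta)
    log_post = ll + priors.log_density(theta) + _log_jacobian(z)
    path = fres.sample_path(rng)
    T = len(path)
    ess_accepted = [float(fres.ess.mean())]

    scale_factor = 1.0
    base_scales = np.asarray(config.proposal_scales, dtype=float)
    n_kept = (config.n_iter - config.burn_in) // config.thin
    kept_theta = np.empty((n_kept, 6))
    kept_ll = np.empty(n_kept)
    kept_paths = np.empty((n_kept, T, 3))
    k = 0
    n_accept = 0
    accept_window = 0

    for it in range(config.n_iter):
        z_prop = z + scale_factor * base_scales * rng.standard_normal(6)
        theta_prop = _to_natural(z_prop)
        lp_prior = priors.log_density(theta_prop) + _log_jacobian(z_prop)
        if np.isfinite(lp_prior):
            ll_prop, fres_prop = loglik_and_filter(theta_prop)
            log_post_prop = ll_prop + lp_prior
            if np.log(rng.random()) < log_post_prop - log_post:
                z, theta, ll = z_prop, theta_prop, ll_prop
                log_post = log_post_prop
                path = fres_prop.sample_path(rng)
                ess_accepted.append(float(fres_prop.ess.mean()))
                n_accept += 1
                accept_window += 1

        if config.adapt and it < config.burn_in and (it + 1) % config.adapt_interval == 0:
            rate = accept_window / config.adapt_interval
            scale_factor *= float(np.exp(rate - config.target_accept))
            scale_factor = float(np.clip(scale_factor, 0.05, 20.0))
            accept_window = 0

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0 and k < n_kept:
            kept_theta[k] = theta
            kept_ll[k] = ll
            kept_paths[k, :, 0] = path.b_v
            kept_paths[k, :, 1] = path.a
            kept_paths[k, :, 2] = path.tau0
            k += 1

    return PosteriorSamples(
        statics=pd.DataFrame(kept_theta[:k], columns=_PARAM_NAMES),
        trajectories=kept_paths[:k],
        loglik=kept_ll[:k],
        accept_rate=n_accept / config.n_iter,
        mean_ess=float(np.mean(ess_accepted)),
    )


def posterior_summaries(
    samples_by_participant: Mapping[str, PosteriorSamples],
    conditions: Optional[Mapping[str, str]] = None,
) -> dict:
    """Per-participant posterior medians and across-participant aggregates.

    Returns a dict with:
      - ``statics``: DataFrame, one row per participant, posterior median
        of each static parameter and walk scale;
      - ``trajectories``: dict participant -> DataFrame(trial, b_v, a, tau0)
        of per-trial posterior medians;
      - ``group_statics``: mean and SD of the medians per condition;
      - ``group_trajectories``: per condition and trial, mean and SD of
        the per-trial medians across participants.
    """
    if not samples_by_participant:
        raise ValueError("no posterior samples supplied")
    conditions = conditions or {p: "all" for p in samples_by_participant}

    statics_rows = {}
    traj_medians = {}
    for pid, samples in samples_by_participant.items():
        if len(samples) == 0:
            raise ValueError(f"participant {pid}: empty sample set")
        statics_rows[pid] = samples.statics.median()
        med = np.median(samples.trajectories, axis=0)  # (T, 3)
        traj_medians[pid] = pd.DataFrame(
            {
                "trial": np.arange(1, med.shape[0] + 1),
                "b_v": med[:, 0],
                "a": med[:, 1],
                "tau0": med[:, 2],
            }
        )
    statics = pd.DataFrame(statics_rows).T
    statics.index.name = "participant"

    grp = statics.assign(condition=[conditions[p] for p in statics.index])
    group_statics = grp.groupby("condition").agg(["mean", "std"])

    traj_frames = []
    for pid, df in traj_medians.items():
        d = df.copy()
        d["condition"] = conditions[pid]
        traj_frames.append(d)
    all_traj = pd.concat(traj_frames, ignore_index=True)
    group_trajectories = (
        all_traj.groupby(["condition", "trial"])[["b_v", "a", "tau0"]]
        .agg(["mean", "std"])
        .reset_index()
    )
    return {
        "statics": statics,
        "trajectories": traj_medians,
        "group_statics": group_statics,
        "group_trajectories": group_trajectories,
    }
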