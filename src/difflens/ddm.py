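"""Trial-level Wiener decision process.

A single trial is modelled as Brownian motion with drift v and unit
diffusion coefficient between absorbing boundaries at 0 and a, starting
at beta * a.  Hitting the upper boundary means choosing the positive
outcome (truth/win); the lower boundary means the negative outcome.
Observed response time is first-passage time plus a non-decision time
tau.  Drift on a trial is linear in the signed ecological validity of
the presented cue pattern, and non-decision time is linear in the
number of presented cues:

    v_t   = v0 + b_v * (P(positive | pattern) - 0.5)
    tau_t = tau0 + b_tau * n_cues

The joint density of (choice, rt) is the defective Wiener
first-passage-time (WFPT) density, evaluated with the standard
small-time / large-time series expansions, switching by the usual
accuracy criterion at a per-term truncation tolerance of 1e-7.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

__all__ = [
    "CHOICE_UPPER",
    "CHOICE_LOWER",
    "LOG_FLOOR",
    "TrialParams",
    "StaticParams",
    "BehavioralObservation",
    "drift_for_trial",
    "ndt_for_trial",
    "wfpt_logpdf",
    "wfpt_logpdf_particles",
    "wfpt_log_density",
    "wfpt_pdf_grid",
    "wfpt_cdf_grid",
    "first_passage_choice_prob",
    "simulate_first_passage",
    "simulate_first_passage_batch",
]

#: Choice codes: upper boundary = positive outcome, lower = negative.
CHOICE_UPPER = 1
CHOICE_LOWER = 0

#: Log-density floor returned for impossible observations (rt <= tau)
#: and used to clip underflow, so downstream weight arithmetic stays finite.
LOG_FLOOR = -700.0

_SERIES_ERR = 1e-7


@dataclass(frozen=True)
class TrialParams:
    """Wiener process parameters for one trial (diffusion coefficient 1,
    time in seconds)."""

    v: float
    a: float
    tau: float
    beta: float

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("boundary separation a must be > 0")
        if not 0.0 < self.beta < 1.0:
            raise ValueError("relative starting point beta must be in (0, 1)")
        if self.tau < 0:
            raise ValueError("non-decision time tau must be >= 0")


@dataclass(frozen=True)
class StaticParams:
    """Time-invariant parameters: base drift v0 (evidence/s), per-cue
    non-decision increment b_tau (s/cue), starting point beta."""

    v0: float
    b_tau: float
    beta: float

    def __post_init__(self) -> None:
        if self.b_tau < 0:
            raise ValueError("b_tau must be >= 0")
        if not 0.0 < self.beta < 1.0:
            raise ValueError("beta must be in (0, 1)")


@dataclass(frozen=True)
class BehavioralObservation:
    """One trial's data: boundary choice and response time in seconds."""

    choice: int
    rt: float

    def __post_init__(self) -> None:
        if self.choice not in (CHOICE_UPPER, CHOICE_LOWER):
            raise ValueError("choice must be CHOICE_UPPER or CHOICE_LOWER")
        if self.rt <= 0:
            raise ValueError("rt must be > 0")


def drift_for_trial(v0: float, b_v: float, validity: float) -> float:
    """Trial drift rate: base drift plus sensitivity times signed validity."""
    return v0 + b_v * validity


def ndt_for_trial(tau0, b_tau, n_cues):
    """Trial non-decision time: base plus a per-cue encoding increment."""
    if np.any(np.asarray(tau0) < 0) or np.any(np.asarray(b_tau) < 0):
        raise ValueError("tau0 and b_tau must be >= 0")
    return tau0 + b_tau * n_cues


def _f0_lower(u: np.ndarray, w: np.ndarray, err: float) -> np.ndarray:
    """Density of first passage through 0 for a zero-drift unit-boundary
    Wiener process started at relative position w, at normalized time u,
    via whichever of the small-time / large-time series needs fewer terms."""
    f = np.empty_like(u)
    sqrt_u = np.sqrt(u)

    # terms needed by each expansion to reach the truncation tolerance;
    # when the log argument exceeds 1 the max(., 0) collapses to the
    # expansion's minimum term count
    arg_s = (2.0 * np.sqrt(2.0 * np.pi)) * sqrt_u * err
    ks = 2.0 + np.sqrt(np.maximum(-2.0 * u * np.log(arg_s), 0.0))
    ks = np.maximum(ks, sqrt_u + 1.0)
    arg_l = np.pi * u * err
    kl = np.sqrt(np.maximum(-2.0 * np.log(arg_l), 0.0)) / (np.pi * sqrt_u)
    kl = np.maximum(kl, 1.0 / (np.pi * sqrt_u))

    # per-element term counts, so a value never depends on what else is
    # in the evaluation batch (oracle/filter equivalence to float precision)
    small = ks < kl
    if np.any(small):
        us, ws = u[small], w[small]
        n_s = np.ceil(ks[small]).astype(np.int64)
        n_max = int(min(n_s.max(), 64))
        acc = np.zeros_like(us)
        # nested term ordering k = 0, 1, -1, 2, -2, ... matches the
        # symmetric ranges used for every fixed term count
        for j in range(n_max):
            k = (j + 1) // 2 if j % 2 else -((j + 1) // 2)
            wk = ws + 2.0 * k
            term = wk * np.exp(-wk * wk / (2.0 * us))
            acc += np.where(n_s > j, term, 0.0)
        f[small] = acc / np.sqrt(2.0 * np.pi * us**3)
    large = ~small
    if np.any(large):
        ul, wl = u[large], w[large]
        n_l = np.ceil(kl[large]).astype(np.int64)
        n_max = int(min(n_l.max(), 512))
        acc = np.zeros_like(ul)
        for k in range(1, n_max + 1):
            term = k * np.exp(-(k**2) * np.pi**2 * ul / 2.0) * np.sin(k * np.pi * wl)
            acc += np.where(n_l >= k, term, 0.0)
        f[large] = np.pi * acc
    return np.maximum(f, 0.0)


def wfpt_logpdf(rt, choice, v, a, tau, beta, err: float = _SERIES_ERR,
                log_floor: float = LOG_FLOOR) -> np.ndarray:
    """Log of the defective joint density of (choice, rt).

    All arguments broadcast; returns an array of the broadcast shape
    (0-d inputs give a 0-d array).  Observations with rt <= tau get the
    log floor rather than raising, so that likelihood code can treat
    impossible data as (numerically) zero-density events.
    """
    rt, choice, v, a, tau, beta = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (rt, choice, v, a, tau, beta))
    )
    out = np.full(rt.shape, log_floor)
    t = rt - tau
    ok = (t > 0) & (a > 0) & (beta > 0) & (beta < 1)
    if not np.any(ok):
        return out if out.ndim else out[()]

    t = t[ok]
    up = choice[ok] == CHOICE_UPPER
    # upper-boundary density is the lower-boundary density of the
    # mirrored process (v -> -v, beta -> 1 - beta)
    vv = np.where(up, -v[ok], v[ok])
    w = np.where(up, 1.0 - beta[ok], beta[ok])
    aa = a[ok]
    u = t / aa**2

    f0 = _f0_lower(u, w, err)
    logf = np.log(np.maximum(f0, 1e-300))
    logpdf = logf - vv * aa * w - vv**2 * t / 2.0 - 2.0 * np.log(aa)
    out[ok] = np.maximum(logpdf, log_floor)
    return out if out.ndim else out[()]


def _logpdf_particles_np(rt, choice, v, a, tau, beta, err, log_floor):
    t = rt - tau
    if choice == CHOICE_UPPER:
        vv = -v
        w = 1.0 - beta
    else:
        vv = v
        w = beta
    bad = t <= 0.0
    any_bad = bool(np.any(bad))
    if any_bad:
        t = np.where(bad, 1.0, t)
    u = t / (a * a)
    f0 = _f0_lower(u, np.broadcast_to(np.asarray(w), u.shape), err)
    logpdf = (
        np.log(np.maximum(f0, 1e-300)) - vv * a * w - vv * vv * t * 0.5
        - 2.0 * np.log(a)
    )
    out = np.maximum(logpdf, log_floor)
    if any_bad:
        out[bad] = log_floor
    return out


try:  # optional acceleration; the numpy path is the reference
    import math as _math

    import numba as _numba

    @_numba.njit(cache=False)
    def _logpdf_particles_nb(rt, choice_upper, v, a, tau, beta, err, log_floor):
        n = v.shape[0]
        out = np.empty(n)
        c_small = 2.0 * _math.sqrt(2.0 * _math.pi)
        pi2 = _math.pi**2
        for i in range(n):
            t = rt - tau[i]
            if t <= 0.0:
                out[i] = log_floor
                continue
            if choice_upper:
                vv = -v[i]
                w = 1.0 - beta
            else:
                vv = v[i]
                w = beta
            aa = a[i]
            u = t / (aa * aa)
            sqrt_u = _math.sqrt(u)
            arg_s = c_small * sqrt_u * err
            ks = 2.0 + _math.sqrt(max(-2.0 * u * _math.log(arg_s), 0.0))
            ks = max(ks, sqrt_u + 1.0)
            arg_l = _math.pi * u * err
            kl = _math.sqrt(max(-2.0 * _math.log(arg_l), 0.0)) / (_math.pi * sqrt_u)
            kl = max(kl, 1.0 / (_math.pi * sqrt_u))
            if ks < kl:
                n_s = min(int(_math.ceil(ks)), 64)
                acc = 0.0
                for j in range(n_s):
                    k = (j + 1) // 2 if j % 2 else -((j + 1) // 2)
                    wk = w + 2.0 * k
                    acc += wk * _math.exp(-wk * wk / (2.0 * u))
                f0 = acc / _math.sqrt(2.0 * _math.pi * u**3)
            else:
                n_l = min(int(_math.ceil(kl)), 512)
                acc = 0.0
                for k in range(1, n_l + 1):
                    acc += (
                        k * _math.exp(-(k**2) * pi2 * u / 2.0)
                        * _math.sin(k * _math.pi * w)
                    )
                f0 = _math.pi * acc
            if f0 < 1e-300:
                f0 = 1e-300
            lp = (
                _math.log(f0) - vv * aa * w - vv * vv * t * 0.5
                - 2.0 * _math.log(aa)
            )
            out[i] = lp if lp > log_floor else log_floor
        return out

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional extra
    _HAVE_NUMBA = False


def wfpt_logpdf_particles(
    rt: float,
    choice: float,
    v: np.ndarray,
    a: np.ndarray,
    tau: np.ndarray,
    beta: float,
    err: float = _SERIES_ERR,
    log_floor: float = LOG_FLOOR,
) -> np.ndarray:
    """Fast path for particle filters: scalar observation, array params.

    Same value as :func:`wfpt_logpdf` (to the last unit of precision of
    the platform libm), skipping broadcasting and validity plumbing
    (beta is assumed in (0, 1), a > 0).
    """
    if _HAVE_NUMBA:
        return _logpdf_particles_nb(
            float(rt),
            choice == CHOICE_UPPER,
            np.ascontiguousarray(v, dtype=float),
            np.ascontiguousarray(a, dtype=float),
            np.ascontiguousarray(tau, dtype=float),
            float(beta),
            err,
            log_floor,
        )
    return _logpdf_particles_np(rt, choice, v, a, tau, beta, err, log_floor)


def wfpt_log_density(obs: BehavioralObservation, params: TrialParams) -> float:
    """Scalar convenience wrapper over :func:`wfpt_logpdf`."""
    return float(
        wfpt_logpdf(obs.rt, obs.choice, params.v, params.a, params.tau, params.beta)
    )


def wfpt_pdf_grid(rt_grid: np.ndarray, choice: int, params: TrialParams) -> np.ndarray:
    """Defective density evaluated on an rt grid (zero where rt <= tau)."""
    lp = wfpt_logpdf(rt_grid, choice, params.v, params.a, params.tau, params.beta)
    pdf = np.exp(lp)
    pdf[np.asarray(rt_grid) <= params.tau] = 0.0
    return pdf


def wfpt_cdf_grid(rt_grid: np.ndarray, choice: int, params: TrialParams) -> np.ndarray:
    """Defective CDF on a grid, by trapezoidal integration of the density.

    The grid should start at or below params.tau and be fine enough for
    the intended accuracy; this is a diagnostic/oracle helper, not a
    high-precision quadrature.
    """
    pdf = wfpt_pdf_grid(rt_grid, choice, params)
    from scipy.integrate import cumulative_trapezoid

    return cumulative_trapezoid(pdf, rt_grid, initial=0.0)


def first_passage_choice_prob(v: float, a: float, beta: float) -> float:
    """Probability of absorption at the upper boundary.

    Standard two-barrier result; continuous at v = 0 where it equals
    beta (evaluated via the analytic limit, not the 0/0 formula).
    """
    if a <= 0 or not 0.0 < beta < 1.0:
        raise ValueError("require a > 0 and 0 < beta < 1")
    x = -2.0 * v * a
    if abs(x) < 1e-10:
        return float(beta)
    if x < 0:  # positive drift: expm1 arguments negative, no overflow
        return float(np.expm1(x * beta) / np.expm1(x))
    if x > 700.0:  # strong negative drift: asymptotic tail
        return float(np.exp(x * beta - x))
    return float(np.expm1(x * beta) / np.expm1(x))


def simulate_first_passage_batch(
    v,
    a,
    tau,
    beta,
    rng: np.random.Generator,
    dt: float = 1e-3,
    max_decision_time: float = 120.0,
):
    """Euler–Maruyama simulation of many independent trials at once.

    Parameters broadcast to a common shape.  Returns (choice, rt)
    arrays.  The discrete step introduces a small positive bias in
    first-passage times of order sqrt(dt); use dt = 1e-4 when comparing
    against the analytic density.
    """
    v, a, tau, beta = np.broadcast_arrays(
        *(np.atleast_1d(np.asarray(x, dtype=float)) for x in (v, a, tau, beta))
    )
    n = v.size
    v, a, tau, beta = (x.ravel().copy() for x in (v, a, tau, beta))
    x = beta * a
    t_dec = np.zeros(n)
    choice = np.full(n, -1, dtype=np.int64)
    active = np.arange(n)
    sqrt_dt = np.sqrt(dt)
    max_steps = int(max_decision_time / dt)
    for _ in range(max_steps):
        if active.size == 0:
            break
        x[active] += v[active] * dt + sqrt_dt * rng.standard_normal(active.size)
        t_dec[active] += dt
        hit_up = x[active] >= a[active]
        hit_lo = x[active] <= 0.0
        done = hit_up | hit_lo
        if np.any(done):
            idx = active[done]
            choice[idx] = np.where(hit_up[done], CHOICE_UPPER, CHOICE_LOWER)
            active = active[~done]
    if active.size:  # walkers still unabsorbed at the cap: resolve by position
        choice[active] = np.where(
            x[active] >= beta[active] * a[active], CHOICE_UPPER, CHOICE_LOWER
        )
    rt = tau + t_dec
    return choice, rt


def simulate_first_passage(
    params: TrialParams, rng: np.random.Generator, dt: float = 1e-3
) -> BehavioralObservation:
    """Simulate a single trial; rt is strictly greater than tau."""
    choice, rt = simulate_first_passage_batch(
        params.v, params.a, params.tau, params.beta, rng, dt=dt
    )
    return BehavioralObservation(choice=int(choice[0]), rt=float(rt[0]))
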