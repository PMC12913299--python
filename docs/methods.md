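# Methods

## Model

`difflens` implements a two-level stochastic model of probabilistic
inference in multiple-cue probability learning (MCPL, the "weather
prediction" family of tasks). On every trial the participant sees a
pattern of 1–3 of 4 binary cues and predicts a binary outcome
(positive = truth/win, negative = lie/loss) under trial-by-trial
feedback.

**Low level (within trial).** Choice and response time arise from a
Wiener diffusion process with unit diffusion coefficient between
absorbing boundaries at 0 and `a`, starting at `beta * a`. The upper
boundary is identified with the positive outcome. Two structural maps
tie the process to the task:

    v_t   = v0 + b_v[t] * (P(positive | pattern_t) - 0.5)
    tau_t = tau0[t] + b_tau * n_cues_t

The drift regressor is the *signed* ecological validity of the
presented pattern, centred at chance, so `b_v` measures how strongly
evidence uptake is aligned with the environment; `v0` is a residual
dynamic bias; `b_tau` is the per-cue encoding cost in seconds; the
starting point `beta` captures an a priori outcome bias. The signed
centring `P - 0.5` is one of several possible scalings of "cue
validity" (the unsigned and doubled variants only rescale `b_v`); the
absolute value `|P - 0.5|` is used for grouping in summaries, never in
the drift map.

**High level (across trials).** Three low-level parameters follow
independent Gaussian random walks:

    b_v[t]  = b_v[t-1]  + sigma_v  * xi,   xi ~ N(0, 1)
    a[t]    = a[t-1]    + sigma_a  * xi
    tau0[t] = tau0[t-1] + sigma_tau * xi

This superstatistical construction deliberately imposes *no* learning
rule: uncertainty reduction is something the fitted trajectory of
`b_v` can reveal, not something built in. The three innovation streams
are independent; a shared innovation would perfectly correlate the
walks, which is not the intended reading of a random walk per
parameter.

Boundary separation is kept at `a >= 0.1` and base non-decision time
at `tau0 >= 0` by *reflection* at the bound. Clipping would create
sticky boundaries that deflate the walk variance near the bound;
reflection preserves innovation magnitude (|reflected − bound| =
|proposed − bound|). Whether the original formulation constrained
these parameters by transform (e.g. log-scale walks) is not
documented; reflection is this package's choice. `b_v` is unbounded —
negative values early in learning represent evidence sampling from
invalid cues.

**Trial-1 priors** (config-overridable defaults): `b_v,1 ~ N(0, 0.5)`
(initial absence of cue knowledge), `a_1 ~ N(1.5, 0.5)` truncated at
0.1, `tau0_1 ~ N(0.3, 0.1)` truncated at 0. Units: evidence/s per unit
validity, evidence units, and seconds, respectively.

## Canonical environment

The canonical environment is the published 14-pattern design: each of
the 2^4 − 2 admissible patterns (all-present and all-absent excluded)
has a fixed per-session count over 246 trials, a designed conditional
outcome probability, and realized outcome counts. For four patterns
the printed designed probability differs from the realized relative
frequency (the frequency table was fixed by design before any
session); the package stores both. `exact_counts` sequence generation
permutes the realized counts (a session is a deterministic multiset in
random order); `iid` sampling uses the designed probabilities. The
marginal validities of the four cues recompute to 0.805, 0.602, 0.398,
0.203 — the designed 0.8/0.6/0.4/0.2 up to integer-count granularity —
which fixes the cue-position ordering.

## First-passage density and simulator

The defective joint density of (choice, rt) is evaluated by the
standard small-time / large-time series for the Wiener first-passage
problem, switching per evaluation by the usual fewest-terms criterion
at a truncation tolerance of 1e-7. Term counts are decided
*per element*, with a nested term ordering (k = 0, 1, −1, 2, −2, …),
so a density value never depends on what else is in the evaluation
batch — this is what lets the particle filter reproduce the
closed-form static log-likelihood exactly (see below). Log-densities
are floored at −700; observations with `rt <= tau` receive the floor
rather than raising, so likelihood code treats impossible data as
zero-density events. Both likelihood routes accumulate per-trial terms
with compensated summation (`math.fsum`).

A numba-compiled kernel evaluates the particle-weight densities when
numba is importable; the pure-numpy implementation is the reference,
and a test pins the two to each other at 1e-12. Without numba the
package runs identically, slower.

The trial simulator is Euler–Maruyama with default step 1e-3 s.
Discretization biases first-passage times upward by O(sqrt(dt))
(missed within-step crossings, effectively a slightly wider boundary);
at dt = 1e-3 this is about a 1% inflation of decision times. Tests
that compare the simulator against the analytic density, and data
generated for inference-validation studies, use finer steps (1e-4 and
2e-4) so simulator bias stays below the estimation error being
measured. The analytic two-barrier absorption probability is evaluated
via `expm1` with the `v -> 0` limit returned analytically (`beta`),
avoiding the 0/0 form.

## Inference

The latent trajectory is integrated out by a bootstrap particle filter
(the proposal is the transition itself), with systematic resampling
when ESS < N/2 and an unbiased-in-expectation marginal-likelihood
estimate. Total weight collapse is reported as a flagged degenerate
result, not an exception. In the limit of zero walk scales and a
degenerate initial state the filter's log marginal likelihood equals
the closed-form static Wiener log-likelihood to better than 1e-10 —
the stochastic machinery is anchored to an exact oracle.

Static parameters (v0, b_tau, beta) and walk scales (sigma_v, sigma_a,
sigma_tau) are sampled by particle-marginal Metropolis–Hastings:
joint Gaussian random-walk proposals on transformed parameters (log
for b_tau and the scales, logit for beta), with a global proposal
factor adapted during burn-in toward ~30% acceptance. Priors
(config-overridable): v0 ~ N(0, 1), beta ~ Beta(5, 5),
b_tau ~ half-N(0.3), each sigma ~ half-N(0.1). Chains start from a
data-moment point (b_tau from the OLS slope of rt on n_cues, neutral
v0 and beta, small scales) rather than a prior draw: pseudo-marginal
chains can stick for a long time at a poor draw whose likelihood
estimate happened to be high, and a moment start avoids that failure
mode. Participants are fit independently; there is no hierarchical
pooling.

Latent-trajectory posteriors are ancestral-path samples from the
accepted filter runs. Paths near t = 1 are degenerate (few surviving
ancestral lines), so the first few trials of estimated trajectories
should not be over-interpreted.

Default chain settings keep 2000 draws after 500 burn-in iterations at
512 particles (a reporting-granularity choice). The recovery studies in the test suite and acceptance
script run 1200–1500 iterations at 512 particles, and 5–10 simulated
participants — sizes chosen so a full study completes in minutes on a
single core while leaving the qualitative conclusions (coverage,
trajectory correlation) stable across seeds.

## Synthetic data

The generator composes the environment, the latent dynamics, and the
trial simulator. Defaults mirror the validated study conditions: 246
trials per participant with the exact designed pattern/outcome counts,
statics (v0 = 0, b_tau = 0.15 s/cue, beta = 0.5) matching the
qualitative fitted pattern reported for real data (near-zero dynamic
bias, ~150 ms encoding cost per cue, at most a small positivity bias),
and random-walk latents from the trial-1 priors above.

Condition presets (`congruent` / `incongruent`) are deterministic
fixture trajectories, not empirical claims: a saturating-exponential
rise of `b_v` (asymptote 6.0 reached with time constant 60 trials for
congruent; 3.5 and 100 for incongruent — values chosen to put drifts
and accuracies in the plausible range for this task) and exponential
decays of `a` (1.8 → 1.2) and `tau0` (0.40 s → 0.28 s), mirroring
practice effects. The preset start values lie inside the support of
the trial-1 priors so that recovery studies are not confounded by a
deliberate prior–data conflict at t = 1. Parameter-recovery claims use
these known trajectories (or random-walk draws); presets exist to
emulate condition-contrast learning-curve shapes for integration
tests.

What the generator does *not* emulate: the salience/trustworthiness
mechanism that produces congruence effects (conditions enter only as
preset shapes and labels), across-trial variability parameters of the
full Ratcliff diffusion model (sv, st0, sz), contaminant/lapse
responses, and any dependence of outcomes on the participant's
choices. Passing recovery tests therefore show the inference machinery
works for data generated by this model family — not that the model is
true of human data.

## Diagnostics and baselines

Accuracy is scored as choice = realized feedback outcome
(feedback-consistent scoring, the natural score under probabilistic
feedback); scoring against the more likely outcome per pattern is
available as an option. Summary tables group patterns by
|P(positive|pattern) − 0.5| rounded to 3 decimals, which yields seven
levels in the canonical environment ({0, .046, .273, .300, .406, .413,
.437}); note the designed probability 0.227 corresponds to the *level*
0.273. RT summaries default to correct trials only (mean correct RT is
the tabled convention); cells with no correct trials are flagged
missing, not zero. Learning curves are smoothed with a trailing moving
average (default lag 20, truncated at the series head); a centered
window is available via `smoothed_series(center=True)`.

Posterior re-simulation draws 500 posterior samples per participant by
default and forward-simulates a fresh session per draw, aggregating
median/mean/SD of RT and accuracy per validity level and condition.

Two baseline formalisms are included for reference. The lens model
equation `r_a = G·Re·Ri + C·sqrt((1−Re²)(1−Ri²))` is evaluated as an
identity given its components (estimating the components from data by
regression is out of scope). Take-the-best is adapted from paired
comparison to single-profile prediction: present cues are examined in
descending |marginal validity − 0.5|; a cue discriminates if its
marginal validity departs from 0.5 by more than 1e-6; opposing cues
whose extremities differ by at most 0.01 cancel and fall through (the
strongest positive and negative cues recompute to 0.805 and 0.203 only
because realized counts are integers — they implement one designed
symmetric validity level); with nothing discriminating, the prediction
is a uniform guess.

## Numerical and design choices at a glance

- Diffusion coefficient fixed at 1; time in seconds; upper boundary =
  positive outcome.
- Density series tolerance 1e-7 per term; log floor −700; per-element
  term counts; compensated summation of log-likelihoods.
- Euler step default 1e-3 s (configurable); finer steps for
  density-vs-simulator comparisons and recovery-study data.
- Latent bounds a >= 0.1, tau0 >= 0 enforced by reflection.
- Pattern bits serialize as a fixed-width 0/1 string, leftmost = cue 1;
  printed-value comparisons and serialized RTs round to 3 decimals,
  ties away from zero.
- Master seeds expand into named substreams (simulate / fit / resim)
  so pipeline stages can be re-run independently and reproducibly.

## Known limitations

- PMMH at desk-scale settings yields hundreds of effectively
  independent draws, not thousands; extreme posterior quantiles are
  noisy at default settings.
- Ancestral-path trajectory samples degenerate near t = 1 (see above).
- The Euler simulator is biased at coarse steps; use the analytic
  density, not simulation, for likelihood work.
- The environment module ships only the canonical 4-cue design;
  arbitrary environments can be constructed via `Environment.from_frame`
  but no naive-Bayes recipe from single-cue validities is provided
  (any such reconstruction would be speculative).
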