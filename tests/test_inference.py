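import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import logsumexp

from difflens import (
    FitConfig,
    PosteriorSamples,
    Priors,
    StaticParams,
    Trajectory,
    particle_filter,
    pmmh,
    posterior_summaries,
    preset_trajectory,
    simulate_participant,
    static_loglik_oracle,
)
from difflens.ddm import wfpt_log_density, wfpt_logpdf, BehavioralObservation, TrialParams
from difflens.inference import design_arrays, moment_theta0
from difflens.superstatistics import InitPrior, LatentState, NoiseScales


STATICS = StaticParams(v0=0.0, b_tau=0.15, beta=0.5)
STATE = LatentState(b_v=4.0, a=1.5, tau0=0.3)


@pytest.fixture(scope="module")
def static_data(env):
    rng = np.random.default_rng(42)
    return simulate_participant(
        env, STATICS, Trajectory.constant(STATE, 246), rng
    )


@pytest.fixture(scope="module")
def short_static_data(env):
    rng = np.random.default_rng(43)
    return simulate_participant(
        env, STATICS, Trajectory.constant(STATE, 246), rng
    ).head(60)


@pytest.fixture(scope="module")
def tiny_static_data(short_static_data):
    # short enough that a zero-noise filter (pure importance sampling
    # from the init prior) keeps its weights under control
    return short_static_data.head(30)


class TestStaticLoglikOracle:
    def test_empty_records_give_zero(self, env, static_data):
        assert static_loglik_oracle(static_data.iloc[0:0], STATICS, STATE, env) == 0.0

    def test_single_trial_equals_trial_density(self, env, static_data):
        one = static_data.iloc[[0]]
        validity, n_cues, rt, choice = design_arrays(one, env)
        obs = BehavioralObservation(choice=int(choice[0]), rt=float(rt[0]))
        params = TrialParams(
            v=STATICS.v0 + STATE.b_v * validity[0],
            a=STATE.a,
            tau=STATE.tau0 + STATICS.b_tau * n_cues[0],
            beta=STATICS.beta,
        )
        assert static_loglik_oracle(one, STATICS, STATE, env) == pytest.approx(
            wfpt_log_density(obs, params), abs=1e-12
        )

    def test_matches_bruteforce_summation(self, env, static_data):
        import math

        validity, n_cues, rt, choice = design_arrays(static_data, env)
        terms = [
            float(
                wfpt_logpdf(
                    rt[t], choice[t],
                    STATICS.v0 + STATE.b_v * validity[t],
                    STATE.a,
                    STATE.tau0 + STATICS.b_tau * n_cues[t],
                    STATICS.beta,
                )
            )
            for t in range(len(rt))
        ]
        brute = math.fsum(terms)
        assert static_loglik_oracle(static_data, STATICS, STATE, env) == pytest.approx(
            brute, abs=1e-10
        )


class TestParticleFilter:
    def test_static_limit_equals_oracle_exactly(self, env, static_data):
        init = InitPrior(
            b_v_loc=STATE.b_v, b_v_scale=0.0, a_loc=STATE.a, a_scale=0.0,
            tau0_loc=STATE.tau0, tau0_scale=0.0,
        )
        res = particle_filter(
            static_data, STATICS, NoiseScales(0, 0, 0), init, env,
            n_particles=64, rng=np.random.default_rng(1),
        )
        oracle = static_loglik_oracle(static_data, STATICS, STATE, env)
        assert abs(res.loglik - oracle) < 1e-10

    def test_diffuse_init_matches_quadrature(self, env, tiny_static_data):
        """With zero walk scales the filter estimates the init-integrated
        likelihood; a tensor-grid quadrature over the 3-D init prior is
        the independent oracle."""
        prior = InitPrior()
        validity, n_cues, rt, choice = design_arrays(tiny_static_data, env)

        # Gauss-Hermite for the unbounded b_v, equal-probability midpoints
        # for the truncated a and tau0 components
        gh_x, gh_w = np.polynomial.hermite_e.hermegauss(40)
        bv_nodes = prior.b_v_loc + prior.b_v_scale * gh_x
        bv_logw = np.log(gh_w) - np.log(np.sqrt(2 * np.pi))
        n_q = 24
        probs = (np.arange(n_q) + 0.5) / n_q
        a_std = (prior.a_min - prior.a_loc) / prior.a_scale
        a_nodes = stats.truncnorm.ppf(probs, a_std, np.inf,
                                      loc=prior.a_loc, scale=prior.a_scale)
        t_std = (prior.tau0_min - prior.tau0_loc) / prior.tau0_scale
        t_nodes = stats.truncnorm.ppf(probs, t_std, np.inf,
                                      loc=prior.tau0_loc, scale=prior.tau0_scale)

        aa, tt = np.meshgrid(a_nodes, t_nodes, indexing="ij")
        aa, tt = aa.ravel()[:, None], tt.ravel()[:, None]
        pieces = []
        for bv, lw in zip(bv_nodes, bv_logw):
            v = STATICS.v0 + bv * validity[None, :]
            tau = tt + STATICS.b_tau * n_cues[None, :]
            ll = wfpt_logpdf(rt[None, :], choice[None, :], v, aa, tau, STATICS.beta)
            pieces.append(lw + logsumexp(ll.sum(axis=1)) - np.log(aa.size))
        quad_ll = logsumexp(pieces)

        rng = np.random.default_rng(9)
        estimates = np.array(
            [
                particle_filter(
                    tiny_static_data, STATICS, NoiseScales(0, 0, 0), prior, env,
                    n_particles=2048, rng=rng, store_paths=False, summarize=False,
                ).loglik
                for _ in range(20)
            ]
        )
        assert estimates.std() < 1.0
        assert abs(estimates.mean() - quad_ll) < 3 * max(estimates.std(), 0.05)

    def test_variance_shrinks_with_more_particles(self, env, short_static_data):
        prior = InitPrior()
        scales = NoiseScales(0.05, 0.01, 0.005)
        rng = np.random.default_rng(2)

        def spread(n):
            return np.std(
                [
                    particle_filter(
                        short_static_data, STATICS, scales, prior, env,
                        n_particles=n, rng=rng, store_paths=False, summarize=False,
                    ).loglik
                    for _ in range(8)
                ]
            )

        assert spread(4096) < spread(512)

    def test_loglik_favors_true_sensitivity_sign(self, env):
        """On data with strong positive sensitivity, the marginal likelihood
        at the true parameters beats the sign-flipped alternative."""
        rng = np.random.default_rng(77)
        data = simulate_participant(
            env, STATICS, Trajectory.constant(LatentState(6.0, 1.5, 0.3), 246),
            rng,
        ).head(120)
        scales = NoiseScales(0.02, 0.005, 0.002)
        wins = 0
        for rep in range(20):
            lls = []
            for loc in (6.0, -6.0):
                init = InitPrior(b_v_loc=loc, b_v_scale=0.3)
                res = particle_filter(
                    data, STATICS, scales, init, env, n_particles=256,
                    rng=np.random.default_rng(1000 + rep),
                    store_paths=False, summarize=False,
                )
                lls.append(res.loglik)
            wins += lls[0] > lls[1]
        assert wins >= 18

    def test_tracks_rising_sensitivity(self, env):
        truth = preset_trajectory("congruent", 246)
        data = simulate_participant(
            env, STATICS, truth, np.random.default_rng(5)
        )
        res = particle_filter(
            data, STATICS, NoiseScales(0.15, 0.02, 0.01), InitPrior(), env,
            n_particles=1024, rng=np.random.default_rng(6),
        )
        rmse_filter = np.sqrt(np.mean((res.filtered_median[:, 0] - truth.b_v) ** 2))
        rmse_prior = np.sqrt(np.mean((InitPrior().b_v_loc - truth.b_v) ** 2))
        assert rmse_filter < rmse_prior
        assert np.all(res.ess >= 1) and np.all(res.ess <= 1024)

    def test_weight_collapse_flagged_not_raised(self, env, short_static_data):
        data = short_static_data.copy()
        data.iloc[0, data.columns.get_loc("rt")] = 0.05  # impossible under any tau
        res = particle_filter(
            data, StaticParams(v0=0.0, b_tau=0.2, beta=0.5),
            NoiseScales(0.05, 0.01, 0.005), InitPrior(), env,
            n_particles=128, rng=np.random.default_rng(3),
        )
        assert res.degenerate
        assert np.isfinite(res.loglik)


class TestPMMH:
    def test_seed_reproducibility(self, env, short_static_data):
        config = FitConfig(n_particles=64, n_iter=30, burn_in=10)
        runs = [
            pmmh(short_static_data, env, Priors(), config, np.random.default_rng(4))
            for _ in range(2)
        ]
        pd.testing.assert_frame_equal(runs[0].statics, runs[1].statics)
        np.testing.assert_array_equal(runs[0].trajectories, runs[1].trajectories)

    def test_static_data_concentrates_scales(self, env):
        """Data generated with constant latent parameters (drawn from a
        state the trial-1 prior supports) pull the walk-scale posteriors
        toward zero: across participants, the typical posterior median
        of every scale falls below twice the prior's lower quartile.

        The latent state must be init-prior-consistent: when the static
        state lies far outside the trial-1 prior, the marginal
        likelihood genuinely prefers a nonzero walk scale, because the
        walk is the only route from the prior to the data-supported
        region.
        """
        state = LatentState(b_v=0.5, a=1.5, tau0=0.3)
        config = FitConfig(n_particles=384, n_iter=700, burn_in=250)
        medians = []
        for seed in (12, 13, 14):
            data = simulate_participant(
                env, STATICS, Trajectory.constant(state, 246),
                np.random.default_rng(40 + seed),
            )
            samples = pmmh(data, env, Priors(), config, np.random.default_rng(seed))
            medians.append(
                samples.statics[["sigma_v", "sigma_a", "sigma_tau"]].median()
            )
        typical = pd.concat(medians, axis=1).median(axis=1)
        threshold = 2 * stats.halfnorm.ppf(0.25, scale=0.1)
        assert (typical < threshold).all(), typical

    def test_moment_init_is_plausible(self, static_data):
        theta0 = moment_theta0(static_data)
        assert 0.02 <= theta0[1] <= 0.8
        assert theta0[2] == 0.5


class TestPosteriorSummaries:
    @staticmethod
    def _toy_samples(values, T=4):
        statics = pd.DataFrame(
            {
                "v0": values, "b_tau": values, "beta": [0.5] * len(values),
                "sigma_v": values, "sigma_a": values, "sigma_tau": values,
            }
        )
        trajectories = np.stack(
            [np.full((T, 3), v, dtype=float) for v in values]
        )
        return PosteriorSamples(
            statics=statics, trajectories=trajectories,
            loglik=np.zeros(len(values)), accept_rate=0.3,
        )

    def test_identical_samples_return_that_sample(self):
        s = self._toy_samples([0.2, 0.2, 0.2])
        out = posterior_summaries({"p1": s})
        assert out["statics"].loc["p1", "v0"] == pytest.approx(0.2)
        assert np.allclose(out["trajectories"]["p1"][["b_v", "a", "tau0"]], 0.2)

    def test_toy_medians_and_group_means(self):
        by_p = {
            "p1": self._toy_samples([0.1, 0.2, 0.3]),
            "p2": self._toy_samples([0.4, 0.5, 0.6]),
            "p3": self._toy_samples([1.0, 2.0, 3.0]),
        }
        conditions = {"p1": "cong", "p2": "cong", "p3": "incong"}
        out = posterior_summaries(by_p, conditions)
        assert out["statics"].loc["p1", "v0"] == pytest.approx(0.2)
        assert out["statics"].loc["p3", "b_tau"] == pytest.approx(2.0)
        g = out["group_statics"]
        assert g.loc["cong", ("v0", "mean")] == pytest.approx((0.2 + 0.5) / 2)
        assert g.loc["cong", ("v0", "std")] == pytest.approx(
            np.std([0.2, 0.5], ddof=1)
        )

    def test_trajectory_length_preserved(self):
        out = posterior_summaries({"p1": self._toy_samples([1.0, 2.0], T=7)})
        assert len(out["trajectories"]["p1"]) == 7

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            posterior_summaries({})
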