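"""Posterior computation: conjugate closed forms, samplers, summaries."""

import math

import numpy as np
import pytest
from scipy import stats

from sgbayes.core_model import SubgroupEstimates
from sgbayes.inference import (
    McmcSettings,
    OverallEffectSpec,
    PosteriorDraws,
    conjugate_posterior,
    conjugate_posterior_bivariate,
    mcmc_posterior,
    overall_effect,
    sign_probabilities,
    summarize,
)
from sgbayes.priors import (
    BivariateNormalPrior,
    DiscretePrior,
    JointPriorSpec,
    NormalPrior,
    SpikeSlabPrior,
    prior_logdensity,
    spike_slab_slab_weight,
)

QUICK = dict(iterations_per_chain=6_000, burn_in=1_000, thin=1)


def grid_posterior_moments(data, spec, lim=3.0, n=401):
    """Brute-force posterior moments by 2-D numeric integration."""
    b = np.linspace(data.mu_hat_B - lim, data.mu_hat_B + lim, n)
    c = np.linspace(data.mu_hat_C - lim, data.mu_hat_C + lim, n)
    B, C = np.meshgrid(b, c, indexing="ij")
    logp = np.empty_like(B)
    from sgbayes.core_model import likelihood_logdensity

    for i in range(n):
        for j in range(n):
            lp = prior_logdensity(spec, B[i, j], C[i, j])
            if math.isfinite(lp):
                lp += likelihood_logdensity(data, B[i, j], C[i, j])
            logp[i, j] = lp
    w = np.exp(logp - logp.max())
    w /= w.sum()
    mB = float((w * B).sum())
    mC = float((w * C).sum())
    return mB, mC, mB - mC


class TestConjugatePosterior:
    def test_matches_numeric_integration_vague(self, stampede):
        spec = JointPriorSpec.vague()
        post = conjugate_posterior(stampede, spec.mu_C, spec.delta)
        mB, mC, d = grid_posterior_moments(stampede, spec, lim=1.5)
        assert post.marginal("mu_B")[0] == pytest.approx(mB, abs=2e-3)
        assert post.marginal("mu_C")[0] == pytest.approx(mC, abs=2e-3)
        assert post.marginal("delta")[0] == pytest.approx(d, abs=3e-3)

    def test_matches_numeric_integration_informative(self, meteor):
        spec = JointPriorSpec.independent(
            NormalPrior(0.0, 10.0), NormalPrior(-0.122, 0.334)
        )
        post = conjugate_posterior(meteor, spec.mu_C, spec.delta)
        mB, mC, d = grid_posterior_moments(meteor, spec, lim=1.5)
        assert post.marginal("mu_B")[0] == pytest.approx(mB, abs=2e-3)
        assert post.marginal("delta")[0] == pytest.approx(d, abs=3e-3)

    def test_vague_agrees_with_frequentist_point_estimates(self, stampede):
        post = conjugate_posterior(
            stampede, NormalPrior(0, 10), NormalPrior(0, 10)
        )
        assert post.marginal("mu_B")[0] == pytest.approx(stampede.mu_hat_B, abs=0.01)
        assert post.marginal("mu_C")[0] == pytest.approx(stampede.mu_hat_C, abs=0.01)
        assert post.marginal("delta")[0] == pytest.approx(
            stampede.mu_hat_B - stampede.mu_hat_C, abs=0.01
        )

    def test_point_mass_delta_pools_subgroups(self, stampede):
        """delta fixed at 0: mu_B = mu_C = inverse-variance-weighted mean."""
        post = conjugate_posterior(
            stampede, NormalPrior(0.0, 1000.0), NormalPrior(0.0, 0.0)
        )
        wB = 1.0 / stampede.var_B
        wC = 1.0 / stampede.var_C
        pooled = (wB * stampede.mu_hat_B + wC * stampede.mu_hat_C) / (wB + wC)
        assert post.marginal("mu_C")[0] == pytest.approx(pooled, abs=1e-4)
        assert post.marginal("mu_B")[0] == pytest.approx(pooled, abs=1e-4)
        assert post.marginal("delta") == (0.0, 0.0)

    def test_vague_limit_recovers_likelihood(self, meteor):
        post = conjugate_posterior(
            meteor, NormalPrior(0, 1e6), NormalPrior(0, 1e6)
        )
        assert post.marginal("mu_B") == pytest.approx(
            (meteor.mu_hat_B, meteor.se_B), rel=1e-4
        )
        assert post.marginal("mu_C") == pytest.approx(
            (meteor.mu_hat_C, meteor.se_C), rel=1e-4
        )

    def test_posterior_shrinks_prior_variance(self, stampede):
        prior_c = NormalPrior(0.0, 0.5)
        prior_d = NormalPrior(0.0, 0.5)
        post = conjugate_posterior(stampede, prior_c, prior_d)
        assert post.marginal("mu_C")[1] < prior_c.sd
        assert post.marginal("delta")[1] < prior_d.sd

    def test_informative_delta_shrinks_interaction(self, stampede):
        """|E(delta | data)| <= |observed difference| with a zero-centred prior."""
        obs = stampede.mu_hat_B - stampede.mu_hat_C
        post = conjugate_posterior(
            stampede, NormalPrior(0, 10), NormalPrior(0.0, 0.1)
        )
        assert abs(post.marginal("delta")[0]) <= abs(obs)

    def test_truncated_prior_rejected(self, stampede):
        with pytest.raises(ValueError):
            conjugate_posterior(
                stampede,
                NormalPrior(0, 10, truncation_upper=-0.23),
                NormalPrior(0, 10),
            )

    def test_power_prior_continuity_to_vague(self, stampede):
        """k -> 0 inflates the informative prior back to the vague answer."""
        vague = conjugate_posterior(stampede, NormalPrior(0, 10), NormalPrior(0, 10))
        info = NormalPrior(-0.288, 0.108)
        means = []
        for k in (1.0, 0.5, 0.1, 1e-4):
            from sgbayes.priors import apply_power_prior

            post = conjugate_posterior(
                stampede, apply_power_prior(info, k), NormalPrior(0, 10)
            )
            means.append(post.marginal("mu_C")[0])
        # monotone approach to the vague posterior mean
        gaps = [abs(m - vague.marginal("mu_C")[0]) for m in means]
        assert gaps == sorted(gaps, reverse=True)
        assert gaps[-1] < 2e-3

    def test_bivariate_prior_update(self, stampede):
        prior = BivariateNormalPrior.vague()
        post = conjugate_posterior_bivariate(stampede, prior)
        mB, mC, d = grid_posterior_moments(
            stampede, JointPriorSpec.from_joint(prior), lim=1.5
        )
        assert post.marginal("mu_B")[0] == pytest.approx(mB, abs=2e-3)
        assert post.marginal("delta")[0] == pytest.approx(d, abs=3e-3)


class TestMcmcSettings:
    def test_validation(self):
        with pytest.raises(ValueError):
            McmcSettings(seed=0, burn_in=100, iterations_per_chain=100)
        with pytest.raises(ValueError):
            McmcSettings(seed=0, n_chains=0)

    def test_defaults_are_desk_scale(self):
        s = McmcSettings(seed=1)
        assert (s.n_chains, s.iterations_per_chain, s.thin, s.burn_in) == (
            2, 50_000, 2, 20_000,
        )
        assert s.retained_per_chain == 15_000


def _mcse(draws, name):
    ess = draws.diagnostics[f"ess_{name}"]
    return np.std(draws.flat(name), ddof=1) / math.sqrt(ess)


class TestMcmcPosterior:
    def test_normal_gibbs_matches_conjugate(self, stampede):
        spec = JointPriorSpec.vague()
        draws = mcmc_posterior(stampede, spec, McmcSettings(seed=101, **QUICK))
        conj = conjugate_posterior(stampede, spec.mu_C, spec.delta)
        for name in ("mu_B", "mu_C", "delta"):
            got = float(np.mean(draws.flat(name)))
            want = conj.marginal(name)[0]
            assert abs(got - want) < 3 * _mcse(draws, name)

    def test_delta_identity_exact_for_every_family(self, stampede, elicited_grid):
        specs = [
            JointPriorSpec.vague(),
            JointPriorSpec.independent(
                NormalPrior(0, 10, truncation_upper=-0.23), NormalPrior(0, 10)
            ),
            JointPriorSpec.independent(
                NormalPrior(0, 10), DiscretePrior((-0.2, 0.0, 0.2), (0.3, 0.4, 0.3))
            ),
            JointPriorSpec.independent(NormalPrior(0, 10), SpikeSlabPrior(slab_sd=1.0)),
            JointPriorSpec.from_joint(BivariateNormalPrior.vague()),
            JointPriorSpec.from_joint(
                __import__("sgbayes").RectifiedJointPrior(-0.25, 0.13, 0.8, 0.05, -0.045)
            ),
            JointPriorSpec.from_joint(elicited_grid),
        ]
        for spec in specs:
            d = mcmc_posterior(
                stampede, spec,
                McmcSettings(seed=7, iterations_per_chain=1500, burn_in=200, thin=1),
            )
            assert np.array_equal(d.delta, d.mu_B - d.mu_C)

    def test_reproducible_under_seed(self, stampede):
        a = mcmc_posterior(stampede, JointPriorSpec.vague(),
                           McmcSettings(seed=3, **QUICK))
        b = mcmc_posterior(stampede, JointPriorSpec.vague(),
                           McmcSettings(seed=3, **QUICK))
        assert np.array_equal(a.mu_B, b.mu_B)

    def test_truncated_muC_respects_bound(self, stampede):
        spec = JointPriorSpec.independent(
            NormalPrior(0, 10, truncation_upper=-0.23), NormalPrior(0, 10)
        )
        draws = mcmc_posterior(stampede, spec, McmcSettings(seed=5, **QUICK))
        assert np.all(draws.mu_C <= -0.23)
        # far-away bound leaves the posterior essentially unchanged
        far = JointPriorSpec.independent(
            NormalPrior(0, 10, truncation_upper=5.0), NormalPrior(0, 10)
        )
        draws_far = mcmc_posterior(stampede, far, McmcSettings(seed=5, **QUICK))
        conj = conjugate_posterior(stampede, NormalPrior(0, 10), NormalPrior(0, 10))
        assert float(np.mean(draws_far.mu_C)) == pytest.approx(
            conj.marginal("mu_C")[0], abs=0.01
        )

    def test_single_value_discrete_equals_point_mass_conjugate(self, stampede):
        spec = JointPriorSpec.independent(
            NormalPrior(0, 10), DiscretePrior((0.0,), (1.0,))
        )
        draws = mcmc_posterior(stampede, spec, McmcSettings(seed=6, **QUICK))
        conj = conjugate_posterior(stampede, NormalPrior(0, 10), NormalPrior(0.0, 0.0))
        assert np.all(draws.delta == 0.0)
        assert float(np.mean(draws.mu_C)) == pytest.approx(
            conj.marginal("mu_C")[0], abs=3 * _mcse(draws, "mu_C")
        )

    def test_spike_slab_inclusion_matches_analytic_oracle(self, stampede):
        delta_hat = stampede.mu_hat_B - stampede.mu_hat_C
        v = stampede.var_B + stampede.var_C
        for tau in (10.0, 1.0, 0.3):
            spec = JointPriorSpec.independent(
                NormalPrior(0, 10), SpikeSlabPrior(slab_sd=tau)
            )
            draws = mcmc_posterior(
                stampede, spec, McmcSettings(seed=8, iterations_per_chain=12_000,
                                             burn_in=2_000, thin=1)
            )
            rate = float(np.mean(draws.flat("R")))
            want = spike_slab_slab_weight(delta_hat, v, tau**2)
            assert rate == pytest.approx(want, abs=0.03)

    def test_spike_dominates_at_large_tau(self, stampede):
        spec = JointPriorSpec.independent(
            NormalPrior(0, 10), SpikeSlabPrior(slab_sd=10.0)
        )
        draws = mcmc_posterior(stampede, spec, McmcSettings(seed=9, **QUICK))
        s = summarize(draws)
        assert s.aux_probs["R"].get(1, 0.0) < 0.1
        # posterior of delta dominated by the spike: tight around zero
        assert abs(s["delta"].mean) < 0.05

    def test_bivariate_gibbs_matches_conjugate(self, stampede, elicited_grid):
        from sgbayes.elicitation import moment_match_bivariate

        prior = moment_match_bivariate(elicited_grid)
        draws = mcmc_posterior(
            stampede, JointPriorSpec.from_joint(prior),
            McmcSettings(seed=10, **QUICK),
        )
        conj = conjugate_posterior_bivariate(stampede, prior)
        for name in ("mu_B", "mu_C", "delta"):
            got = float(np.mean(draws.flat(name)))
            assert abs(got - conj.marginal(name)[0]) < 3 * _mcse(draws, name)

    def test_rectified_posterior_matches_numeric_integration(self, stampede):
        """Independent scipy-based quadrature over the mixed measure.

        The joint prior has Lebesgue density on the open negative quadrant
        plus atoms on mu_B = 0, on mu_C = 0, and at the origin; each piece
        is integrated with its own measure and pooled.
        """
        from sgbayes.priors import RectifiedJointPrior

        a, b_sd, c_slope, d_sd, e = -0.252, 0.131, 0.816, 0.054, -0.045
        prior = RectifiedJointPrior(a, b_sd, c_slope, d_sd, e)
        draws = mcmc_posterior(
            stampede, JointPriorSpec.from_joint(prior),
            McmcSettings(seed=11, iterations_per_chain=30_000, burn_in=5_000, thin=1),
        )

        def lik(mb, mc):
            return stats.norm.pdf(stampede.mu_hat_B, mb, stampede.se_B) * (
                stats.norm.pdf(stampede.mu_hat_C, mc, stampede.se_C)
            )

        n = 600
        edges = np.linspace(-1.2, 0.0, n + 1)
        mid = 0.5 * (edges[:-1] + edges[1:])
        step = edges[1] - edges[0]
        C, B = np.meshgrid(mid, mid, indexing="ij")  # rows = mu_C
        sd_cond = np.sqrt(d_sd**2 + e * mid)  # per mu_C value
        # continuous x continuous
        w_cc = (
            stats.norm.pdf(mid, a, b_sd)[:, None]
            * stats.norm.pdf(B, c_slope * C, sd_cond[:, None])
            * lik(B, C)
            * step**2
        )
        # mu_B = 0 atom, mu_C continuous
        atom_B = stats.norm.sf(0.0, c_slope * mid, sd_cond)
        w_b0 = stats.norm.pdf(mid, a, b_sd) * atom_B * lik(0.0, mid) * step
        # mu_C = 0 atom: conditional is RN(0, d^2)
        atom_C = stats.norm.sf(0.0, a, b_sd)
        w_c0 = atom_C * stats.norm.pdf(mid, 0.0, d_sd) * lik(mid, 0.0) * step
        w_00 = atom_C * 0.5 * lik(0.0, 0.0)

        total = w_cc.sum() + w_b0.sum() + w_c0.sum() + w_00
        mB = ((w_cc * B).sum() + (w_c0 * mid).sum()) / total
        mC = ((w_cc * C).sum() + (w_b0 * mid).sum()) / total
        assert float(np.mean(draws.mu_B)) == pytest.approx(mB, abs=0.01)
        assert float(np.mean(draws.mu_C)) == pytest.approx(mC, abs=0.01)
        # the prior atoms propagate into the posterior
        assert np.mean(draws.mu_C == 0.0) == pytest.approx(
            (w_c0.sum() + w_00) / total, abs=0.01
        )

    def test_grid_prior_posterior_matches_enumeration(self, stampede, elicited_grid):
        from sgbayes.core_model import likelihood_logdensity

        draws = mcmc_posterior(
            stampede, JointPriorSpec.from_joint(elicited_grid),
            McmcSettings(seed=12, **QUICK),
        )
        logw = []
        vals = []
        for i, vC in enumerate(elicited_grid.muC_values):
            for j, vB in enumerate(elicited_grid.muB_values):
                p = elicited_grid.joint_probs[i, j]
                if p > 0:
                    logw.append(math.log(p) + likelihood_logdensity(stampede, vB, vC))
                    vals.append((vB, vC))
        w = np.exp(np.array(logw) - max(logw))
        w /= w.sum()
        vals = np.array(vals)
        assert float(np.mean(draws.mu_B)) == pytest.approx(
            float(w @ vals[:, 0]), abs=0.01
        )
        assert float(np.mean(draws.mu_C)) == pytest.approx(
            float(w @ vals[:, 1]), abs=0.005
        )


class TestSummaries:
    def _degenerate(self, value=-1.0, n=2000):
        arr = np.full((1, n), value)
        return PosteriorDraws(mu_B=arr, mu_C=arr, delta=arr - arr)

    def test_degenerate_draws(self):
        s = summarize(self._degenerate())
        assert s["mu_B"] == pytest.approx((-1.0, 0.0, -1.0, -1.0, 1.0, False))
        assert s["delta"].prob_below_0 == 0.0

    def test_sign_probabilities_complementary(self, stampede):
        draws = mcmc_posterior(stampede, JointPriorSpec.vague(),
                               McmcSettings(seed=13, **QUICK))
        p = sign_probabilities(draws)
        below = float(np.mean(draws.delta < 0))
        at_or_above = float(np.mean(draws.delta >= 0))
        assert below + at_or_above == 1.0
        assert p.p_delta_below_0 == below
        assert p.p_mu_C_below_0 > 0.99

    def test_minimum_draw_requirement(self):
        with pytest.raises(ValueError):
            summarize(self._degenerate(n=10))

    def test_overall_effect_limits_and_convexity(self, stampede):
        draws = mcmc_posterior(stampede, JointPriorSpec.vague(),
                               McmcSettings(seed=14, **QUICK))
        assert np.array_equal(overall_effect(draws, OverallEffectSpec(1.0)), draws.mu_B)
        assert np.array_equal(overall_effect(draws, OverallEffectSpec(0.0)), draws.mu_C)
        mid = overall_effect(draws, OverallEffectSpec(0.5))
        lo = np.minimum(draws.mu_B, draws.mu_C)
        hi = np.maximum(draws.mu_B, draws.mu_C)
        assert np.all((mid >= lo) & (mid <= hi))

    def test_invalid_pi_raises(self):
        with pytest.raises(ValueError):
            OverallEffectSpec(1.5)

    def test_misaligned_aux_raises(self):
        arr = np.zeros((1, 1500))
        with pytest.raises(ValueError):
            PosteriorDraws(mu_B=arr, mu_C=arr, delta=arr,
                           aux={"R": np.zeros((1, 10))})

    def test_parameter_recovery_with_tiny_variances(self):
        """Posterior concentrates on the truth as sampling noise vanishes."""
        from sgbayes.synthetic import SyntheticScenario, generate_scenario

        scn = SyntheticScenario(
            true_mu_B=-0.4, true_mu_C=-0.1, var_B=1e-8, var_C=1e-8,
            n_replicates=1, seed=21,
        )
        data = generate_scenario(scn)[0]
        post = conjugate_posterior(data, NormalPrior(0, 10), NormalPrior(0, 10))
        assert post.marginal("mu_B")[0] == pytest.approx(-0.4, abs=1e-3)
        assert post.marginal("mu_C")[0] == pytest.approx(-0.1, abs=1e-3)
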