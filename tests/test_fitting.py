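"""Hierarchical fitting: transforms, shrinkage, priors, diagnostics, joint model."""

import numpy as np
import pandas as pd
import pytest

from cogrel import synth, transforms
from cogrel.fitting import (FittingError, GroupPosterior, ModelSpec,
                            SamplerSettings, check_convergence,
                            fit_joint_correlated, fit_per_session, subject_mle)


class TestTransforms:
    def test_latent_native_round_trip_is_identity(self, rng):
        # |z| <= 5: beyond that the normal CDF saturates in float64
        z = np.clip(rng.normal(0, 2, size=500), -5, 5)
        for lo, hi in [(0, 1), (0, 30), (0, 2), (0, 5)]:
            back = transforms.to_latent(transforms.to_native(z, lo, hi), lo, hi)
            np.testing.assert_allclose(back, z, atol=1e-10)

    def test_native_respects_bounds_and_monotone(self, rng):
        z = np.sort(rng.normal(0, 3, size=200))
        x = transforms.to_native(z, 0.0, 5.0)
        assert (x > 0).all() and (x < 5).all()
        assert (np.diff(x) >= 0).all()


class TestModelSpec:
    def test_winning_models_have_canonical_parameterisation(self):
        assert ModelSpec.bandit_winning().param_names == \
            ["a_rew", "a_pun", "r_sens", "p_sens", "xi"]
        assert ModelSpec.gamble_winning().param_names == ["rho", "lam", "tau"]

    def test_reduced_variant_expansion(self):
        m = ModelSpec(task="bandit", shared_learning_rate=True, lapse=False)
        assert m.param_names == ["a", "r_sens", "p_sens"]
        canon = m.expand(np.array([[0.3, 4.0, 5.0]]))
        np.testing.assert_allclose(canon, [[0.3, 0.3, 4.0, 5.0, 0.0]])
        g = ModelSpec(task="gamble", fix_rho=True)
        np.testing.assert_allclose(g.expand(np.array([[2.0, 0.5]])),
                                   [[1.0, 2.0, 0.5]])


class TestPerSessionFit:
    def test_single_subject_rejected(self, small_bandit_study):
        df = small_bandit_study.bandit
        solo = df[df.subject == 1]
        with pytest.raises(FittingError):
            fit_per_session(ModelSpec.bandit_winning(), solo, session=1)

    def test_posterior_draws_respect_bounds(self, bandit_posterior_s1):
        x = bandit_posterior_s1.subject_native_draws()
        b = bandit_posterior_s1.model.bounds
        assert (x >= b[:, 0]).all() and (x <= b[:, 1]).all()

    def test_group_means_recover_generating_values(self, bandit_posterior_s1,
                                                   small_bandit_study):
        truth = small_bandit_study.truth
        gen = truth[truth.session == 1].groupby("param")["value"].mean()
        est = bandit_posterior_s1.group_mean_native
        # learning rates are well constrained by 200 trials
        assert abs(est["a_rew"] - gen["a_rew"]) < 0.15
        assert abs(est["a_pun"] - gen["a_pun"]) < 0.15

    def test_shrinkage_toward_group_mean(self, small_bandit_study,
                                         bandit_posterior_s1):
        """Hierarchical subject estimates vary less than subject-wise MLEs."""
        mle = subject_mle(ModelSpec.bandit_winning(), small_bandit_study.bandit,
                          session=1)
        post = bandit_posterior_s1.subject_means
        for name in ("a_rew", "a_pun", "r_sens", "p_sens"):
            assert post[name].var() < mle[name].var()

    def test_prior_only_fit_reproduces_priors(self, small_gamble_study):
        """With the likelihood switched off the group posteriors match the
        priors: latent means ~ N(0,1), SDs ~ half-normal(0.2)."""
        post = fit_per_session(ModelSpec.gamble_winning(),
                               small_gamble_study.gamble, session=1,
                               settings=SamplerSettings(chains=2, warmup=500,
                                                        draws=1500),
                               seed=3, prior_only=True)
        mu = post.draws["mu"]
        sig = post.draws["sigma"]
        assert abs(mu.mean()) < 0.15
        assert abs(mu.std() - 1.0) < 0.2
        half_normal_mean = 0.2 * np.sqrt(2 / np.pi)
        assert abs(sig.mean() - half_normal_mean) < 0.05

    def test_full_lapse_cohort_recovers_high_lapse(self):
        spec = synth.PopulationSpec("bandit", [
            synth.ParamSpec("a_rew", -0.25, 0.4, 0.5, 0, 1),
            synth.ParamSpec("a_pun", -0.5, 0.4, 0.5, 0, 1),
            synth.ParamSpec("r_sens", -0.84, 0.4, 0.5, 0, 30),
            synth.ParamSpec("p_sens", -0.84, 0.4, 0.5, 0, 30),
            synth.ParamSpec("xi", 5.0, 0.01, 0.0, 0, 1),
        ], n_subjects=8)
        study = synth.simulate_study(bandit_spec=spec, gamble_spec=None, seed=31)
        post = fit_per_session(ModelSpec.bandit_winning(), study.bandit,
                               session=1,
                               settings=SamplerSettings(chains=2, warmup=300,
                                                        draws=300), seed=5)
        assert post.group_mean_native["xi"] > 0.8

    def test_pooled_single_prior_mode_units(self, small_gamble_study,
                                            quick_settings):
        post = fit_per_session(ModelSpec.gamble_winning(),
                               small_gamble_study.gamble, session=None,
                               settings=quick_settings, seed=9)
        sessions = {s for (_, s) in post.units}
        assert sessions == {1, 2}
        assert len(post.units) == 24


class TestJointFit:
    def test_roster_mismatch_rejected(self, small_gamble_study, quick_settings):
        df = small_gamble_study.gamble
        drop = df[~((df.subject == 1) & (df.session == 2))]
        with pytest.raises(FittingError):
            fit_joint_correlated(ModelSpec.gamble_winning(), drop,
                                 settings=quick_settings)

    def test_duplicated_sessions_give_near_perfect_correlation(
            self, small_gamble_study, quick_settings):
        """If session 2 is an exact copy of session 1 the embedded
        correlation posterior concentrates near 1."""
        df = small_gamble_study.gamble
        s1 = df[df.session == 1]
        dup = pd.concat([s1, s1.assign(session=2)], ignore_index=True)
        post = fit_joint_correlated(ModelSpec.gamble_winning(), dup,
                                    settings=quick_settings, seed=13)
        rel = post.reliability.set_index("param")
        assert (rel["r_mean"] > 0.9).all()

    def test_correlation_draws_are_valid(self, small_gamble_study, quick_settings):
        post = fit_joint_correlated(ModelSpec.gamble_winning(),
                                    small_gamble_study.gamble,
                                    settings=quick_settings, seed=17)
        r = post.draws["r"]
        assert (np.abs(r) <= 1).all()

    def test_zero_correlation_population_recovered(self, quick_settings):
        spec = synth.default_gamble_population(
            n_subjects=25, corr={"rho": 0.0, "lam": 0.0, "tau": 0.0})
        study = synth.simulate_study(bandit_spec=None, gamble_spec=spec, seed=41)
        post = fit_joint_correlated(ModelSpec.gamble_winning(), study.gamble,
                                    settings=quick_settings, seed=19)
        rel = post.reliability.set_index("param")
        assert (rel["r_mean"].abs() < 0.3).all()

    def test_interval_coverage_over_replications(self):
        """95% intervals for the embedded correlation cover the generating
        value in most small replications."""
        hits = 0
        reps = 12
        for k in range(reps):
            spec = synth.default_gamble_population(
                n_subjects=14, corr={"rho": 0.7, "lam": 0.7, "tau": 0.7})
            study = synth.simulate_study(bandit_spec=None, gamble_spec=spec,
                                         seed=500 + k)
            post = fit_joint_correlated(
                ModelSpec.gamble_winning(), study.gamble,
                settings=SamplerSettings(chains=2, warmup=300, draws=300),
                seed=600 + k)
            rel = post.reliability.set_index("param")
            hits += int(rel.loc["lam", "r_q2.5"] <= 0.7 <= rel.loc["lam", "r_q97.5"])
        assert hits >= int(0.7 * reps)


class TestConvergenceDiagnostics:
    def _make_posterior(self, draws_mu, draws_sigma, latent):
        return GroupPosterior(model=ModelSpec.gamble_winning(),
                              units=[(i + 1, 1) for i in range(latent.shape[2])],
                              draws={"mu": draws_mu, "sigma": draws_sigma,
                                     "latent": latent})

    def test_single_chain_rejected(self, rng):
        post = self._make_posterior(rng.normal(size=(1, 200, 3)),
                                    np.abs(rng.normal(size=(1, 200, 3))),
                                    rng.normal(size=(1, 200, 4, 3)))
        with pytest.raises(FittingError):
            check_convergence(post)

    def test_well_mixed_chains_pass(self, rng):
        post = self._make_posterior(rng.normal(size=(2, 400, 3)),
                                    np.abs(rng.normal(size=(2, 400, 3))),
                                    rng.normal(size=(2, 400, 4, 3)))
        rep = check_convergence(post)
        assert rep.ok and not rep.multimodal

    def test_shifted_chain_raises_rhat_flag(self, rng):
        mu = rng.normal(size=(2, 400, 3))
        mu[1, :, 0] += 5.0
        post = self._make_posterior(mu, np.abs(rng.normal(size=(2, 400, 3))),
                                    rng.normal(size=(2, 400, 4, 3)))
        rep = check_convergence(post)
        assert any(f.startswith("mu[rho") for f in rep.rhat_flags)
        assert not rep.ok

    def test_bimodal_subject_marginal_is_flagged(self, rng):
        latent = rng.normal(scale=0.1, size=(2, 400, 4, 3))
        latent[:, :, 2, 1] += np.where(rng.random((2, 400)) < 0.5, -2.0, 2.0)
        post = self._make_posterior(rng.normal(size=(2, 400, 3)),
                                    np.abs(rng.normal(size=(2, 400, 3))),
                                    latent)
        rep = check_convergence(post)
        assert (3, "lam") in rep.multimodal
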