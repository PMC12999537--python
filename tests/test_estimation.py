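"""Tests of the samplers, configuration validation, and convergence checks."""

import numpy as np
import pytest

from conftest import random_instance
from fakemix import model
from fakemix.estimate import (
    McmcConfig,
    ModelSpec,
    PosteriorResult,
    PriorConfig,
    check_convergence,
    fit,
    make_evaluator,
    state_pointwise_loglik,
)
from fakemix.simulate import SimulationDesign, simulate
from fakemix.types import ItemParameters, PersonParameters, PopulationParameters


def test_unknown_variant_rejected(tiny_design):
    with pytest.raises(ValueError):
        ModelSpec(variant="not_a_model", weights=tiny_design.weights)


def test_invalid_prior_scale_rejected():
    with pytest.raises(ValueError):
        PriorConfig(slope_sd=-1.0)


def test_rt_variant_requires_times(tiny_design, tiny_data):
    from fakemix.types import AssessmentData

    no_rt = AssessmentData(responses=tiny_data.responses)
    spec = ModelSpec(variant="person_by_item_rt", weights=tiny_design.weights)
    with pytest.raises(ValueError):
        fit(no_rt, spec, mcmc=McmcConfig(chains=1, warmup=5, samples=5))


def test_sampler_likelihood_matches_kernel_oracle():
    """The sampler's internal pointwise likelihood must agree with the pure
    probability kernel for the full model on random states."""
    rng = np.random.default_rng(53)
    data, items, weights, persons, pop = random_instance(
        rng, n_persons=8, n_items=4, n_traits=2, n_categories=4
    )
    spec = ModelSpec(variant="person_by_item_rt", weights=weights)
    ev = make_evaluator(data, spec)
    state = dict(
        ev.state,
        alpha_trait=items.alpha_trait, alpha_fake=items.alpha_fake,
        gamma=items.gamma, beta=items.beta,
        delta_s=items.delta_s, delta_f=items.delta_f,
        nu_phi=pop.nu_phi, nu_psi=pop.nu_psi, lam=pop.lam,
        sigma_rt=pop.sigma_rt, X=persons.values,
    )
    pw = state_pointwise_loglik(data, spec, state)
    ref = model.joint_marginal_loglik(data, items, weights, persons, pop, pointwise=True)
    np.testing.assert_allclose(pw, ref, atol=1e-10)


def test_identification_constraints_hold_in_every_draw(tiny_fit):
    d = tiny_fit.draws
    assert np.all(d["gamma"][:, :, :, :, 0] == 0)
    assert np.all(d["beta"][:, :, :, 0] == 0)
    assert np.all(d["lam"] > 0)
    assert np.all(d["nu_phi"] > 0)
    assert np.all(d["nu_psi"] > 0)
    assert np.all(d["sigma_rt"] > 0)
    assert np.all(d["alpha_trait"] >= 0)
    assert np.all(d["alpha_fake"] > 0)
    corr = d["corr"]
    assert np.allclose(np.diagonal(corr, axis1=-2, axis2=-1), 1.0)
    assert np.all(np.abs(corr) <= 1.0 + 1e-9)


def test_hmc_gradients_match_finite_differences(tiny_design, tiny_data):
    from fakemix.estimate import _ChainSampler

    for variant in ("person_by_item_rt", "person_mix_no_rt", "nonmixture_mgpcm"):
        spec = ModelSpec(variant=variant, weights=tiny_design.weights)
        ev = _ChainSampler(tiny_data, spec, PriorConfig(), McmcConfig(), (5,))
        ev._build_layout()
        v0 = ev._pack(ev.state)
        _, g = ev._logpost_and_grad(v0)
        rng = np.random.default_rng(1)
        for i in rng.choice(len(v0), size=25, replace=False):
            vp = v0.copy()
            vp[i] += 1e-6
            vm = v0.copy()
            vm[i] -= 1e-6
            fd = (ev._logpost_and_grad(vp)[0] - ev._logpost_and_grad(vm)[0]) / 2e-6
            assert abs(fd - g[i]) / max(1.0, abs(fd)) < 1e-5


def test_prior_recovery_with_minimal_data():
    """With almost no data the posterior of the proportionality constant
    should look like its positive-truncated prior."""
    d = SimulationDesign(n_persons=2, items_per_trait=1, seed=31)
    data = simulate(d)
    spec = ModelSpec(variant="person_by_item_rt", weights=d.weights)
    res = fit(data, spec, mcmc=McmcConfig(chains=2, warmup=200, samples=300, seed=8,
                                          n_leapfrog=8, store_loglik=False))
    lam = res.draws["lam"].ravel()
    assert np.all(lam > 0)
    # half-normal sd 0.5 has median ~0.34; stay within a generous band
    assert 0.1 < np.median(lam) < 0.8


class TestCheckConvergence:
    def _result(self, draws_lam):
        # minimal nonmixture-style result carrying one monitored family
        d = SimulationDesign(n_persons=5, items_per_trait=1, seed=1)
        spec = ModelSpec(variant="nonmixture_nrm", weights=d.weights)
        chains, S = draws_lam.shape[:2]
        I, K1 = d.n_items, d.n_categories
        draws = {
            "gamma": np.zeros((chains, S, 3, I, K1)) + draws_lam[:, :, None, None, None],
            "alpha_fake": np.exp(draws_lam)[:, :, None] * np.ones(I),
        }
        return PosteriorResult(
            spec=spec, draws=draws, person_draws=None, loglik_resp=None,
            loglik_joint=None, mcmc=McmcConfig(), priors=PriorConfig(),
        )

    def test_stationary_chains_pass(self):
        rng = np.random.default_rng(0)
        res = self._result(rng.normal(0, 1, (2, 400)))
        ok, offenders = check_convergence(res)
        assert ok and offenders == []

    def test_separated_chains_fail(self):
        rng = np.random.default_rng(0)
        draws = rng.normal(0, 1, (2, 400))
        draws[1] += 10.0
        ok, offenders = check_convergence(self._result(draws))
        assert not ok and len(offenders) > 0

    def test_infinite_threshold_is_vacuous(self):
        rng = np.random.default_rng(0)
        draws = rng.normal(0, 1, (2, 400))
        draws[1] += 10.0
        ok, _ = check_convergence(self._result(draws), threshold=np.inf)
        assert ok

    def test_single_chain_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            check_convergence(self._result(rng.normal(0, 1, (1, 400))))


@pytest.mark.parametrize(
    "variant", ["person_mix_rt", "person_mix_no_rt", "nonmixture_mnrm", "nonmixture_nrm"]
)
def test_reduced_variants_fit_and_respect_constraints(tiny_design, tiny_data, variant):
    spec = ModelSpec(variant=variant, weights=tiny_design.weights)
    res = fit(tiny_data, spec, mcmc=McmcConfig(chains=2, warmup=60, samples=60,
                                               seed=2, n_leapfrog=6))
    assert res.n_samples == 60
    assert np.all(res.draws["gamma"][:, :, :, :, 0] == 0)
    if variant.startswith("person_mix"):
        pi = res.draws["pi"]
        np.testing.assert_allclose(pi.sum(axis=-1), 1.0, atol=1e-9)
        assert np.all(pi > 0)


def test_marginalized_and_augmented_samplers_agree():
    """The HMC sampler over the class-marginalized likelihood and the
    data-augmented Gibbs sampler (explicit class draws) target the same
    posterior; their posterior means must agree within Monte-Carlo error."""
    d = SimulationDesign(n_persons=60, items_per_trait=2, seed=41)
    data = simulate(d)
    spec = ModelSpec(variant="person_by_item_rt", weights=d.weights)
    res_m = fit(data, spec, mcmc=McmcConfig(chains=2, warmup=300, samples=400, seed=2,
                                            n_leapfrog=12, store_loglik=False,
                                            store_persons=False))
    res_g = fit(data, spec, mcmc=McmcConfig(chains=2, warmup=1500, samples=1500, seed=3,
                                            marginalize=False, store_loglik=False,
                                            store_persons=False))
    lam_m = float(res_m.posterior_mean("lam"))
    lam_g = float(res_g.posterior_mean("lam"))
    assert lam_m == pytest.approx(lam_g, abs=0.12)
    nu_m = float(res_m.posterior_mean("nu_phi"))
    nu_g = float(res_g.posterior_mean("nu_phi"))
    assert nu_m == pytest.approx(nu_g, abs=0.15)
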