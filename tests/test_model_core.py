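"""Unit and property tests of the probability kernel."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import logsumexp, softmax

from conftest import brute_force_cell_terms, random_instance
from fakemix import model
from fakemix.types import (
    AssessmentData,
    ItemParameters,
    PersonParameters,
    PopulationParameters,
    ScoringWeights,
)


def _single_item_setup(D=1, K=2, alpha=1.0, theta=1.0, fake_slope=0.0, eta=0.0):
    K1 = K + 1
    trait_w = np.arange(K1, dtype=float)[None, None, :] * np.ones((1, D, 1))
    weights = ScoringWeights(trait=trait_w, faking=np.zeros((1, K1)))
    items = ItemParameters(
        alpha_trait=np.full((1, D), alpha), alpha_fake=np.array([fake_slope]),
        gamma=np.zeros((3, 1, K1)), beta=np.zeros((1, 3)),
        delta_s=np.array([1.7]), delta_f=np.array([1.5]),
    )
    vals = np.zeros((1, D + 3))
    vals[0, :D] = theta
    vals[0, D] = eta
    persons = PersonParameters(values=vals, n_traits=D)
    pop = PopulationParameters(corr=np.eye(D + 3), nu_phi=0.5, nu_psi=1.0, lam=0.2)
    return items, weights, persons, pop


class TestCategoryProbabilities:
    def test_uniform_when_all_propensities_zero(self):
        items, weights, persons, _ = _single_item_setup(K=1, alpha=0.0, theta=0.0)
        p = model.category_probabilities(0, persons, items, weights)
        np.testing.assert_allclose(p[0, 0], [0.5, 0.5], atol=1e-14)

    def test_s_only_class_ignores_faking_score(self):
        rng = np.random.default_rng(3)
        data, items, weights, persons, pop = random_instance(rng)
        vals = persons.values.copy()
        vals[:, weights.n_traits] += 5.0  # shift every eta
        persons2 = PersonParameters(values=vals, n_traits=weights.n_traits)
        p1 = model.category_probabilities(0, persons, items, weights)
        p2 = model.category_probabilities(0, persons2, items, weights)
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_known_softmax_value(self):
        # D=1, K=2, slope 1, weights (0,1,2), theta=1, zero intercepts
        items, weights, persons, _ = _single_item_setup(D=1, K=2, alpha=1.0, theta=1.0)
        p = model.category_probabilities(0, persons, items, weights)
        np.testing.assert_allclose(p[0, 0], softmax([0.0, 1.0, 2.0]), atol=1e-12)
        np.testing.assert_allclose(p[0, 0], [0.0900, 0.2447, 0.6652], atol=5e-5)

    def test_shift_invariance_of_propensities(self):
        rng = np.random.default_rng(8)
        data, items, weights, persons, pop = random_instance(rng)
        p1 = model.category_probabilities(1, persons, items, weights)
        shifted = ItemParameters(
            alpha_trait=items.alpha_trait, alpha_fake=items.alpha_fake,
            gamma=items.gamma, beta=items.beta,
            delta_s=items.delta_s, delta_f=items.delta_f,
        )
        # shifting all category propensities of one item by a constant is a
        # softmax invariance; emulate by adding the constant to the logits
        logits = model.category_logits(shifted, weights, persons)
        logits[:, :, 0, :] += 3.7
        p2 = np.exp(logits - logsumexp(logits, axis=-1, keepdims=True))[1]
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_collapse_sf_to_s_only_without_faking(self):
        rng = np.random.default_rng(5)
        data, items, weights, persons, pop = random_instance(rng)
        gamma = items.gamma.copy()
        gamma[1] = gamma[0]  # shared intercepts
        collapsed = ItemParameters(
            alpha_trait=items.alpha_trait, alpha_fake=np.zeros(items.n_items),
            gamma=gamma, beta=items.beta, delta_s=items.delta_s, delta_f=items.delta_f,
        )
        p_sf = model.category_probabilities(1, persons, collapsed, weights)
        p_s = model.category_probabilities(0, persons, collapsed, weights)
        np.testing.assert_allclose(p_sf, p_s, atol=1e-12)

    def test_probability_vectors_are_normalized(self):
        rng = np.random.default_rng(17)
        _, items, weights, persons, _ = random_instance(rng, n_persons=6)
        for cls in range(3):
            p = model.category_probabilities(cls, persons, items, weights)
            assert np.all(p >= 0)
            np.testing.assert_allclose(p.sum(axis=-1), 1.0, atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        items, weights, persons, _ = _single_item_setup()
        bad = ScoringWeights(trait=weights.trait[:, :, :2], faking=weights.faking[:, :2])
        with pytest.raises(ValueError):
            model.category_probabilities(0, persons, items, bad)


class TestResponseTimes:
    def test_log_density_peaks_at_time_intensity(self):
        items, weights, persons, pop = _single_item_setup()
        mu = model.rt_log_means(items, pop, persons)
        assert mu[0, 0, 0] == pytest.approx(items.delta_s[0])  # phi = 0
        # the normal density of ln(t) is maximized where ln(t) equals its mean
        grid = np.linspace(0.5, 15, 400)
        dens = [
            model.rt_log_density(np.full((1, 1), t), items, pop, persons)[0, 0, 0] + np.log(t)
            for t in grid
        ]
        assert np.log(grid[int(np.argmax(dens))]) == pytest.approx(items.delta_s[0], abs=0.02)

    def test_sf_time_intensity_combination(self):
        # the combination rule delta_s + lam * delta_f at the calibrated values
        # (inputs are stated at two decimals, so allow their rounding error)
        assert 1.72 + 0.23 * 1.53 == pytest.approx(2.08, abs=0.015)
        items, weights, persons, pop = _single_item_setup()
        mu = model.rt_log_means(items, pop, persons)
        assert mu[1, 0, 0] == pytest.approx(items.delta_s[0] + pop.lam * items.delta_f[0])

    def test_standard_normal_density_value(self):
        items, weights, persons, pop = _single_item_setup()
        items.delta_f[0] = 0.0
        pop.sigma_rt[:] = 1.0
        ld = model.rt_log_density(np.full((1, 1), 1.0), items, pop, persons)
        assert ld[2, 0, 0] == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)

    def test_sf_mean_exceeds_s_only_mean(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            _, items, weights, persons, pop = random_instance(rng)
            mu = model.rt_log_means(items, pop, persons)
            assert np.all(mu[1] > mu[0])  # lam > 0 and delta_f > 0

    def test_nonpositive_time_rejected(self):
        items, weights, persons, pop = _single_item_setup()
        with pytest.raises(ValueError):
            model.rt_log_density(np.zeros((1, 1)), items, pop, persons)


class TestClassProbabilities:
    def test_flat_model_gives_equal_thirds(self):
        items, weights, persons, pop = _single_item_setup()
        p = model.class_probabilities(persons, items, pop)
        np.testing.assert_allclose(p, 1.0 / 3.0, atol=1e-12)

    def test_unit_slope_softmax_value(self):
        items, weights, persons, pop = _single_item_setup()
        vals = persons.values.copy()
        vals[0, -1] = 1.0  # psi = 1
        persons2 = PersonParameters(values=vals, n_traits=persons.n_traits)
        p = model.class_probabilities(persons2, items, pop)
        np.testing.assert_allclose(p[0, 0], softmax([0.0, 1.0, 2.0]), atol=1e-12)

    def test_expected_class_score_increasing_in_psi(self):
        items, weights, _, pop = _single_item_setup()
        scores = []
        for psi in np.linspace(-2, 2, 9):
            vals = np.zeros((1, 4))
            vals[0, -1] = psi
            p = model.class_probabilities(
                PersonParameters(values=vals, n_traits=1), items, pop
            )[0, 0]
            scores.append(p[1] + 2 * p[2])
        assert np.all(np.diff(scores) > 0)


class TestMarginalLikelihood:
    def test_degenerate_mixture_reduces_to_single_class(self):
        rng = np.random.default_rng(31)
        data, items, weights, persons, pop = random_instance(rng, n_persons=1, n_items=1)
        beta = items.beta.copy()
        beta[:, 1:] = -300.0  # force the S-only class
        forced = ItemParameters(
            alpha_trait=items.alpha_trait, alpha_fake=items.alpha_fake,
            gamma=items.gamma, beta=beta, delta_s=items.delta_s, delta_f=items.delta_f,
        )
        ll = model.joint_marginal_loglik(data, forced, weights, persons, pop)
        expected = brute_force_cell_terms(data, forced, weights, persons, pop, 0, 0)[0]
        assert ll == pytest.approx(expected, abs=1e-8)

    def test_person_permutation_invariance(self):
        rng = np.random.default_rng(37)
        data, items, weights, persons, pop = random_instance(rng, n_persons=5)
        ll = model.joint_marginal_loglik(data, items, weights, persons, pop)
        perm = rng.permutation(5)
        data2 = AssessmentData(responses=data.responses[perm], times=data.times[perm])
        persons2 = PersonParameters(values=persons.values[perm], n_traits=persons.n_traits)
        ll2 = model.joint_marginal_loglik(data2, items, weights, persons2, pop)
        assert ll == pytest.approx(ll2, abs=1e-10)

    @pytest.mark.parametrize("include_rt", [True, False])
    def test_matches_brute_force_enumeration(self, include_rt):
        rng = np.random.default_rng(41)
        for _ in range(5):
            data, items, weights, persons, pop = random_instance(
                rng, n_persons=3, n_items=2, n_traits=1, n_categories=3
            )
            ll = model.joint_marginal_loglik(data, items, weights, persons, pop, include_rt)
            ref = 0.0
            for n in range(3):
                for i in range(2):
                    terms = brute_force_cell_terms(
                        data, items, weights, persons, pop, n, i, include_rt
                    )
                    ref += logsumexp(terms)
            assert ll == pytest.approx(ref, abs=1e-10)


class TestResponsibilities:
    def test_uninformative_data_returns_prior(self):
        # identical response and RT models across classes: posterior = prior
        items, weights, persons, pop = _single_item_setup(alpha=0.0)
        items.delta_f[0] = items.delta_s[0] / (1.0 + pop.lam)  # not equal -> use zero
        items.delta_s[0] = 0.0
        items.delta_f[0] = 0.0
        data = AssessmentData(responses=np.array([[1]]), times=np.full((1, 1), 1.0))
        r = model.responsibilities(data, items, weights, persons, pop)
        np.testing.assert_allclose(r[0, 0], 1.0 / 3.0, atol=1e-12)

    def test_degenerate_prior_dominates(self):
        rng = np.random.default_rng(43)
        data, items, weights, persons, pop = random_instance(rng, n_persons=2, n_items=2)
        beta = items.beta.copy()
        beta[:, 1:] = -300.0
        forced = ItemParameters(
            alpha_trait=items.alpha_trait, alpha_fake=items.alpha_fake,
            gamma=items.gamma, beta=beta, delta_s=items.delta_s, delta_f=items.delta_f,
        )
        r = model.responsibilities(data, forced, weights, persons, pop)
        np.testing.assert_allclose(r[:, :, 0], 1.0, atol=1e-10)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(deadline=None, max_examples=20, derandomize=True)
    def test_probability_outputs_normalized_for_arbitrary_instances(self, seed):
        rng = np.random.default_rng(seed)
        data, items, weights, persons, pop = random_instance(rng, n_persons=3, n_items=2)
        r = model.responsibilities(data, items, weights, persons, pop)
        assert np.all(r >= 0)
        np.testing.assert_allclose(r.sum(axis=-1), 1.0, atol=1e-12)
        p = model.class_probabilities(persons, items, pop)
        np.testing.assert_allclose(p.sum(axis=-1), 1.0, atol=1e-12)

    def test_matches_brute_force_normalized_products(self):
        rng = np.random.default_rng(47)
        data, items, weights, persons, pop = random_instance(rng, n_persons=3, n_items=3)
        r = model.responsibilities(data, items, weights, persons, pop)
        for n in range(3):
            for i in range(3):
                terms = np.array(
                    brute_force_cell_terms(data, items, weights, persons, pop, n, i)
                )
                expected = np.exp(terms - logsumexp(terms))
                np.testing.assert_allclose(r[n, i], expected, atol=1e-12)
        np.testing.assert_allclose(r.sum(axis=-1), 1.0, atol=1e-12)
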