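"""Tests of the synthetic-assessment generator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fakemix import model
from fakemix.simulate import (
    NEG_PROPENSITY,
    SimulationDesign,
    default_correlations,
    draw_persons,
    make_desirability_weights,
    simulate,
)
from fakemix.types import ItemParameters


class TestDesirabilityWeights:
    def test_monotone_increasing_is_integer_grid(self):
        np.testing.assert_allclose(
            make_desirability_weights("monotone-increasing", 6), np.arange(7.0)
        )

    def test_midpoint_peak_is_symmetric(self):
        w = make_desirability_weights("peak-at-midpoint", 6)
        assert np.argmax(w) == 3
        assert w[3] == 6.0
        np.testing.assert_allclose(w, w[::-1])
        assert w[0] == 0.0 and w[6] == 0.0

    @pytest.mark.parametrize("shape,peak", [
        ("monotone-increasing", None),
        ("peak-interior", 5),
        ("peak-interior", 4),
        ("peak-at-midpoint", None),
    ])
    def test_range_and_peak_location(self, shape, peak):
        w = make_desirability_weights(shape, 6, peak)
        assert w.min() >= 0.0 and w.max() <= 6.0
        if peak is not None:
            assert np.argmax(w) == peak

    def test_peak_outside_range_rejected(self):
        with pytest.raises(ValueError):
            make_desirability_weights("peak-interior", 6, 9)

    @given(K=st.integers(min_value=1, max_value=10), peak=st.integers(min_value=0, max_value=10))
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_any_trajectory_respects_the_weight_metric(self, K, peak):
        peak = min(peak, K)
        w = make_desirability_weights("peak-interior", K, peak)
        assert w.min() >= 0.0 and w.max() <= 6.0
        assert np.argmax(w) == peak and w[peak] == 6.0


class TestDrawPersons:
    def test_independence_under_identity_correlation(self):
        p = draw_persons(10_000, np.eye(6), seed=1)
        c = np.corrcoef(p.values, rowvar=False)
        off = c[~np.eye(6, dtype=bool)]
        assert np.max(np.abs(off)) < 0.05

    def test_marginal_means_near_zero(self):
        p = draw_persons(4_000, default_correlations(), seed=2)
        assert np.all(np.abs(p.values.mean(axis=0)) < 4.0 / np.sqrt(4_000))

    def test_faking_strategy_inclination_correlation_recovered(self):
        corr = default_correlations()
        p = draw_persons(10_000, corr, seed=3)
        c = np.corrcoef(p.eta, p.psi)[0, 1]
        assert c == pytest.approx(0.32, abs=0.05)

    def test_non_positive_definite_rejected(self):
        bad = np.full((6, 6), 0.99)
        np.fill_diagonal(bad, 1.0)
        bad[0, 1] = bad[1, 0] = -0.99
        with pytest.raises(np.linalg.LinAlgError):
            draw_persons(10, bad, seed=0)


class TestSimulate:
    def test_seeded_runs_are_bit_reproducible(self):
        d = SimulationDesign(n_persons=30, items_per_trait=2, seed=9)
        a = simulate(d, replication=2)
        d2 = SimulationDesign(n_persons=30, items_per_trait=2, seed=9)
        b = simulate(d2, replication=2)
        np.testing.assert_array_equal(a.responses, b.responses)
        np.testing.assert_array_equal(a.times, b.times)
        np.testing.assert_array_equal(a.true_classes, b.true_classes)

    def test_degenerate_class_intercepts_force_s_only(self):
        d0 = SimulationDesign(n_persons=50, items_per_trait=2, seed=13)
        beta = d0.items.beta.copy()
        beta[:, 1:] = NEG_PROPENSITY
        items = ItemParameters(
            alpha_trait=d0.items.alpha_trait, alpha_fake=d0.items.alpha_fake,
            gamma=d0.items.gamma, beta=beta,
            delta_s=d0.items.delta_s, delta_f=d0.items.delta_f,
        )
        d = SimulationDesign(n_persons=50, items_per_trait=2, seed=13, items=items,
                             weights=d0.weights, population=d0.population)
        data = simulate(d)
        assert np.all(data.true_classes == 0)

    def test_response_frequencies_match_category_probabilities(self):
        d = SimulationDesign(n_persons=4_000, items_per_trait=1, seed=17)
        data = simulate(d)
        p = model.category_probabilities(0, data.true_persons, d.items, d.weights)
        i = 0
        cells = data.true_classes[:, i] == 0
        expected = p[cells, i, :].mean(axis=0)
        K1 = d.n_categories
        freq = np.bincount(data.responses[cells, i], minlength=K1) / cells.sum()
        se = np.sqrt(expected * (1 - expected) / cells.sum())
        assert np.all(np.abs(freq - expected) < 4 * se + 1e-3)

    def test_sf_log_times_match_model_implied_mean(self):
        d = SimulationDesign(n_persons=2_000, items_per_trait=2, seed=19)
        data = simulate(d)
        mu = model.rt_log_means(d.items, d.population, data.true_persons)[1]
        cells = data.true_classes == 1
        observed = np.log(data.times[cells]).mean()
        expected = mu[cells].mean()
        se = d.population.sigma_rt[1] / np.sqrt(cells.sum())
        assert observed == pytest.approx(expected, abs=4 * se)

    def test_class_frequencies_match_average_probabilities(self):
        d = SimulationDesign(n_persons=2_000, items_per_trait=10, seed=23)
        data = simulate(d)
        p = model.class_probabilities(data.true_persons, d.items, d.population)
        expected = p.mean(axis=(0, 1))
        freq = np.bincount(data.true_classes.ravel(), minlength=3) / data.true_classes.size
        se = np.sqrt(expected * (1 - expected) / data.true_classes.size)
        assert np.all(np.abs(freq - expected) < 3 * se * 3)  # cells share persons

    def test_median_rt_ordering_matches_empirical_pattern(self):
        d = SimulationDesign(n_persons=2_000, items_per_trait=5, seed=29)
        data = simulate(d)
        med = [np.median(data.times[data.true_classes == c]) for c in range(3)]
        assert med[1] > med[0] > med[2]  # S&F > S-only > F-only
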