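"""Tests of classification tables, assignments, and recovery metrics."""

import numpy as np
import pandas as pd
import pytest

from fakemix import analysis, model
from fakemix.analysis import (
    ClassProbabilityTable,
    class_probability_table,
    fisher_mean_correlation,
    hit_rate,
    modal_assignment,
    recovery_metrics,
    strategy_consistency,
)
from fakemix.estimate import McmcConfig, ModelSpec, PosteriorResult, PriorConfig


def _table(probs):
    probs = np.asarray(probs, dtype=float)
    return ClassProbabilityTable(
        probs=probs,
        item_proportions=probs.mean(axis=0),
        overall=probs.mean(axis=(0, 1)),
        overall_ci=np.zeros((3, 2)),
        mode="conditional",
    )


class TestModalAssignment:
    def test_clear_mode(self):
        t = _table([[[0.6, 0.3, 0.1]]])
        assert modal_assignment(t)[0, 0] == 0

    def test_tie_breaks_to_less_pronounced_strategy(self):
        t = _table([[[0.5, 0.5, 0.0], [0.0, 0.5, 0.5]]])
        np.testing.assert_array_equal(modal_assignment(t)[0], [0, 1])


class TestStrategyConsistency:
    def test_single_class_pattern(self):
        df = strategy_consistency(np.zeros((3, 5), dtype=int))
        assert df.set_index("pattern").loc["one class: S-only", "n_persons"] == 3

    def test_two_class_pattern(self):
        assign = np.array([[1, 2, 1, 2]])
        df = strategy_consistency(assign).set_index("pattern")
        assert df.loc["two classes: S&F/F-only", "n_persons"] == 1

    def test_hand_enumerated_mixture_of_patterns(self):
        assign = np.array([
            [0, 0, 0],  # constant S-only
            [0, 2, 0],  # S-only / F-only
            [1, 2, 1],  # S&F / F-only
            [0, 1, 2],  # all three
        ])
        df = strategy_consistency(assign).set_index("pattern")
        assert df.loc["one class: S-only", "n_persons"] == 1
        assert df.loc["two classes: S-only/F-only", "n_persons"] == 1
        assert df.loc["two classes: S&F/F-only", "n_persons"] == 1
        assert df.loc["three classes", "n_persons"] == 1
        assert df["n_persons"].sum() == 4


class TestHitRate:
    def test_perfect_agreement(self):
        a = np.array([[0, 1], [2, 0]])
        assert hit_rate(a, a) == 100.0

    def test_hand_counted_fraction(self):
        assign = np.array([[0, 1, 2], [0, 1, 2]])
        truth = np.array([[0, 1, 1], [0, 0, 2]])
        assert hit_rate(assign, truth) == pytest.approx(100 * 4 / 6)

    def test_missing_truth_rejected(self):
        with pytest.raises(ValueError):
            hit_rate(np.zeros((2, 2)), None)


class TestRecoveryMetrics:
    def test_exact_recovery(self):
        x = np.arange(5.0)
        rep = recovery_metrics({"a": [x]}, {"a": [x]}, correlation_families=("a",))
        row = rep["a"]
        assert row["bias"] == 0 and row["rmse"] == 0
        assert row["correlation"] == pytest.approx(1.0, abs=1e-4)

    def test_constant_shift(self):
        x = np.arange(5.0)
        rep = recovery_metrics({"a": [x + 0.5]}, {"a": [x]})
        assert rep["a"]["bias"] == pytest.approx(0.5)
        assert rep["a"]["rmse"] == pytest.approx(0.5)

    def test_noise_limit(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 20_000)
        est = x + rng.normal(0, 0.3, x.size)
        rep = recovery_metrics({"a": [est]}, {"a": [x]})
        assert rep["a"]["bias"] == pytest.approx(0.0, abs=0.02)
        assert rep["a"]["rmse"] == pytest.approx(0.3, abs=0.02)

    def test_fisher_aggregation(self):
        assert fisher_mean_correlation([0.5, 0.5]) == pytest.approx(0.5)
        z = np.tanh(np.mean(np.arctanh([0.2, 0.9])))
        assert fisher_mean_correlation([0.2, 0.9]) == pytest.approx(z)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            recovery_metrics({"a": [np.zeros(3)]}, {"a": [np.zeros(4)]})


class TestClassProbabilityTable:
    def test_undefined_for_nonmixture(self, tiny_design, tiny_data, tiny_fit):
        spec = ModelSpec(variant="nonmixture_mgpcm", weights=tiny_design.weights)
        res = PosteriorResult(
            spec=spec, draws=tiny_fit.draws, person_draws=tiny_fit.person_draws,
            loglik_resp=None, loglik_joint=None, mcmc=McmcConfig(), priors=PriorConfig(),
        )
        with pytest.raises(ValueError):
            class_probability_table(res, tiny_data)

    def test_rows_sum_to_one_and_aggregation_consistent(self, tiny_data, tiny_fit):
        table = class_probability_table(tiny_fit, tiny_data, mode="conditional", thin=25)
        np.testing.assert_allclose(table.probs.sum(axis=-1), 1.0, atol=1e-10)
        np.testing.assert_allclose(
            table.overall, table.item_proportions.mean(axis=0), atol=1e-12
        )

    def test_single_draw_structural_matches_kernel(self, tiny_design, tiny_data, tiny_fit):
        table = class_probability_table(tiny_fit, tiny_data, mode="structural",
                                        thin=10**9)  # first draw of each chain
        # recompute from the first stored draws directly
        expected = np.zeros_like(table.probs)
        count = 0
        for ch in range(tiny_fit.n_chains):
            s = tiny_fit.state_at(ch, 0)
            items = tiny_design.items
            from fakemix.types import ItemParameters, PersonParameters, PopulationParameters
            it = ItemParameters(
                alpha_trait=s["alpha_trait"], alpha_fake=s["alpha_fake"], gamma=s["gamma"],
                beta=s["beta"], delta_s=s["delta_s"], delta_f=s["delta_f"],
            )
            pop = PopulationParameters(
                corr=np.eye(6), nu_phi=float(s["nu_phi"]), nu_psi=float(s["nu_psi"]),
                lam=float(s["lam"]), sigma_rt=s["sigma_rt"],
            )
            persons = PersonParameters(values=s["X"], n_traits=3)
            expected += model.class_probabilities(persons, it, pop)
            count += 1
        np.testing.assert_allclose(table.probs, expected / count, atol=1e-6)

    def test_conditional_matches_responsibilities_oracle(self, tiny_design, tiny_data, tiny_fit):
        table = class_probability_table(tiny_fit, tiny_data, mode="conditional", thin=10**9)
        from fakemix.types import ItemParameters, PersonParameters, PopulationParameters

        expected = np.zeros_like(table.probs)
        count = 0
        for ch in range(tiny_fit.n_chains):
            s = tiny_fit.state_at(ch, 0)
            it = ItemParameters(
                alpha_trait=s["alpha_trait"], alpha_fake=s["alpha_fake"], gamma=s["gamma"],
                beta=s["beta"], delta_s=s["delta_s"], delta_f=s["delta_f"],
            )
            pop = PopulationParameters(
                corr=np.eye(6), nu_phi=float(s["nu_phi"]), nu_psi=float(s["nu_psi"]),
                lam=float(s["lam"]), sigma_rt=s["sigma_rt"],
            )
            persons = PersonParameters(values=s["X"], n_traits=3)
            expected += model.responsibilities(tiny_data, it, tiny_design.weights, persons, pop)
            count += 1
        np.testing.assert_allclose(table.probs, expected / count, atol=1e-6)

    def test_structural_and_conditional_coincide_for_identical_class_models(
        self, tiny_design, tiny_data, tiny_fit
    ):
        # force identical response and RT models across classes in the draws
        draws = {k: v.copy() for k, v in tiny_fit.draws.items()}
        draws["alpha_fake"][:] = 0.0
        draws["alpha_trait"][:] = 0.0
        draws["gamma"][:] = 0.0
        draws["delta_s"][:] = 0.0
        draws["delta_f"][:] = 0.0
        draws["sigma_rt"][:] = 0.5
        res = PosteriorResult(
            spec=tiny_fit.spec, draws=draws, person_draws=tiny_fit.person_draws,
            loglik_resp=None, loglik_joint=None, mcmc=tiny_fit.mcmc, priors=tiny_fit.priors,
        )
        t_struct = class_probability_table(res, tiny_data, mode="structural", thin=50)
        t_cond = class_probability_table(res, tiny_data, mode="conditional", thin=50)
        np.testing.assert_allclose(t_struct.probs, t_cond.probs, atol=1e-9)

    def test_to_frame_layout(self, tiny_data, tiny_fit):
        table = class_probability_table(tiny_fit, tiny_data, thin=100)
        df = table.to_frame(tiny_data)
        assert isinstance(df, pd.DataFrame)
        assert len(df) == tiny_data.n_persons * tiny_data.n_items
        assert {"person_id", "item_id", "p_S-only"}.issubset(df.columns)
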