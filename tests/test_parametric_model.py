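import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import MULTIPLY_PAIR
from infoseek.bias_statistics import (
    AggregateTables,
    aggregate_tables,
    positive_evidence_approach,
    sampling_favorite,
)
from infoseek.parametric_model import (
    MEAN_FIRST_CARD,
    ModelParams,
    choice_probabilities,
    crossvalidate,
    effective_card,
    fit_aggregate,
    hierarchical_fit,
    omega,
    option_values,
    predict_stage1,
    predict_stage2,
    stage1_values,
    stage2_values,
)
from infoseek.synthetic_data import PopulationSpec, generate_population
from infoseek.task_engine import Direction, Operation

REDUCED = ModelParams(beta1=1.0, beta2=2.0, beta3=4.0, tau=1.0)


class TestEffectiveCard:
    def test_inversion_examples(self):
        assert effective_card(10, Direction.SMALL) == 1
        assert effective_card(9, Direction.SMALL) == 2
        assert effective_card(1, Direction.SMALL) == 10

    def test_big_identity(self):
        assert effective_card(5, Direction.BIG) == 5

    def test_mean_first_card(self):
        assert MEAN_FIRST_CARD == 5.5


class TestOmega:
    def test_zero_at_equality(self):
        assert omega(1.7, 1.7) == 0.0

    def test_limit_minus_quarter(self):
        assert omega(0.0, 60.0) == pytest.approx(-0.25, abs=1e-9)

    @given(d=st.floats(-30, 30))
    def test_symmetric_in_sign(self, d):
        assert omega(0.0, d) == pytest.approx(omega(d, 0.0))

    @given(a=st.floats(-20, 20), b=st.floats(-20, 20))
    def test_bounded(self, a, b):
        assert -0.25 <= omega(a, b) <= 0.0


class TestOptionValues:
    def test_stage1_reduced_example(self):
        vals = stage1_values(7.0, "AA", REDUCED)
        assert vals["A"] == pytest.approx(1.5)
        assert vals["B"] == pytest.approx(-1.5)

    def test_stage1_aa_beta4_bonus_to_b(self):
        base = stage1_values(7.0, "AA", REDUCED)
        full = stage1_values(7.0, "AA",
                             ModelParams(1.0, 2.0, 4.0, 1.0, beta4=0.1))
        assert full["B"] - base["B"] == pytest.approx(0.1 * 5.5)
        assert full["A"] == base["A"]

    def test_stage1_ab_beta4_bonus_to_a_scales_with_card(self):
        base = stage1_values(7.0, "AB", REDUCED)
        full = stage1_values(7.0, "AB",
                             ModelParams(1.0, 2.0, 4.0, 1.0, beta4=0.1))
        assert full["A"] - base["A"] == pytest.approx(0.7)

    def test_stage1_beta5_devalues_sampling_on_aa_only(self):
        full = ModelParams(1.0, 2.0, 4.0, 1.0, beta5=0.2)
        aa_base = stage1_values(7.0, "AA", REDUCED)["sampleA"]
        aa_full = stage1_values(7.0, "AA", full)["sampleA"]
        assert aa_full - aa_base == pytest.approx(-1.4)
        assert stage1_values(7.0, "AB", full)["sampleB"] \
            == stage1_values(7.0, "AB", REDUCED)["sampleB"]

    def test_stage2_beta6_example(self):
        params = ModelParams(beta1=2.0, beta2=0.0, beta3=0.0, tau=1.0,
                             beta6=0.5)
        vals = stage2_values(7.0, 3.0, params)
        assert vals["A"] == pytest.approx(8.0)
        # each sampling value shifts by beta6*(own - other), so the A-B
        # difference is 2*beta6*(c1-c2)
        assert vals["sampleA"] - vals["sampleB"] == pytest.approx(4.0)

    def test_stage1_option_set_excludes_unpurchasable_row(self):
        vals = option_values(stage=1, trial_type="AB", card_eff=4.0,
                             params=REDUCED)
        assert "sampleA" not in vals and "sampleB" in vals

    def test_unknown_stage_rejected(self):
        with pytest.raises(ValueError):
            option_values(stage=3, params=REDUCED)


class TestChoiceProbabilities:
    def test_equal_values_uniform(self):
        p = choice_probabilities({"A": 2.0, "B": 2.0, "s": 2.0}, tau=1.3)
        assert all(v == pytest.approx(1 / 3) for v in p.values())

    def test_tau_zero_uniform(self):
        p = choice_probabilities({"A": 5.0, "B": -3.0}, tau=0.0)
        assert all(v == pytest.approx(0.5) for v in p.values())

    @given(v=st.lists(st.floats(-50, 50), min_size=2, max_size=4),
           tau=st.floats(0, 5))
    def test_sums_to_one(self, v, tau):
        p = choice_probabilities(dict(enumerate(v)), tau)
        assert sum(p.values()) == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            choice_probabilities({}, 1.0)


class TestPredictions:
    def test_reduced_big_small_symmetric(self):
        for tt in ("AA", "AB"):
            big = predict_stage1(REDUCED, Direction.BIG, tt)
            small = predict_stage1(REDUCED, Direction.SMALL, tt)
            # SMALL at card i == BIG at card 11-i
            np.testing.assert_allclose(
                small["p_sample"].to_numpy(),
                big["p_sample"].to_numpy()[::-1], atol=1e-12)

    def test_reduced_predictions_have_zero_bias_statistics(self):
        tables = _tables_from_predictions(REDUCED, REDUCED)
        assert positive_evidence_approach(
            tables, Operation.MULTIPLY, "AA").point == pytest.approx(0.0)
        assert sampling_favorite(
            tables, Operation.MULTIPLY, "STRONG").point == pytest.approx(0.0)

    def test_beta5_induces_positive_pea_in_predictions(self):
        full = ModelParams(1.0, 2.0, 4.0, 1.0, beta5=0.15)
        tables = _tables_from_predictions(full, full)
        assert positive_evidence_approach(
            tables, Operation.MULTIPLY, "AA").point > 0.05

    def test_beta5_raises_guessing_on_aa_over_ab(self):
        full = ModelParams(1.0, 2.0, 4.0, 1.0, beta5=0.15)
        aa = 1 - predict_stage1(full, Direction.BIG, "AA")["p_sample"]
        ab = 1 - predict_stage1(full, Direction.BIG, "AB")["p_sample"]
        assert aa.mean() > ab.mean()

    def test_beta6_induces_positive_favorite_in_predictions(self):
        full = ModelParams(1.0, 2.0, 4.0, 1.0, beta6=0.4)
        tables = _tables_from_predictions(full, full)
        assert sampling_favorite(
            tables, Operation.MULTIPLY, "STRONG").point > 1.0


def _tables_from_predictions(params_s1, params_s2):
    """AggregateTables whose cells hold exact model probabilities."""
    stage1, stage2 = {}, {}
    for d in Direction:
        cond = f"multiply_{d.value}"
        s1 = np.zeros((2, 10, 5))
        for t, tt in enumerate(("AA", "AB")):
            f = predict_stage1(params_s1, d, tt)
            s1[t, :, 0] = 1.0
            s1[t, :, 1] = 1 - f["p_sample"].to_numpy()
            s1[t, :, 2] = f["p_choose_a"].to_numpy()
            s1[t, :, 3] = f["p_choose_b"].to_numpy()
            s1[t, :, 4] = f["p_sample"].to_numpy()
        f2 = predict_stage2(params_s2, d)
        s2 = np.zeros((10, 10, 6))
        s2[:, :, 0] = 1.0
        s2[:, :, 1] = (f2["p_choose_a"] + f2["p_choose_b"]) \
            .to_numpy().reshape(10, 10)
        s2[:, :, 2] = f2["p_choose_a"].to_numpy().reshape(10, 10)
        s2[:, :, 3] = f2["p_choose_b"].to_numpy().reshape(10, 10)
        s2[:, :, 4] = f2["p_sample_a"].to_numpy().reshape(10, 10)
        s2[:, :, 5] = f2["p_sample_b"].to_numpy().reshape(10, 10)
        stage1[cond] = s1
        stage2[cond] = s2
    from infoseek.task_engine import Condition

    conds = tuple(Condition.from_name(c) for c in stage1)
    return AggregateTables(conds, stage1, stage2)


class TestFitAggregate:
    def test_noise_free_self_consistency(self):
        truth = ModelParams(1.0, 2.0, 4.0, 1.0, beta4=0.1, beta5=0.1)
        tables = _tables_from_predictions(truth, truth)
        fit = fit_aggregate(tables, 1, Operation.MULTIPLY, full=True,
                            n_restarts=15, seed=4)
        assert fit.objective < 1e-6
        # identified combinations: tau-scaled betas
        assert fit.params.tau * fit.params.beta4 == pytest.approx(0.1,
                                                                  rel=0.05)
        assert fit.params.tau * fit.params.beta5 == pytest.approx(0.1,
                                                                  rel=0.05)

    def test_same_seed_identical(self):
        tables = _tables_from_predictions(REDUCED, REDUCED)
        f1 = fit_aggregate(tables, 1, Operation.MULTIPLY, n_restarts=5,
                           seed=7)
        f2 = fit_aggregate(tables, 1, Operation.MULTIPLY, n_restarts=5,
                           seed=7)
        assert f1.params == f2.params and f1.objective == f2.objective

    def test_tau_canonicalized_nonnegative(self):
        tables = _tables_from_predictions(REDUCED, REDUCED)
        fit = fit_aggregate(tables, 2, Operation.MULTIPLY, n_restarts=8,
                            seed=1)
        assert fit.params.tau >= 0

    def test_boxes_logged(self):
        tables = _tables_from_predictions(REDUCED, REDUCED)
        fit = fit_aggregate(tables, 1, Operation.MULTIPLY, n_restarts=2,
                            seed=0)
        assert set(fit.boxes) == {"beta1", "beta2", "beta3", "tau"}

    def test_empty_tables_rejected(self):
        empty = AggregateTables(
            (), {"multiply_big": np.zeros((2, 10, 5)),
                 "multiply_small": np.zeros((2, 10, 5))},
            {"multiply_big": np.zeros((10, 10, 6)),
             "multiply_small": np.zeros((10, 10, 6))})
        with pytest.raises(ValueError):
            fit_aggregate(empty, 1, Operation.MULTIPLY)


class TestCrossValidation:
    def test_fold_assignment_reproducible(self, reduced_multiply_dataset):
        cv1 = crossvalidate(reduced_multiply_dataset, 1, Operation.MULTIPLY,
                            k=4, seed=5, n_restarts=2)
        cv2 = crossvalidate(reduced_multiply_dataset, 1, Operation.MULTIPLY,
                            k=4, seed=5, n_restarts=2)
        assert cv1.equals(cv2)

    def test_too_many_folds_rejected(self, reduced_multiply_dataset):
        with pytest.raises(ValueError, match="exceeds"):
            crossvalidate(reduced_multiply_dataset, 1, Operation.MULTIPLY,
                          k=10 ** 6)


class TestHierarchicalFit:
    def test_identical_subjects_near_zero_covariance(self):
        spec = PopulationSpec(n_subjects=12, policy="PARAMETRIC_FULL",
                              mean={"beta4": 0.1},
                              conditions=Operation.MULTIPLY, seed=31)
        ds = generate_population(spec)
        fit = hierarchical_fit(ds, Operation.MULTIPLY, max_iter=3,
                               laplace=False)
        # all subjects share one parameter vector; MAP scatter shrinks
        scatter = fit.subject_params[["beta4", "beta5", "beta6"]].var()
        assert scatter.max() < 0.5

    def test_requires_two_subjects(self):
        spec = PopulationSpec(n_subjects=1, policy="PARAMETRIC_REDUCED",
                              conditions=Operation.MULTIPLY, seed=32)
        ds = generate_population(spec)
        with pytest.raises(ValueError):
            hierarchical_fit(ds, Operation.MULTIPLY)
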