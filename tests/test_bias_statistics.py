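import numpy as np
import pandas as pd
import pytest

from conftest import MULTIPLY_BIG, MULTIPLY_PAIR, MULTIPLY_SMALL
from infoseek.bias_statistics import (
    MissingCellError,
    aggregate_tables,
    bootstrap_ci,
    policy_aggregate_tables,
    positive_evidence_approach,
    rejecting_unsampled,
    sampling_depth,
    sampling_favorite,
)
from infoseek.cli_io.schema import GameplayDataset
from infoseek.optimal_dp import expected_cards_optimal
from infoseek.synthetic_data import PopulationSpec, generate_population
from infoseek.task_engine import Operation


def _trial_row(uid=1, gameplay=1, block=1, trial=1, condition="multiply_big",
               offered_row="A", a1=5, a2=7, b1=3, b2=2, n_samples=0,
               chosen_row="A", samples=()):
    """Hand-built valid trial row (caller ensures consistency)."""
    from infoseek.task_engine import Board, Condition

    board = Board((a1, a2), (b1, b2))
    win = board.winner(Condition.from_name(condition))
    total_cost = {0: 0, 1: 10, 2: 25, 3: 45}[n_samples]
    rec = {
        "uid": uid, "gameplay": gameplay, "block": block, "trial": trial,
        "condition": condition, "trial_type": "AA" if offered_row == "A"
        else "AB", "a1": a1, "a2": a2, "b1": b1, "b2": b2, "first_row": 0,
        "offered_row": offered_row, "n_samples": n_samples,
        "guess_stage": n_samples + 1, "chosen_row": chosen_row,
        "winning_row": win, "total_cost": total_cost,
        "points": (60 if chosen_row == win else -50) - total_cost,
    }
    for k in range(3):
        rec[f"s{k + 1}_row"] = samples[k][0] if k < len(samples) else None
        rec[f"s{k + 1}_value"] = samples[k][1] if k < len(samples) else None
    return rec


@pytest.fixture()
def hand_built_dataset():
    """10 trials with counts small enough to verify by hand."""
    rows = [
        # multiply_big AA, card 5: 2 guesses (one A, one B), 1 sample
        _trial_row(uid=1, trial=1, a1=5, chosen_row="A"),
        _trial_row(uid=1, trial=2, a1=5, chosen_row="B"),
        _trial_row(uid=1, trial=3, a1=5, n_samples=1, samples=[("A", 7)]),
        # multiply_big AB, card 5: 1 guess A; 1 sampler who then samples A
        _trial_row(uid=2, trial=1, offered_row="B", a1=5, chosen_row="A"),
        _trial_row(uid=2, trial=2, offered_row="B", a1=5, b1=3, n_samples=2,
                   samples=[("B", 3), ("A", 7)], chosen_row="B"),
        # multiply_small AA card 5: all guess
        _trial_row(uid=3, trial=1, condition="multiply_small", a1=5,
                   chosen_row="B"),
        _trial_row(uid=3, trial=2, condition="multiply_small", a1=5,
                   chosen_row="B"),
        # multiply_small AB card 5: sampler samples B at stage 2
        _trial_row(uid=3, trial=3, condition="multiply_small",
                   offered_row="B", a1=5, b1=3, n_samples=2,
                   samples=[("B", 3), ("B", 2)], chosen_row="A"),
        # multiply_big AA card 9
        _trial_row(uid=4, trial=1, a1=9, a2=2, chosen_row="A"),
        _trial_row(uid=4, trial=2, a1=9, a2=2, n_samples=1,
                   samples=[("A", 2)], chosen_row="B"),
    ]
    return GameplayDataset(trials=pd.DataFrame(rows))


class TestAggregateTables:
    def test_hand_counts(self, hand_built_dataset):
        tables = aggregate_tables(hand_built_dataset, MULTIPLY_PAIR,
                                  validate=True)
        cell = tables.stage1_cell(MULTIPLY_BIG, "AA", 5)
        assert cell["n"] == 3 and cell["n_guess"] == 2
        assert cell["n_choose_a"] == 1 and cell["n_choose_b"] == 1
        assert cell["n_sample"] == 1
        cell = tables.stage1_cell(MULTIPLY_BIG, "AB", 5)
        assert cell["n"] == 2 and cell["n_guess"] == 1
        s2 = tables.stage2_cell(MULTIPLY_BIG, 5, 3)
        assert s2["n"] == 1 and s2["n_sample_a"] == 1 and s2["n_sample_b"] == 0
        s2s = tables.stage2_cell(MULTIPLY_SMALL, 5, 3)
        assert s2s["n_sample_b"] == 1

    def test_p_guess_accessor(self, hand_built_dataset):
        tables = aggregate_tables(hand_built_dataset, MULTIPLY_PAIR)
        p = tables.p_guess(MULTIPLY_BIG, "AA")
        assert p[4] == pytest.approx(2 / 3)  # card 5
        assert p[8] == pytest.approx(1 / 2)  # card 9
        assert np.isnan(p[0])  # card 1 never seen

    def test_empty_cells_are_missing_not_zero(self, hand_built_dataset):
        tables = aggregate_tables(hand_built_dataset, MULTIPLY_PAIR)
        assert np.isnan(tables.p_sample_a(MULTIPLY_BIG)[0, 0])

    def test_all_guess_dataset_pguess_one(self):
        spec = PopulationSpec(n_subjects=20, policy="ALWAYS_GUESS",
                              conditions=Operation.MULTIPLY, seed=5)
        ds = generate_population(spec)
        tables = aggregate_tables(ds, MULTIPLY_PAIR)
        for cond in MULTIPLY_PAIR:
            for tt in ("AA", "AB"):
                p = tables.p_guess(cond, tt)
                assert np.nanmin(p) == 1.0

    def test_per_subject_flag_changes_weighting(self, hand_built_dataset):
        pooled = aggregate_tables(hand_built_dataset, MULTIPLY_PAIR)
        per_subj = aggregate_tables(hand_built_dataset, MULTIPLY_PAIR,
                                    per_subject=True)
        # card-5 AA cell: uid 1 contributes 3 trials pooled, 1 unit here
        assert per_subj.stage1_cell(MULTIPLY_BIG, "AA", 5)["n"] == 1
        assert pooled.stage1_cell(MULTIPLY_BIG, "AA", 5)["n"] == 3
        assert per_subj.p_guess(MULTIPLY_BIG, "AA")[4] == pytest.approx(2 / 3)

    def test_invalid_rows_rejected(self, hand_built_dataset):
        bad = hand_built_dataset.trials.copy()
        bad.loc[0, "total_cost"] = 7
        with pytest.raises(ValueError, match="invalid"):
            aggregate_tables(GameplayDataset(trials=bad), MULTIPLY_PAIR,
                             validate=True)


class TestStatisticsNulls:
    def test_identical_tables_give_zero(self, hand_built_dataset):
        tables = aggregate_tables(hand_built_dataset, MULTIPLY_PAIR)
        # overwrite SMALL tables with BIG's counts: all statistics must be 0
        tables.stage1["multiply_small"] = tables.stage1["multiply_big"]
        tables.stage2["multiply_small"] = tables.stage2["multiply_big"]
        pea = positive_evidence_approach(tables, Operation.MULTIPLY, "AA",
                                         on_missing="skip")
        assert pea.point == 0.0
        fav = sampling_favorite(tables, Operation.MULTIPLY, "STRONG",
                                on_missing="skip")
        assert fav.point == 0.0

    def test_optimal_policy_statistics_exactly_zero(self, qt_multiply):
        tables = policy_aggregate_tables(qt_multiply)
        assert positive_evidence_approach(
            tables, Operation.MULTIPLY, "AA").point == 0.0
        assert positive_evidence_approach(
            tables, Operation.MULTIPLY, "AB").point == 0.0
        # cards where the policy never guesses have undefined choice
        # probabilities in that trial type; they drop out symmetrically
        with pytest.warns(UserWarning, match="empty cell"):
            assert rejecting_unsampled(tables, MULTIPLY_BIG,
                                       on_missing="skip").point == 0.0
            assert rejecting_unsampled(tables, MULTIPLY_SMALL,
                                       on_missing="skip").point == 0.0
        assert sampling_favorite(
            tables, Operation.MULTIPLY, "STRONG").point == 0.0
        assert sampling_favorite(
            tables, Operation.MULTIPLY, "WEAK").point == 0.0

    def test_optimal_agent_simulation_near_zero(self,
                                                optimal_multiply_dataset):
        tables = aggregate_tables(optimal_multiply_dataset, MULTIPLY_PAIR)
        pea = positive_evidence_approach(tables, Operation.MULTIPLY, "AA",
                                         on_missing="skip")
        assert abs(pea.point) < 0.25  # pure sampling noise

    def test_missing_cells_raise_by_default(self, hand_built_dataset):
        tables = aggregate_tables(hand_built_dataset, MULTIPLY_PAIR)
        with pytest.raises(MissingCellError):
            positive_evidence_approach(tables, Operation.MULTIPLY, "AA")

    def test_shuffling_trials_invariant(self, hand_built_dataset):
        tables = aggregate_tables(hand_built_dataset, MULTIPLY_PAIR)
        shuffled = GameplayDataset(trials=hand_built_dataset.trials.sample(
            frac=1.0, random_state=4))
        tables2 = aggregate_tables(shuffled, MULTIPLY_PAIR)
        for cond in ("multiply_big", "multiply_small"):
            np.testing.assert_array_equal(tables.stage1[cond],
                                          tables2.stage1[cond])


class TestStatisticSigns:
    """Bias statistics respond to the matching beta of simulating agents."""

    def _dataset(self, seed, **means):
        spec = PopulationSpec(
            n_subjects=900, policy="PARAMETRIC_FULL",
            mean=means, conditions=Operation.MULTIPLY, seed=seed)
        return generate_population(spec)

    def test_beta5_drives_positive_evidence_approach(self):
        low = self._dataset(11, beta5=0.05)
        high = self._dataset(12, beta5=0.2)
        stats = []
        for ds in (low, high):
            tables = aggregate_tables(ds, MULTIPLY_PAIR)
            stats.append(positive_evidence_approach(
                tables, Operation.MULTIPLY, "AA", on_missing="skip").point)
        assert 0 < stats[0] < stats[1]

    def test_beta4_drives_rejecting_unsampled(self):
        ds = self._dataset(13, beta4=0.15)
        tables = aggregate_tables(ds, MULTIPLY_PAIR)
        assert rejecting_unsampled(tables, MULTIPLY_BIG,
                                   on_missing="skip").point > 0

    def test_beta6_drives_sampling_favorite(self):
        ds = self._dataset(14, beta6=0.5)
        tables = aggregate_tables(ds, MULTIPLY_PAIR)
        strong = sampling_favorite(tables, Operation.MULTIPLY, "STRONG",
                                   on_missing="skip")
        weak = sampling_favorite(tables, Operation.MULTIPLY, "WEAK",
                                 on_missing="skip")
        assert strong.point > 0 and weak.point > 0


class TestBootstrap:
    def test_same_seed_identical(self, hand_built_dataset):
        fn = (lambda t: positive_evidence_approach(
            t, Operation.MULTIPLY, "AA", on_missing="skip").point)
        r1 = bootstrap_ci(hand_built_dataset, fn, MULTIPLY_PAIR, n_boot=50,
                          sample_size=20, seed=9)
        r2 = bootstrap_ci(hand_built_dataset, fn, MULTIPLY_PAIR, n_boot=50,
                          sample_size=20, seed=9)
        assert (r1.point, r1.ci_low, r1.ci_high) \
            == (r2.point, r2.ci_low, r2.ci_high)

    def test_constant_statistic_zero_width(self, hand_built_dataset):
        r = bootstrap_ci(hand_built_dataset, lambda t: 1.25, MULTIPLY_PAIR,
                         n_boot=40, sample_size=10, seed=1)
        assert r.ci_low == r.ci_high == r.point == 1.25

    def test_ci_brackets_point_on_real_data(self, optimal_multiply_dataset):
        fn = (lambda t: positive_evidence_approach(
            t, Operation.MULTIPLY, "AB", on_missing="skip").point)
        r = bootstrap_ci(optimal_multiply_dataset, fn, MULTIPLY_PAIR,
                         n_boot=200, sample_size=800, seed=3)
        assert r.ci_low <= r.point <= r.ci_high
        assert r.ci_low <= 0.0 <= r.ci_high  # optimal agents: truth is 0


class TestSamplingDepth:
    def test_optimal_agent_zero_depth(self, optimal_multiply_dataset,
                                      qt_multiply):
        depth, retest = sampling_depth(optimal_multiply_dataset, qt_multiply)
        assert depth["rel_depth"].abs().max() == 0.0

    def test_always_guess_matches_negative_expectation(self, qt_multiply):
        spec = PopulationSpec(n_subjects=150, policy="ALWAYS_GUESS",
                              conditions=Operation.MULTIPLY, seed=21)
        ds = generate_population(spec)
        depth, _ = sampling_depth(ds, qt_multiply, method="expectation")
        expected = -np.mean([expected_cards_optimal(t)
                             for t in qt_multiply.values()])
        assert depth["rel_depth"].mean() == pytest.approx(expected, abs=0.02)

    def test_stable_subjects_reproduce_across_gameplays(self, qt_multiply):
        # stable per-subject sampling propensity (spread in beta2) -> r > 0
        cov = np.zeros((7, 7))
        cov[1, 1] = 2.25
        spec = PopulationSpec(n_subjects=150, policy="PARAMETRIC_REDUCED",
                              cov=cov, conditions=Operation.MULTIPLY,
                              n_gameplays=2, seed=22)
        ds = generate_population(spec)
        _, retest = sampling_depth(ds, qt_multiply)
        assert retest > 0.5

    def test_single_gameplay_subjects_no_retest(self, qt_multiply):
        spec = PopulationSpec(n_subjects=10, policy="OPTIMAL",
                              conditions=Operation.MULTIPLY, seed=23)
        ds = generate_population(spec)
        _, retest = sampling_depth(ds, qt_multiply)
        assert np.isnan(retest)
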