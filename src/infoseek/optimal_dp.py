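"""Backward-induction solution of each condition of the card game.

Every reachable canonical state gets action values: ``q_guess`` for guessing
either row (expected points net of costs paid) and ``q_sample`` for each
purchasable row (expected best-action value of the successor state). All
expectations are taken under the non-tied-board measure, with transition
probabilities proportional to the number of non-tied completions consistent
with each revealed card value.

An optional per-turn ``extra_sample_cost`` implements the subjective-cost
variant of the model (it is charged per sample action on top of the game's
10/15/20 point schedule, without appearing in the recorded point totals).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import pandas as pd

from .task_engine import (
    CARD_VALUES,
    SAMPLE_COSTS,
    STAGE_ENTRY_COST,
    WIN_POINTS,
    LOSS_POINTS,
    Board,
    Condition,
    IllegalActionError,
    Operation,
    Stage,
    TrialState,
    _completion_counts,
)

__all__ = ["StateValues", "QTable", "solve", "solve_cached",
           "q_guess", "relative_value_of_guessing",
           "expected_cards_optimal", "replay_optimal", "qtable_to_frame"]

#: Total cost paid after sampling at every opportunity (10 + 15 + 20).
FULL_COST = sum(SAMPLE_COSTS.values())

#: Guess value in any non-tied terminal state: certain win net of all costs.
TERMINAL_GUESS_VALUE = WIN_POINTS - FULL_COST


@dataclass(frozen=True)
class StateValues:
    """Action values of one canonical state."""

    q_guess_a: float
    q_guess_b: float
    q_sample: dict  # row -> value, one entry per purchasable row
    p_win_a: float
    weight: int  # number of non-tied completions (state probability mass)

    @property
    def q_guess_max(self) -> float:
        return max(self.q_guess_a, self.q_guess_b)

    @property
    def q_sample_max(self) -> float:
        return max(self.q_sample.values())

    @property
    def q_star(self) -> float:
        return max(self.q_guess_max, self.q_sample_max)

    @property
    def best_guess_row(self) -> str:
        return "A" if self.q_guess_a >= self.q_guess_b else "B"

    @property
    def guess_is_optimal(self) -> bool:
        """Greedy policy with ties broken toward guessing."""
        return self.q_guess_max >= self.q_sample_max

    @property
    def best_sample_row(self) -> str:
        rows = sorted(self.q_sample)  # deterministic: 'A' preferred on ties
        return max(rows, key=lambda r: (self.q_sample[r], r == "A"))


@dataclass
class QTable:
    condition: Condition
    extra_sample_cost: float = 0.0
    entries: dict = field(default_factory=dict)  # state key -> StateValues

    def state_values(self, state: TrialState) -> StateValues:
        return self.entries[state.key()]

    def stage1(self, first_card: int, offered_row: str) -> StateValues:
        return self.entries[(1, (first_card,), (), offered_row)]

    def stage2(self, revealed_a, revealed_b) -> StateValues:
        return self.entries[(2, tuple(sorted(revealed_a)),
                             tuple(sorted(revealed_b)), None)]


def q_guess(state: TrialState, row: str) -> float:
    """Expected points of guessing ``row`` now: 60*p(win) - 50*p(lose) - costs."""
    from .task_engine import win_probability

    p = win_probability(state, row)
    return WIN_POINTS * p + LOSS_POINTS * (1.0 - p) - state.total_cost


def _state_weight(condition: Condition, rev_a: tuple, rev_b: tuple) -> int:
    wa, wb, _ = _completion_counts(condition, rev_a, rev_b)
    return wa + wb


def _multisets(n: int):
    return list(itertools.combinations_with_replacement(CARD_VALUES, n))


def solve(condition: Condition, extra_sample_cost: float = 0.0) -> QTable:
    """Solve one condition by backward induction over all canonical states."""
    table = QTable(condition, extra_sample_cost)
    ec = float(extra_sample_cost)

    def guess_values(rev_a, rev_b, cost):
        wa, wb, _ = _completion_counts(condition, rev_a, rev_b)
        total = wa + wb
        p_a = wa / total
        qa = WIN_POINTS * p_a + LOSS_POINTS * (1 - p_a) - cost
        qb = WIN_POINTS * (1 - p_a) + LOSS_POINTS * p_a - cost
        return qa, qb, p_a, total

    def child_key(stage, rev_a, rev_b, row, drawn):
        if row == "A":
            rev_a = tuple(sorted(rev_a + (drawn,)))
        else:
            rev_b = tuple(sorted(rev_b + (drawn,)))
        return (stage + 1, rev_a, rev_b, None)

    # Stage 3: three cards revealed, one hidden. Sampling reveals the last
    # card; every non-tied terminal board is then a certain win worth
    # 60 - 45 points, so the sample value is constant.
    for na in (2, 1):
        nb = 3 - na
        for rev_a in _multisets(na):
            for rev_b in _multisets(nb):
                weight = _state_weight(condition, rev_a, rev_b)
                if weight == 0:
                    continue  # unreachable under the non-tie measure
                qa, qb, p_a, _ = guess_values(rev_a, rev_b,
                                              STAGE_ENTRY_COST[Stage.STAGE3])
                row = "A" if na == 1 else "B"
                qs = TERMINAL_GUESS_VALUE - ec
                table.entries[(3, rev_a, rev_b, None)] = StateValues(
                    qa, qb, {row: qs}, p_a, weight)

    # Stage 2: two cards revealed. AA layout has both on row A (only row B
    # purchasable); AB layout has one per row (both rows purchasable).
    def sample_value(stage, rev_a, rev_b, row, weight):
        acc = 0.0
        for drawn in CARD_VALUES:
            child = table.entries.get(child_key(stage, rev_a, rev_b, row, drawn))
            if child is None:
                continue
            acc += child.weight * child.q_star
        return acc / weight - ec

    for rev_a, rev_b, rows in (
        [(ra, (), ("B",)) for ra in _multisets(2)]
        + [((a1,), (b1,), ("A", "B"))
           for a1 in CARD_VALUES for b1 in CARD_VALUES]
    ):
        rev_a = tuple(sorted(rev_a))
        weight = _state_weight(condition, rev_a, rev_b)
        if weight == 0:
            continue
        qa, qb, p_a, _ = guess_values(rev_a, rev_b,
                                      STAGE_ENTRY_COST[Stage.STAGE2])
        qs = {row: sample_value(2, rev_a, rev_b, row, weight) for row in rows}
        table.entries[(2, rev_a, rev_b, None)] = StateValues(
            qa, qb, qs, p_a, weight)

    # Stage 1: one card revealed on row A, one face-down card offered.
    for first in CARD_VALUES:
        rev_a = (first,)
        weight = _state_weight(condition, rev_a, ())
        qa, qb, p_a, _ = guess_values(rev_a, (), 0)
        for offered in ("A", "B"):
            acc = 0.0
            for drawn in CARD_VALUES:
                child = table.entries.get(child_key(1, rev_a, (), offered, drawn))
                if child is None:
                    continue
                acc += child.weight * child.q_star
            qs = {offered: acc / weight - ec}
            table.entries[(1, rev_a, (), offered)] = StateValues(
                qa, qb, qs, p_a, weight)

    return table


@lru_cache(maxsize=32)
def _solve_cached(condition: Condition, extra_sample_cost: float) -> QTable:
    return solve(condition, extra_sample_cost)


def solve_cached(condition: Condition, extra_sample_cost: float = 0.0) -> QTable:
    """Memoized ``solve`` (tables are immutable once built)."""
    return _solve_cached(condition, float(extra_sample_cost))


def relative_value_of_guessing(table: QTable, state: TrialState) -> float:
    """Best guess value minus best sample value (positive favors guessing)."""
    sv = table.state_values(state)
    if not sv.q_sample:
        raise IllegalActionError("state has no sample actions")
    return sv.q_guess_max - sv.q_sample_max


def expected_cards_optimal(table: QTable) -> float:
    """Expected number of cards sampled per trial by the greedy optimal policy.

    The expectation runs over the first-card value, the offer location
    (P(AA) = 1/3, P(AB) = 2/3) and all transitions, under the non-tied-board
    measure. Greedy ties between guessing and sampling are broken toward
    guessing; ties between sample rows toward row A.
    """
    memo: dict = {}

    def expected_more(key) -> float:
        if key in memo:
            return memo[key]
        sv = table.entries[key]
        if sv.guess_is_optimal:
            memo[key] = 0.0
            return 0.0
        stage, rev_a, rev_b, _ = key
        if stage == 3:
            memo[key] = 1.0
            return 1.0
        row = sv.best_sample_row
        acc = 0.0
        for drawn in CARD_VALUES:
            if row == "A":
                ck = (stage + 1, tuple(sorted(rev_a + (drawn,))), rev_b, None)
            else:
                ck = (stage + 1, rev_a, tuple(sorted(rev_b + (drawn,))), None)
            child = table.entries.get(ck)
            if child is None:
                continue
            acc += child.weight * expected_more(ck)
        result = 1.0 + acc / sv.weight
        memo[key] = result
        return result

    total_weight = sum(_state_weight(table.condition, (v,), ())
                       for v in CARD_VALUES)
    value = 0.0
    for offered, p_off in (("A", 1 / 3), ("B", 2 / 3)):
        for v in CARD_VALUES:
            key = (1, (v,), (), offered)
            w = table.entries[key].weight
            value += p_off * (w / total_weight) * expected_more(key)
    return value


def replay_optimal(table: QTable, board: Board, offered_row: str):
    """Run the greedy optimal policy on a known non-tied board.

    Returns ``(n_samples, guess_row, points)``. Card reveal order within a
    row follows the board's stored order.
    """
    condition = table.condition
    if board.is_tied(condition):
        raise ValueError("tied boards are excluded by convention")
    shown_a, shown_b = 1, 0  # first card free on row A
    for stage in (1, 2, 3):
        rev_a = tuple(sorted(board.a[:shown_a]))
        rev_b = tuple(sorted(board.b[:shown_b]))
        key = (stage, rev_a, rev_b, offered_row if stage == 1 else None)
        sv = table.entries[key]
        if sv.guess_is_optimal:
            n = shown_a + shown_b - 1
            points = (WIN_POINTS if sv.best_guess_row == board.winner(condition)
                      else LOSS_POINTS) - STAGE_ENTRY_COST[Stage(stage)]
            return n, sv.best_guess_row, points
        row = offered_row if stage == 1 else sv.best_sample_row
        if row == "A":
            shown_a += 1
        else:
            shown_b += 1
    # sampled all three times: terminal, guess the known winner
    return 3, board.winner(condition), TERMINAL_GUESS_VALUE


def qtable_to_frame(table: QTable) -> pd.DataFrame:
    """Flatten a QTable to one row per (state, action) for inspection."""
    rows = []
    for (stage, rev_a, rev_b, offered), sv in sorted(table.entries.items()):
        base = {
            "condition": table.condition.name,
            "stage": stage,
            "revealed_a": "+".join(map(str, rev_a)),
            "revealed_b": "+".join(map(str, rev_b)),
            "offered_row": offered or "",
            "q_star": sv.q_star,
        }
        rows.append({**base, "action": "guess_A", "value": sv.q_guess_a})
        rows.append({**base, "action": "guess_B", "value": sv.q_guess_b})
        for row, val in sorted(sv.q_sample.items()):
            rows.append({**base, "action": f"sample_{row}", "value": val})
    return pd.DataFrame(rows)
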