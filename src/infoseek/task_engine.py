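"""Exact probabilistic model of the 2x2 card game.

Two rows of two cards each, values uniform on 1..10 with replacement. The
first card is revealed for free and its row is, by definition, "row A".
Subjects then pay escalating costs (10/15/20 points) to reveal further cards,
or guess the winning row at any point for +60 (correct) / -50 (incorrect),
net of costs paid.

Tied boards carry no probability mass: every probability in this module is
conditional on the completed four-card board being non-tied (equivalent to
re-dealing tied boards). This convention is what reproduces the game's
published worked-example numbers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from enum import Enum, IntEnum
from functools import lru_cache

__all__ = [
    "Operation",
    "Direction",
    "Condition",
    "CONDITIONS",
    "Stage",
    "ActionKind",
    "ActionSpec",
    "TrialState",
    "TrialOutcome",
    "Board",
    "CARD_VALUES",
    "SAMPLE_COSTS",
    "WIN_POINTS",
    "LOSS_POINTS",
    "InvalidCardError",
    "IllegalActionError",
    "UndefinedWinnerError",
    "row_score",
    "winner",
    "win_probability",
    "legal_actions",
    "apply_action",
    "initial_state",
]

CARD_VALUES = tuple(range(1, 11))

#: Cost of the sample action at each sampling stage.
SAMPLE_COSTS = {1: 10, 2: 15, 3: 20}

WIN_POINTS = 60
LOSS_POINTS = -50


class InvalidCardError(ValueError):
    """A card value outside 1..10 was supplied."""


class IllegalActionError(ValueError):
    """An action was applied in a state where it is not legal."""


class UndefinedWinnerError(ValueError):
    """Winner requested on a fully revealed tied board."""


class Operation(Enum):
    ADD = "add"
    MULTIPLY = "multiply"
    SINGLE = "single"


class Direction(Enum):
    BIG = "big"
    SMALL = "small"


@dataclass(frozen=True)
class Condition:
    """One of the six task conditions (3 operations x 2 directions)."""

    operation: Operation
    direction: Direction

    @property
    def name(self) -> str:
        return f"{self.operation.value}_{self.direction.value}"

    @classmethod
    def from_name(cls, name: str) -> "Condition":
        op, _, direction = name.lower().partition("_")
        return cls(Operation(op), Direction(direction))

    @property
    def pair(self) -> Operation:
        return self.operation

    @property
    def mirror(self) -> "Condition":
        """The matched condition with the opposite direction."""
        other = Direction.SMALL if self.direction is Direction.BIG else Direction.BIG
        return Condition(self.operation, other)

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.name


CONDITIONS = tuple(
    Condition(op, d) for op in Operation for d in Direction
)


class Stage(IntEnum):
    STAGE1 = 1
    STAGE2 = 2
    STAGE3 = 3
    CHOICE = 4
    TERMINAL = 5


#: Total sampling cost already paid on entering each sampling stage.
STAGE_ENTRY_COST = {Stage.STAGE1: 0, Stage.STAGE2: 10, Stage.STAGE3: 25}


class ActionKind(Enum):
    SAMPLE = "sample"
    GUESS = "guess"


@dataclass(frozen=True)
class ActionSpec:
    kind: ActionKind
    target: str  # row identifier, "A" or "B"

    def __post_init__(self) -> None:
        if self.target not in ("A", "B"):
            raise ValueError(f"target must be 'A' or 'B', got {self.target!r}")


def _check_cards(values) -> None:
    for v in values:
        if v not in CARD_VALUES:
            raise InvalidCardError(f"card value {v!r} outside 1..10")


def row_score(condition: Condition, values) -> int:
    """Score of a fully revealed row under the condition's operation.

    For SINGLE conditions the row is represented by its best card in the
    relevant direction (max for BIG, min for SMALL).
    """
    _check_cards(values)
    if len(values) != 2:
        raise ValueError("row_score expects exactly two card values")
    if condition.operation is Operation.ADD:
        return values[0] + values[1]
    if condition.operation is Operation.MULTIPLY:
        return values[0] * values[1]
    if condition.direction is Direction.BIG:
        return max(values)
    return min(values)


def winner(condition: Condition, row_a, row_b) -> str:
    """Winning row of a fully revealed board: 'A', 'B' or 'TIE'."""
    sa = row_score(condition, tuple(row_a))
    sb = row_score(condition, tuple(row_b))
    if sa == sb:
        return "TIE"
    if condition.direction is Direction.BIG:
        return "A" if sa > sb else "B"
    return "A" if sa < sb else "B"


@dataclass(frozen=True)
class Board:
    """A fully dealt board in canonical orientation (row A = first card's row).

    ``a[0]`` is the free first card. Within each row, later entries are
    revealed later when that row is sampled.
    """

    a: tuple
    b: tuple

    def __post_init__(self) -> None:
        _check_cards(self.a)
        _check_cards(self.b)
        if len(self.a) != 2 or len(self.b) != 2:
            raise ValueError("Board requires two cards per row")

    def winner(self, condition: Condition) -> str:
        return winner(condition, self.a, self.b)

    def is_tied(self, condition: Condition) -> bool:
        return self.winner(condition) == "TIE"


@dataclass(frozen=True)
class TrialState:
    """Canonical game state.

    Revealed cards are stored as sorted tuples (cards within a row are
    exchangeable). ``offered_row`` is only meaningful at STAGE1, where a
    single face-down card is purchasable; at later sampling stages every
    incomplete row can be sampled.
    """

    condition: Condition
    stage: Stage
    revealed_a: tuple
    revealed_b: tuple
    offered_row: str | None = None  # "A" or "B" at STAGE1, else None
    total_cost: int = 0

    def __post_init__(self) -> None:
        _check_cards(self.revealed_a)
        _check_cards(self.revealed_b)
        object.__setattr__(self, "revealed_a", tuple(sorted(self.revealed_a)))
        object.__setattr__(self, "revealed_b", tuple(sorted(self.revealed_b)))
        if self.stage in STAGE_ENTRY_COST:
            n = len(self.revealed_a) + len(self.revealed_b)
            if n != int(self.stage):
                raise ValueError(
                    f"{self.stage.name} requires {int(self.stage)} revealed "
                    f"cards, got {n}"
                )
            if self.total_cost != STAGE_ENTRY_COST[self.stage]:
                raise ValueError(
                    f"total_cost {self.total_cost} inconsistent with "
                    f"{self.stage.name}"
                )
        if self.stage is Stage.STAGE1 and self.offered_row not in ("A", "B"):
            raise ValueError("STAGE1 state requires offered_row 'A' or 'B'")

    @property
    def trial_type(self) -> str | None:
        """'AA' or 'AB' once defined (stage >= 1 via the offer)."""
        if self.stage is Stage.STAGE1:
            return "AA" if self.offered_row == "A" else "AB"
        if self.stage is Stage.STAGE2:
            return "AA" if len(self.revealed_a) == 2 else "AB"
        return None  # merged at stage 3 and beyond

    @property
    def n_hidden(self) -> int:
        return 4 - len(self.revealed_a) - len(self.revealed_b)

    def key(self):
        """Canonical hashable key used by the DP solver."""
        return (int(self.stage), self.revealed_a, self.revealed_b,
                self.offered_row)


def initial_state(condition: Condition, first_card: int,
                  offered_row: str) -> TrialState:
    """The STAGE1 state after the free first card is revealed on row A."""
    return TrialState(condition, Stage.STAGE1, (first_card,), (),
                      offered_row=offered_row, total_cost=0)


@lru_cache(maxsize=None)
def _completion_counts(condition: Condition, revealed_a: tuple,
                       revealed_b: tuple):
    """(#A-wins, #B-wins, #ties) over all uniform completions of hidden cards."""
    need_a = 2 - len(revealed_a)
    need_b = 2 - len(revealed_b)
    wins_a = wins_b = ties = 0
    for extra_a in itertools.product(CARD_VALUES, repeat=need_a):
        row_a = revealed_a + extra_a
        for extra_b in itertools.product(CARD_VALUES, repeat=need_b):
            w = winner(condition, row_a, revealed_b + extra_b)
            if w == "A":
                wins_a += 1
            elif w == "B":
                wins_b += 1
            else:
                ties += 1
    return wins_a, wins_b, ties


def win_probability(state: TrialState, guess_row: str) -> float:
    """Probability that ``guess_row`` wins, given the revealed cards.

    Computed by enumerating all equally likely completions of hidden cards
    and taking the fraction of strict wins among non-tied completions.
    """
    if guess_row not in ("A", "B"):
        raise ValueError("guess_row must be 'A' or 'B'")
    wins_a, wins_b, _ = _completion_counts(
        state.condition, state.revealed_a, state.revealed_b)
    total = wins_a + wins_b
    if total == 0:
        raise UndefinedWinnerError("fully revealed tied board has no winner")
    return (wins_a if guess_row == "A" else wins_b) / total


def legal_actions(state: TrialState) -> tuple:
    """Actions available in ``state``: guesses plus purchasable sample rows."""
    if state.stage is Stage.TERMINAL:
        raise IllegalActionError("terminal state has no actions")
    guesses = (ActionSpec(ActionKind.GUESS, "A"),
               ActionSpec(ActionKind.GUESS, "B"))
    if state.stage is Stage.CHOICE:
        return guesses
    if state.stage is Stage.STAGE1:
        samples = (ActionSpec(ActionKind.SAMPLE, state.offered_row),)
    else:
        samples = tuple(
            ActionSpec(ActionKind.SAMPLE, row)
            for row, revealed in (("A", state.revealed_a),
                                  ("B", state.revealed_b))
            if len(revealed) < 2
        )
    return samples + guesses


def apply_action(state: TrialState, action: ActionSpec,
                 drawn: int | None = None, board: Board | None = None):
    """Apply a legal action.

    SAMPLE requires ``drawn`` (the revealed card value) and returns the next
    ``TrialState``. GUESS requires ``board`` (the complete deal, needed to
    resolve the winner) and returns a ``TrialOutcome``.
    """
    if action not in legal_actions(state):
        raise IllegalActionError(f"{action} illegal in stage {state.stage.name}")
    if action.kind is ActionKind.SAMPLE:
        if drawn is None:
            raise ValueError("SAMPLE requires the drawn card value")
        _check_cards((drawn,))
        cost = state.total_cost + SAMPLE_COSTS[int(state.stage)]
        rev_a, rev_b = state.revealed_a, state.revealed_b
        if action.target == "A":
            rev_a = rev_a + (drawn,)
        else:
            rev_b = rev_b + (drawn,)
        return TrialState(state.condition, Stage(int(state.stage) + 1),
                          rev_a, rev_b, offered_row=None, total_cost=cost)
    if board is None:
        raise ValueError("GUESS requires the full board to resolve the winner")
    win_row = board.winner(state.condition)
    if win_row == "TIE":
        raise UndefinedWinnerError("cannot resolve a guess on a tied board")
    correct = action.target == win_row
    points = (WIN_POINTS if correct else LOSS_POINTS) - state.total_cost
    return TrialOutcome(chosen_row=action.target, winning_row=win_row,
                        points=points)


@dataclass(frozen=True)
class TrialOutcome:
    chosen_row: str
    winning_row: str
    points: int

    def __post_init__(self) -> None:
        if not (LOSS_POINTS - 45) <= self.points <= WIN_POINTS:
            raise ValueError(f"points {self.points} out of range")
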