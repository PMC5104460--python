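"""Independent brute-force expectimax oracle for the card game.

Deliberately shares no code with the package's DP solver: scoring, winner
determination and the recursion are all re-implemented from the task rules,
enumerating explicit completion sets (all assignments of hidden cards,
tied boards excluded globally).
"""

import itertools
from functools import lru_cache

CARDS = tuple(range(1, 11))
COSTS = {1: 10, 2: 15, 3: 20}


def board_winner(cond_name: str, a, b) -> str:
    op, direction = cond_name.split("_")
    if op == "add":
        sa, sb = a[0] + a[1], b[0] + b[1]
    elif op == "multiply":
        sa, sb = a[0] * a[1], b[0] * b[1]
    else:  # single
        pick = max if direction == "big" else min
        sa, sb = pick(a), pick(b)
    if sa == sb:
        return "T"
    if direction == "big":
        return "A" if sa > sb else "B"
    return "A" if sa < sb else "B"


def completions(cond_name, rev_a, rev_b):
    """All non-tied full boards consistent with the revealed cards."""
    out = []
    for xa in itertools.product(CARDS, repeat=2 - len(rev_a)):
        a = tuple(rev_a) + xa
        for xb in itertools.product(CARDS, repeat=2 - len(rev_b)):
            b = tuple(rev_b) + xb
            if board_winner(cond_name, a, b) != "T":
                out.append((a, b))
    return out


def guess_values(cond_name, rev_a, rev_b, cost):
    comps = completions(cond_name, rev_a, rev_b)
    n = len(comps)
    na = sum(1 for a, b in comps if board_winner(cond_name, a, b) == "A")
    qa = 60 * na / n - 50 * (n - na) / n - cost
    qb = 60 * (n - na) / n - 50 * na / n - cost
    return qa, qb


@lru_cache(maxsize=None)
def best_value(cond_name, rev_a, rev_b, cost, restrict_row, extra):
    """Optimal expectimax value; restrict_row limits sampling (stage-1 offer)."""
    qa, qb = guess_values(cond_name, rev_a, rev_b, cost)
    best = max(qa, qb)
    n_revealed = len(rev_a) + len(rev_b)
    if n_revealed < 4:
        rows = [restrict_row] if restrict_row else [
            r for r, rev in (("A", rev_a), ("B", rev_b)) if len(rev) < 2]
        for row in rows:
            best = max(best, q_sample(cond_name, rev_a, rev_b, row, cost,
                                      extra))
    return best


def q_sample(cond_name, rev_a, rev_b, row, cost, extra=0.0):
    """Expected best-value after paying to reveal the next card on ``row``."""
    stage = len(rev_a) + len(rev_b)
    next_cost = cost + COSTS[stage]
    comps = completions(cond_name, rev_a, rev_b)
    acc = 0.0
    for drawn in CARDS:
        if row == "A":
            child_a = tuple(sorted(rev_a + (drawn,)))
            child_b = tuple(rev_b)
            weight = sum(1 for a, b in comps if a[len(rev_a)] == drawn)
        else:
            child_a = tuple(rev_a)
            child_b = tuple(sorted(rev_b + (drawn,)))
            weight = sum(1 for a, b in comps if b[len(rev_b)] == drawn)
        if weight == 0:
            continue
        acc += weight * best_value(cond_name, child_a, child_b, next_cost,
                                   None, extra)
    return acc / len(comps) - extra


def win_probability(cond_name, rev_a, rev_b, row) -> float:
    comps = completions(cond_name, rev_a, rev_b)
    wins = sum(1 for a, b in comps if board_winner(cond_name, a, b) == row)
    return wins / len(comps)
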