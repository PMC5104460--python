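"""Synthetic agent populations for the card game and the gamble task.

Agents with known latent parameters play the exact task (uniform 1-10 deals,
re-dealt ties, uniform stage-1 offers, 10/15/20 cost schedule), producing
datasets with the statistical structure every downstream analysis assumes.
Policies: the greedy optimal policy, immediate guessing, and the parametric
softmax model (reduced or full). Parametric agents use the modelled
decisions at stage 1 and stage 2 AB; at stage 2 AA and stage 3 (outside the
modelled scope) they compare the mean effective card values of the rows with
the same beta1/beta2/beta3 machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parametric_model import (
    MEAN_FIRST_CARD,
    ModelParams,
    choice_probabilities,
    effective_card,
    omega,
    stage1_values,
    stage2_values,
)
from .task_engine import (
    CARD_VALUES,
    SAMPLE_COSTS,
    WIN_POINTS,
    LOSS_POINTS,
    Board,
    Condition,
    CONDITIONS,
    Direction,
    Operation,
)

__all__ = [
    "AgentSpec",
    "PopulationSpec",
    "AGE_GROUPS",
    "EDUCATION_LEVELS",
    "DEFAULT_PARAM_MEANS",
    "PARAM_NAMES",
    "simulate_agent",
    "generate_population",
    "simulate_gamble_population",
    "generate_linked_populations",
]

POLICIES = ("OPTIMAL", "PARAMETRIC_REDUCED", "PARAMETRIC_FULL",
            "ALWAYS_GUESS")

#: Minimum age category is 18-25 (minors are excluded by construction).
AGE_GROUPS = ("18-25", "26-35", "36-45", "46-59", "60+")
EDUCATION_LEVELS = ("None", "GCSE", "ALev", "Degree")

TRIALS_PER_BLOCK = 11
BLOCKS_PER_GAMEPLAY = 2

PARAM_NAMES = ("beta1", "beta2", "beta3", "beta4", "beta5", "beta6",
               "log_tau")

#: Population-mean defaults giving U-shaped, broadly optimal-looking behavior.
DEFAULT_PARAM_MEANS = {"beta1": 1.0, "beta2": 2.0, "beta3": 4.0,
                       "beta4": 0.0, "beta5": 0.0, "beta6": 0.0,
                       "log_tau": 0.0}


@dataclass(frozen=True)
class AgentSpec:
    uid: int
    policy: str = "OPTIMAL"
    params: ModelParams | None = None
    age_group: str = AGE_GROUPS[0]
    education: str = EDUCATION_LEVELS[1]

    def __post_init__(self) -> None:
        if self.policy not in POLICIES:
            raise ValueError(f"unknown policy {self.policy!r}")
        if self.policy.startswith("PARAMETRIC") and self.params is None:
            raise ValueError("parametric policies need ModelParams")
        if self.age_group not in AGE_GROUPS:
            raise ValueError(f"unknown age group {self.age_group!r}")


@dataclass
class PopulationSpec:
    """Hyper-distribution and design of a synthetic population.

    ``mean``/``cov`` parameterize a multivariate normal over
    (beta1, beta2, beta3, beta4, beta5, beta6, log_tau). ``conditions``
    fixes the two conditions of every gameplay; None draws a random ordered
    pair of distinct conditions per gameplay, and an Operation restricts the
    draw to that pair's two directions.
    """

    n_subjects: int
    policy: str = "PARAMETRIC_REDUCED"
    mean: dict = field(default_factory=lambda: dict(DEFAULT_PARAM_MEANS))
    cov: np.ndarray | None = None
    conditions: tuple | Operation | None = None
    n_gameplays: int = 1
    seed: int | None = None

    def mean_vector(self) -> np.ndarray:
        m = dict(DEFAULT_PARAM_MEANS, **self.mean)
        return np.array([m[k] for k in PARAM_NAMES])

    def cov_matrix(self) -> np.ndarray:
        if self.cov is None:
            return np.zeros((len(PARAM_NAMES), len(PARAM_NAMES)))
        cov = np.asarray(self.cov, dtype=float)
        if cov.shape != (len(PARAM_NAMES), len(PARAM_NAMES)):
            raise ValueError(f"cov must be {len(PARAM_NAMES)}x"
                             f"{len(PARAM_NAMES)}")
        if not np.allclose(cov, cov.T):
            raise ValueError("covariance must be symmetric")
        if np.linalg.eigvalsh(cov).min() < -1e-10:
            raise ValueError("covariance must be positive semi-definite")
        return cov


def _deal_board(condition: Condition, rng) -> Board:
    """Uniform 1-10 deal, re-dealt until non-tied (tie-exclusion convention)."""
    while True:
        cards = rng.integers(1, 11, size=4)
        board = Board((int(cards[0]), int(cards[1])),
                      (int(cards[2]), int(cards[3])))
        if not board.is_tied(condition):
            return board


def _parametric_stage_probs(policy_params: ModelParams, condition: Condition,
                            board: Board, stage: int, shown_a: int,
                            shown_b: int, offered_row: str):
    """(options, probabilities) for a parametric agent at any stage."""
    d = condition.direction
    p = policy_params
    if stage == 1:
        tt = "AA" if offered_row == "A" else "AB"
        vals = stage1_values(effective_card(board.a[0], d), tt, p)
        sample_key = "sampleA" if tt == "AA" else "sampleB"
        probs = choice_probabilities(vals, p.tau)
        return (("A", "B", sample_key), probs)
    if stage == 2 and shown_a == 1:  # AB layout: the modelled 4-way decision
        vals = stage2_values(effective_card(board.a[0], d),
                             effective_card(board.b[0], d), p)
        return (("A", "B", "sampleA", "sampleB"),
                choice_probabilities(vals, p.tau))
    # outside the modelled scope: compare mean effective values of the rows
    eff_a = np.mean([effective_card(v, d) for v in board.a[:shown_a]])
    eff_b = (np.mean([effective_card(v, d) for v in board.b[:shown_b]])
             if shown_b else MEAN_FIRST_CARD)
    v_a = p.beta1 * (eff_a - eff_b)
    v_b = -v_a
    v_s = p.beta2 + p.beta3 * omega(v_a, v_b)
    sample_key = "sampleA" if shown_a < 2 else "sampleB"
    vals = {"A": v_a, "B": v_b, sample_key: v_s}
    return (("A", "B", sample_key), choice_probabilities(vals, p.tau))


def _play_trial(agent: AgentSpec, condition: Condition, rng,
                qtable=None) -> dict:
    from .optimal_dp import solve_cached

    board = _deal_board(condition, rng)
    # physical row of the first card is cosmetic; canonical row A = its row
    first_row = int(rng.integers(0, 2))
    offered_row = "A" if rng.random() < (1 / 3) else "B"

    if agent.policy == "OPTIMAL" and qtable is None:
        qtable = solve_cached(condition)

    shown_a, shown_b = 1, 0
    samples = []  # (row, value)
    chosen = None
    for stage in (1, 2, 3):
        if agent.policy == "ALWAYS_GUESS":
            p_a_win = _p_win(condition, board, shown_a, shown_b, "A")
            chosen = "A" if p_a_win >= 0.5 else "B"
            break
        if agent.policy == "OPTIMAL":
            rev_a = tuple(sorted(board.a[:shown_a]))
            rev_b = tuple(sorted(board.b[:shown_b]))
            key = (stage, rev_a, rev_b, offered_row if stage == 1 else None)
            sv = qtable.entries[key]
            if sv.guess_is_optimal:
                chosen = sv.best_guess_row
                break
            row = offered_row if stage == 1 else sv.best_sample_row
        else:
            options, probs = _parametric_stage_probs(
                agent.params, condition, board, stage, shown_a, shown_b,
                offered_row)
            pick = rng.choice(len(options),
                              p=[probs[o] for o in options])
            action = options[pick]
            if action in ("A", "B"):
                chosen = action
                break
            row = "A" if action == "sampleA" else "B"
        if row == "A":
            samples.append(("A", board.a[shown_a]))
            shown_a += 1
        else:
            samples.append(("B", board.b[shown_b]))
            shown_b += 1
    else:
        # sampled three times: all cards known, guess the winner
        chosen = board.winner(condition)

    guess_stage = len(samples) + 1
    total_cost = sum(SAMPLE_COSTS[k + 1] for k in range(len(samples)))
    win_row = board.winner(condition)
    points = (WIN_POINTS if chosen == win_row else LOSS_POINTS) - total_cost
    rec = {
        "uid": agent.uid, "condition": condition.name,
        "trial_type": "AA" if offered_row == "A" else "AB",
        "a1": board.a[0], "a2": board.a[1],
        "b1": board.b[0], "b2": board.b[1],
        "first_row": first_row, "offered_row": offered_row,
        "n_samples": len(samples), "guess_stage": guess_stage,
        "chosen_row": chosen, "winning_row": win_row,
        "total_cost": total_cost, "points": points,
    }
    for k in range(3):
        rec[f"s{k + 1}_row"] = samples[k][0] if k < len(samples) else None
        rec[f"s{k + 1}_value"] = samples[k][1] if k < len(samples) else None
    return rec


def _p_win(condition, board, shown_a, shown_b, row):
    from .task_engine import TrialState, Stage, win_probability

    stage = shown_a + shown_b
    state = TrialState(condition, Stage(stage),
                       tuple(sorted(board.a[:shown_a])),
                       tuple(sorted(board.b[:shown_b])),
                       offered_row="A" if stage == 1 else None,
                       total_cost={1: 0, 2: 10, 3: 25}[stage])
    return win_probability(state, row)


def _gameplay_conditions(spec_conditions, rng):
    if isinstance(spec_conditions, Operation):
        pair = [Condition(spec_conditions, d) for d in Direction]
        order = rng.permutation(2)
        return [pair[order[0]], pair[order[1]]]
    if spec_conditions is not None:
        return [c if isinstance(c, Condition) else Condition.from_name(c)
                for c in spec_conditions]
    idx = rng.choice(len(CONDITIONS), size=2, replace=False)
    return [CONDITIONS[idx[0]], CONDITIONS[idx[1]]]


def simulate_agent(agent: AgentSpec, n_gameplays: int, rng,
                   conditions=None) -> list:
    """Simulate complete gameplays (2 blocks x 11 trials) for one agent."""
    records = []
    for gp in range(1, n_gameplays + 1):
        conds = _gameplay_conditions(conditions, rng)
        for block, condition in enumerate(conds, start=1):
            for trial in range(1, TRIALS_PER_BLOCK + 1):
                rec = _play_trial(agent, condition, rng)
                rec.update(gameplay=gp, block=block, trial=trial)
                records.append(rec)
    return records


def generate_population(spec: PopulationSpec):
    """Draw a population from the hyper-distribution and simulate it.

    Returns a ``GameplayDataset`` whose demographics table also carries the
    true latent parameters (column-prefixed ``true_``) for recovery tests.
    """
    from .cli_io.schema import GameplayDataset

    rng = np.random.default_rng(spec.seed)
    mean = spec.mean_vector()
    cov = spec.cov_matrix()
    draws = rng.multivariate_normal(mean, cov, size=spec.n_subjects)

    records, demo = [], []
    for k in range(spec.n_subjects):
        uid = k + 1
        theta = dict(zip(PARAM_NAMES, draws[k]))
        params = ModelParams(
            beta1=theta["beta1"], beta2=theta["beta2"], beta3=theta["beta3"],
            tau=float(np.exp(theta["log_tau"])),
            beta4=theta["beta4"] if spec.policy == "PARAMETRIC_FULL" else 0.0,
            beta5=theta["beta5"] if spec.policy == "PARAMETRIC_FULL" else 0.0,
            beta6=theta["beta6"] if spec.policy == "PARAMETRIC_FULL" else 0.0,
        ) if spec.policy.startswith("PARAMETRIC") else None
        agent = AgentSpec(
            uid=uid, policy=spec.policy, params=params,
            age_group=AGE_GROUPS[rng.integers(len(AGE_GROUPS))],
            education=EDUCATION_LEVELS[rng.integers(len(EDUCATION_LEVELS))])
        records.extend(simulate_agent(agent, spec.n_gameplays, rng,
                                      conditions=spec.conditions))
        demo.append({"uid": uid, "age_group": agent.age_group,
                     "education": agent.education,
                     **{f"true_{k2}": v for k2, v in theta.items()}})
    trials = pd.DataFrame(records)
    return GameplayDataset(trials=trials, demographics=pd.DataFrame(demo))


# ---------------------------------------------------------------------------
# gamble task


def _gamble_menu(rng, n_per_type: int = 10) -> list:
    """30-trial menu (10 per type); amount ranges span both clearly-better
    and clearly-worse gambles so the value-independent biases are
    identifiable."""
    menu = []
    for _ in range(n_per_type):
        c = int(rng.integers(15, 61))
        menu.append(("GAIN", c, int(round(c * rng.uniform(1.2, 3.2))), 0))
    for _ in range(n_per_type):
        g = int(rng.integers(20, 81))
        menu.append(("MIXED", 0, g, -int(rng.integers(10, 71))))
    for _ in range(n_per_type):
        c = int(rng.integers(15, 61))
        menu.append(("LOSS", -c, -int(round(c * rng.uniform(1.2, 3.2))), 0))
    rng.shuffle(menu)
    return menu


def simulate_gamble_population(n_subjects: int, rng,
                               params: pd.DataFrame | None = None,
                               mean=(0.3, 0.0, 0.0), sd=(0.1, 0.25, 0.25),
                               n_plays: int = 1) -> pd.DataFrame:
    """Simulate 30-choice gamble plays; choices drawn from ``p_gamble``.

    Per-subject (mu, beta_gain, beta_loss) are either supplied in ``params``
    (columns uid/mu/beta_gain/beta_loss) or drawn independently normal with
    the given means/sds (mu floored at 0.05, betas clipped inside (-1, 1)).
    """
    from .pavlovian_gamble import GambleParams, GambleTrial, p_gamble

    if params is None:
        mu = np.maximum(rng.normal(mean[0], sd[0], n_subjects), 0.05)
        bg = np.clip(rng.normal(mean[1], sd[1], n_subjects), -0.95, 0.95)
        bl = np.clip(rng.normal(mean[2], sd[2], n_subjects), -0.95, 0.95)
        params = pd.DataFrame({"uid": np.arange(1, n_subjects + 1),
                               "mu": mu, "beta_gain": bg, "beta_loss": bl})
    rows = []
    for rec in params.itertuples():
        gp = GambleParams(mu=float(rec.mu), beta_gain=float(rec.beta_gain),
                          beta_loss=float(rec.beta_loss))
        for play in range(1, n_plays + 1):
            for tt, certain, o1, o2 in _gamble_menu(rng):
                trial = GambleTrial(tt, certain, o1, o2)
                chose = bool(rng.random() < p_gamble(trial, gp))
                rows.append({"uid": rec.uid, "play": play, "trial_type": tt,
                             "certain": certain, "outcome1": o1,
                             "outcome2": o2, "chose_gamble": chose})
    return pd.DataFrame(rows)


def generate_linked_populations(n_subjects: int, seed: int | None = None,
                                link: float = 1.0, pair: Operation =
                                Operation.MULTIPLY, n_gameplays: int = 1):
    """Joint card-game + gamble populations with a shared approach factor.

    A latent standard-normal factor u drives both the gamble approach-avoid
    index (beta_gain - beta_loss) and the card-game bias parameters
    beta4/beta5/beta6 with strength ``link`` (0 = no linkage, the null).
    Returns (gameplay dataset, gamble dataframe, true subject table).
    """
    from .cli_io.schema import GameplayDataset

    rng = np.random.default_rng(seed)
    u = rng.standard_normal(n_subjects)
    bg = np.clip(0.15 + 0.3 * link * u + rng.normal(0, 0.05, n_subjects),
                 -0.95, 0.95)
    bl = np.clip(0.15 - 0.3 * link * u + rng.normal(0, 0.05, n_subjects),
                 -0.95, 0.95)
    b4 = 0.08 + 0.06 * link * u + rng.normal(0, 0.01, n_subjects)
    b5 = 0.08 + 0.06 * link * u + rng.normal(0, 0.01, n_subjects)
    b6 = 0.30 + 0.25 * link * u + rng.normal(0, 0.02, n_subjects)

    records, demo = [], []
    for k in range(n_subjects):
        uid = k + 1
        params = ModelParams(beta1=1.0, beta2=2.0, beta3=4.0, tau=1.0,
                             beta4=float(b4[k]), beta5=float(b5[k]),
                             beta6=float(b6[k]))
        agent = AgentSpec(uid=uid, policy="PARAMETRIC_FULL", params=params)
        records.extend(simulate_agent(agent, n_gameplays, rng,
                                      conditions=pair))
        demo.append({"uid": uid, "age_group": AGE_GROUPS[0],
                     "education": EDUCATION_LEVELS[1],
                     "true_u": u[k], "true_beta4": b4[k],
                     "true_beta5": b5[k], "true_beta6": b6[k],
                     "true_beta_gain": bg[k], "true_beta_loss": bl[k]})
    dataset = GameplayDataset(trials=pd.DataFrame(records),
                              demographics=pd.DataFrame(demo))
    gamble_params = pd.DataFrame({"uid": np.arange(1, n_subjects + 1),
                                  "mu": np.full(n_subjects, 0.3),
                                  "beta_gain": bg, "beta_loss": bl})
    gambles = simulate_gamble_population(n_subjects, rng,
                                         params=gamble_params)
    return dataset, gambles, pd.DataFrame(demo)
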