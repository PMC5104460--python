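"""Approach-bias summary statistics and sampling-depth trait measures.

Three statistics compare behavior across matched framings of the task:

* positive evidence approach - signed BIG-minus-SMALL difference in stage-1
  guess probabilities, summed over card values;
* rejecting unsampled options - AB-minus-AA difference in stage-1 row-A
  choice probabilities, summed over card values;
* sampling the favorite - BIG-minus-SMALL difference in the relative
  probability of sampling row A at stage 2, summed over strong
  (|i-j| >= 4) or weak (1 <= |i-j| <= 3) evidence bands.

All three are exactly 0 for any policy that is identical across the matched
framings. Confidence intervals come from a percentile bootstrap that
resamples gameplays with replacement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task_engine import CARD_VALUES, Condition, Direction, Operation

__all__ = [
    "AggregateTables",
    "BiasResult",
    "aggregate_tables",
    "policy_aggregate_tables",
    "positive_evidence_approach",
    "rejecting_unsampled",
    "sampling_favorite",
    "bootstrap_ci",
    "sampling_depth",
    "MissingCellError",
]

S1_COUNTS = ("n", "n_guess", "n_choose_a", "n_choose_b", "n_sample")
S2_COUNTS = ("n", "n_guess", "n_choose_a", "n_choose_b",
             "n_sample_a", "n_sample_b")


class MissingCellError(ValueError):
    """A statistic touched a cell with no observations."""


@dataclass
class AggregateTables:
    """Per-cell counts of stage-1 and stage-2 decisions.

    ``stage1[cond]`` has shape (2 trial types, 10 cards, 5 counts) with trial
    type order (AA, AB); ``stage2[cond]`` has shape (10, 10, 6) indexed by
    (row-A card i, row-B card j). Cells with zero trials are missing, not
    zero probability.
    """

    conditions: tuple
    stage1: dict
    stage2: dict

    _TT = ("AA", "AB")

    def _cond_key(self, condition) -> str:
        return condition.name if isinstance(condition, Condition) else condition

    def stage1_cell(self, condition, trial_type: str, card: int):
        arr = self.stage1.get(self._cond_key(condition))
        if arr is None:
            return None
        row = arr[self._TT.index(trial_type), card - 1]
        return dict(zip(S1_COUNTS, row))

    def stage2_cell(self, condition, i: int, j: int):
        arr = self.stage2.get(self._cond_key(condition))
        if arr is None:
            return None
        return dict(zip(S2_COUNTS, arr[i - 1, j - 1]))

    def p_guess(self, condition, trial_type: str) -> np.ndarray:
        """P(guess at stage 1) per card value; NaN for empty cells."""
        arr = self.stage1[self._cond_key(condition)][self._TT.index(trial_type)]
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(arr[:, 0] > 0, arr[:, 1] / arr[:, 0], np.nan)

    def p_choose_a_stage1(self, condition, trial_type: str) -> np.ndarray:
        """P(choice = A | guessed at stage 1) per card value."""
        arr = self.stage1[self._cond_key(condition)][self._TT.index(trial_type)]
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(arr[:, 1] > 0, arr[:, 2] / arr[:, 1], np.nan)

    def p_sample_a(self, condition) -> np.ndarray:
        """Relative P(sample A) over (i, j) cells among stage-2 AB samplers."""
        arr = self.stage2[self._cond_key(condition)]
        denom = arr[:, :, 4] + arr[:, :, 5]
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, arr[:, :, 4] / denom, np.nan)

    def to_frames(self):
        """Long-format DataFrames (stage1, stage2) for inspection/export."""
        s1 = []
        for cond, arr in self.stage1.items():
            for t, tt in enumerate(self._TT):
                for c in CARD_VALUES:
                    s1.append({"condition": cond, "trial_type": tt, "card": c,
                               **dict(zip(S1_COUNTS, arr[t, c - 1]))})
        s2 = []
        for cond, arr in self.stage2.items():
            for i in CARD_VALUES:
                for j in CARD_VALUES:
                    s2.append({"condition": cond, "i": i, "j": j,
                               **dict(zip(S2_COUNTS, arr[i - 1, j - 1]))})
        return pd.DataFrame(s1), pd.DataFrame(s2)


def _stage1_count_cols(df: pd.DataFrame) -> np.ndarray:
    """(n_trials, 5) count indicators for stage-1 cells."""
    guessed = (df["guess_stage"] == 1).to_numpy()
    chose_a = guessed & (df["chosen_row"] == "A").to_numpy()
    chose_b = guessed & (df["chosen_row"] == "B").to_numpy()
    return np.column_stack([
        np.ones(len(df)), guessed, chose_a, chose_b, ~guessed,
    ]).astype(float)


def _stage2_count_cols(df: pd.DataFrame) -> np.ndarray:
    guessed = (df["guess_stage"] == 2).to_numpy()
    chose_a = guessed & (df["chosen_row"] == "A").to_numpy()
    chose_b = guessed & (df["chosen_row"] == "B").to_numpy()
    sampled = (df["n_samples"] >= 2).to_numpy()
    samp_a = sampled & (df["s2_row"] == "A").to_numpy()
    samp_b = sampled & (df["s2_row"] == "B").to_numpy()
    return np.column_stack([
        np.ones(len(df)), guessed, chose_a, chose_b, samp_a, samp_b,
    ]).astype(float)


class _CellCounter:
    """Per-gameplay cell-count matrices enabling O(1)-per-replicate bootstrap.

    Stage-1 cells: condition x trial type x card; stage-2 cells: condition x
    (i, j) over AB trials that reached stage 2. Aggregation over any weighting
    of gameplays is a single matrix product.
    """

    def __init__(self, dataset, conditions):
        trials = dataset.trials
        self.conditions = tuple(conditions)
        cond_names = [c.name for c in self.conditions]
        df = trials[trials["condition"].isin(cond_names)]
        keys = pd.MultiIndex.from_frame(trials[["uid", "gameplay"]])
        self.gameplays = keys.unique()
        gp_codes = pd.MultiIndex.from_frame(df[["uid", "gameplay"]])
        self.n_gameplays = len(self.gameplays)
        g = self.gameplays.get_indexer(gp_codes)

        n_cond = len(cond_names)
        cond_code = df["condition"].map(
            {c: k for k, c in enumerate(cond_names)}).to_numpy()
        tt_code = (df["trial_type"] == "AB").to_numpy().astype(int)
        card_code = df["a1"].to_numpy() - 1

        # stage 1: every trial contributes
        c1 = (cond_code * 2 + tt_code) * 10 + card_code
        self.s1_shape = (n_cond, 2, 10, len(S1_COUNTS))
        n_cells1 = n_cond * 20
        cols1 = _stage1_count_cols(df)
        self.M1 = np.zeros((self.n_gameplays, n_cells1 * len(S1_COUNTS)))
        flat = c1 * len(S1_COUNTS)
        for k in range(len(S1_COUNTS)):
            np.add.at(self.M1, (g, flat + k), cols1[:, k])

        # stage 2: AB trials that reached stage 2
        mask2 = (tt_code == 1) & (df["n_samples"] >= 1).to_numpy()
        df2 = df[mask2]
        g2 = g[mask2]
        j_code = df2["s1_value"].to_numpy(dtype=float).astype(int) - 1
        c2 = (cond_code[mask2] * 100 + card_code[mask2] * 10 + j_code)
        self.s2_shape = (n_cond, 10, 10, len(S2_COUNTS))
        n_cells2 = n_cond * 100
        cols2 = _stage2_count_cols(df2)
        self.M2 = np.zeros((self.n_gameplays, n_cells2 * len(S2_COUNTS)))
        flat2 = c2 * len(S2_COUNTS)
        for k in range(len(S2_COUNTS)):
            np.add.at(self.M2, (g2, flat2 + k), cols2[:, k])

    def tables(self, weights: np.ndarray | None = None) -> AggregateTables:
        if weights is None:
            s1 = self.M1.sum(axis=0)
            s2 = self.M2.sum(axis=0)
        else:
            s1 = weights @ self.M1
            s2 = weights @ self.M2
        s1 = s1.reshape(self.s1_shape)
        s2 = s2.reshape(self.s2_shape)
        return AggregateTables(
            conditions=self.conditions,
            stage1={c.name: s1[k] for k, c in enumerate(self.conditions)},
            stage2={c.name: s2[k] for k, c in enumerate(self.conditions)},
        )


def aggregate_tables(dataset, conditions, per_subject: bool = False,
                     validate: bool = False) -> AggregateTables:
    """Frequency tables per cell, pooled over trials.

    Datasets are validated at the I/O boundary (``read_dataset``); pass
    ``validate=True`` to re-check here. With ``per_subject=True``, cell
    counts are replaced by sums of per-subject proportions (denominator =
    number of contributing subjects), so every ratio the accessors report is
    a mean over subjects of joint proportions rather than a pooled
    frequency.
    """
    if validate:
        from .cli_io.schema import validate_trials

        errors = validate_trials(dataset.trials)
        if errors:
            raise ValueError(
                f"{len(errors)} invalid rows, first: {errors[0]}")
    conditions = [c if isinstance(c, Condition) else Condition.from_name(c)
                  for c in conditions]
    if not per_subject:
        return _CellCounter(dataset, conditions).tables()

    stage1 = {c.name: np.zeros((2, 10, len(S1_COUNTS))) for c in conditions}
    stage2 = {c.name: np.zeros((10, 10, len(S2_COUNTS))) for c in conditions}
    for _, sub in dataset.trials.groupby("uid"):
        t = _CellCounter(_TrialsOnly(sub), conditions).tables()
        for c in conditions:
            arr = t.stage1[c.name]
            with np.errstate(invalid="ignore", divide="ignore"):
                props = arr / arr[:, :, :1]
            occupied = arr[:, :, 0] > 0
            props[:, :, 0] = 1.0
            stage1[c.name][occupied] += props[occupied]
            arr2 = t.stage2[c.name]
            with np.errstate(invalid="ignore", divide="ignore"):
                props2 = arr2 / arr2[:, :, :1]
            occupied2 = arr2[:, :, 0] > 0
            props2[:, :, 0] = 1.0
            stage2[c.name][occupied2] += props2[occupied2]
    return AggregateTables(tuple(conditions), stage1, stage2)


class _TrialsOnly:
    def __init__(self, trials):
        self.trials = trials


def policy_aggregate_tables(qtables: dict) -> AggregateTables:
    """Choice tables implied by the greedy optimal policy of solved QTables.

    Cells hold policy probabilities (unit mass per cell): stage-1 guess/
    choose indicators per (trial type, card) and stage-2 AB relative
    sampling preferences per (i, j), with exact ties split 0.5/0.5. Feeding
    these into the bias statistics yields the normative-model values.
    """
    conditions = []
    stage1, stage2 = {}, {}
    for cond, table in qtables.items():
        cond = cond if isinstance(cond, Condition) else Condition.from_name(cond)
        conditions.append(cond)
        s1 = np.zeros((2, 10, len(S1_COUNTS)))
        for t, tt in enumerate(("AA", "AB")):
            offered = "A" if tt == "AA" else "B"
            for card in CARD_VALUES:
                sv = table.entries[(1, (card,), (), offered)]
                guess = 1.0 if sv.guess_is_optimal else 0.0
                if sv.q_guess_a == sv.q_guess_b:
                    choose_a = 0.5
                else:
                    choose_a = 1.0 if sv.q_guess_a > sv.q_guess_b else 0.0
                s1[t, card - 1] = [1.0, guess, guess * choose_a,
                                   guess * (1 - choose_a), 1 - guess]
        s2 = np.zeros((10, 10, len(S2_COUNTS)))
        for i in CARD_VALUES:
            for j in CARD_VALUES:
                sv = table.entries[(2, (i,), (j,), None)]
                guess = 1.0 if sv.guess_is_optimal else 0.0
                if sv.q_guess_a == sv.q_guess_b:
                    choose_a = 0.5
                else:
                    choose_a = 1.0 if sv.q_guess_a > sv.q_guess_b else 0.0
                qa, qb = sv.q_sample["A"], sv.q_sample["B"]
                samp_a = 0.5 if qa == qb else (1.0 if qa > qb else 0.0)
                s2[i - 1, j - 1] = [1.0, guess, guess * choose_a,
                                    guess * (1 - choose_a), samp_a,
                                    1 - samp_a]
        stage1[cond.name] = s1
        stage2[cond.name] = s2
    return AggregateTables(tuple(conditions), stage1, stage2)


@dataclass
class BiasResult:
    name: str
    point: float
    level: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    n_gameplays: int | None = None
    n_boot: int | None = None
    cells_used: int | None = None

    def __float__(self) -> float:
        return float(self.point)


def _handle_missing(values: np.ndarray, what: str, on_missing: str):
    bad = np.isnan(values)
    if not bad.any():
        return values
    if on_missing == "raise":
        raise MissingCellError(
            f"{what}: {int(bad.sum())} empty cell(s); pass "
            "on_missing='skip' to exclude them")
    warnings.warn(f"{what}: excluding {int(bad.sum())} empty cell(s)")
    return values


def positive_evidence_approach(tables: AggregateTables, pair: Operation,
                               trial_type: str,
                               on_missing: str = "raise") -> BiasResult:
    """Sum_{i>=6}(pGuess_big - pGuess_small) + sum_{i<=5}(small - big)."""
    big = tables.p_guess(Condition(pair, Direction.BIG), trial_type)
    small = tables.p_guess(Condition(pair, Direction.SMALL), trial_type)
    diff = _handle_missing(big - small, "positive_evidence_approach",
                           on_missing)
    sign = np.where(np.arange(1, 11) >= 6, 1.0, -1.0)
    used = ~np.isnan(diff)
    value = float(np.nansum(sign * diff))
    return BiasResult("positive_evidence_approach", value,
                      cells_used=int(used.sum()))


def rejecting_unsampled(tables: AggregateTables, condition: Condition,
                        on_missing: str = "raise") -> BiasResult:
    """Sum_i [p(Choice=A)_{i,AB} - p(Choice=A)_{i,AA}] at stage-1 guesses."""
    p_ab = tables.p_choose_a_stage1(condition, "AB")
    p_aa = tables.p_choose_a_stage1(condition, "AA")
    diff = _handle_missing(p_ab - p_aa, "rejecting_unsampled", on_missing)
    used = ~np.isnan(diff)
    return BiasResult("rejecting_unsampled", float(np.nansum(diff)),
                      cells_used=int(used.sum()))


def _band_masks(band: str):
    i = np.arange(1, 11)[:, None]
    j = np.arange(1, 11)[None, :]
    if band == "STRONG":
        upper = i - j >= 4  # row A clearly higher
        lower = j - i >= 4
    elif band == "WEAK":
        upper = (i - j >= 1) & (i - j <= 3)
        lower = (j - i >= 1) & (j - i <= 3)
    else:
        raise ValueError("band must be 'STRONG' or 'WEAK'")
    return upper, lower


def sampling_favorite(tables: AggregateTables, pair: Operation, band: str,
                      on_missing: str = "raise") -> BiasResult:
    """BIG-minus-SMALL difference in P(Sample=A), summed over evidence bands.

    The upper band (row A favored) enters positively, the mirrored band
    negatively, per the published strong/weak-evidence formulas.
    """
    p_big = tables.p_sample_a(Condition(pair, Direction.BIG))
    p_small = tables.p_sample_a(Condition(pair, Direction.SMALL))
    diff = p_big - p_small
    upper, lower = _band_masks(band)
    sel = diff[upper | lower]
    _handle_missing(sel, f"sampling_favorite[{band}]", on_missing)
    value = float(np.nansum(diff[upper]) - np.nansum(diff[lower]))
    used = int((~np.isnan(sel)).sum())
    return BiasResult(f"sampling_favorite_{band.lower()}", value,
                      cells_used=used)


def bootstrap_ci(dataset, statistic_fn, conditions, n_boot: int = 1000,
                 sample_size: int = 10000, level: float = 0.95,
                 seed: int | None = None, name: str = "") -> BiasResult:
    """Percentile bootstrap CI, resampling gameplays with replacement.

    ``statistic_fn`` maps an AggregateTables to a float. The point estimate
    is computed on the full dataset; each replicate draws ``sample_size``
    gameplays with replacement (implemented as multinomial weights).
    """
    conditions = [c if isinstance(c, Condition) else Condition.from_name(c)
                  for c in conditions]
    counter = _CellCounter(dataset, conditions)
    point = float(statistic_fn(counter.tables()))
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    p = np.full(counter.n_gameplays, 1.0 / counter.n_gameplays)
    for b in range(n_boot):
        w = rng.multinomial(sample_size, p).astype(float)
        reps[b] = float(statistic_fn(counter.tables(w)))
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(reps, [alpha, 1.0 - alpha])
    return BiasResult(name or getattr(statistic_fn, "__name__", "statistic"),
                      point, level=level, ci_low=float(lo), ci_high=float(hi),
                      n_gameplays=counter.n_gameplays, n_boot=n_boot)


def sampling_depth(dataset, qtables: dict, method: str = "replay"):
    """Per-gameplay mean cards sampled relative to the optimal policy.

    ``method='replay'`` replays each trial's board and offer through the
    greedy optimal policy; ``method='expectation'`` subtracts the
    per-condition expected optimal sample count instead. Returns
    ``(depth_frame, retest_r)`` where retest_r is the Pearson correlation of
    gameplay-1 and gameplay-2 means (NaN when fewer than two subjects
    qualify).
    """
    from .optimal_dp import expected_cards_optimal, replay_optimal
    from .task_engine import Board

    qtables = {k.name if isinstance(k, Condition) else k: v
               for k, v in qtables.items()}
    trials = dataset.trials
    missing = set(trials["condition"].unique()) - set(qtables)
    if missing:
        raise ValueError(f"no solved QTable for conditions: {sorted(missing)}")
    if method == "expectation":
        expect = {c: expected_cards_optimal(t) for c, t in qtables.items()}
        rel = (trials["n_samples"].to_numpy(float)
               - trials["condition"].map(expect).to_numpy(float))
    elif method == "replay":
        rel = np.empty(len(trials))
        for idx, row in enumerate(trials.itertuples()):
            board = Board((row.a1, row.a2), (row.b1, row.b2))
            n_opt, _, _ = replay_optimal(qtables[row.condition], board,
                                         row.offered_row)
            rel[idx] = row.n_samples - n_opt
        rel = np.asarray(rel)
    else:
        raise ValueError("method must be 'replay' or 'expectation'")
    depth = (pd.DataFrame({"uid": trials["uid"].to_numpy(),
                           "gameplay": trials["gameplay"].to_numpy(),
                           "rel_depth": rel})
             .groupby(["uid", "gameplay"], as_index=False)["rel_depth"]
             .mean())
    wide = depth.pivot(index="uid", columns="gameplay", values="rel_depth")
    retest_r = np.nan
    if {1, 2} <= set(wide.columns):
        both = wide[[1, 2]].dropna()
        if len(both) >= 2 and both.std().min() > 0:
            retest_r = float(np.corrcoef(both[1], both[2])[0, 1])
    return depth, retest_r
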