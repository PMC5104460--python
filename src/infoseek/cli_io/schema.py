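"""Canonical gameplay dataset schema, readers/writers and validation.

One row per trial, UTF-8 delimited text with a header. Sample events are
flattened into nullable columns (s1_row/s1_value, ...) for portability. Row
"A" is always the row of the first revealed card; the physical screen row is
recorded in ``first_row`` but plays no analytic role. All four board values
are stored (they are revealed to the subject at the end of every trial), so
optimal-policy replays are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ..task_engine import Board, Condition, CONDITIONS

__all__ = ["GameplayDataset", "TRIAL_COLUMNS", "read_dataset",
           "write_dataset", "validate_trials", "SchemaError"]

TRIAL_COLUMNS = [
    "uid", "gameplay", "block", "trial", "condition", "trial_type",
    "a1", "a2", "b1", "b2", "first_row", "offered_row", "n_samples",
    "s1_row", "s1_value", "s2_row", "s2_value", "s3_row", "s3_value",
    "guess_stage", "chosen_row", "winning_row", "total_cost", "points",
]

_NULLABLE_INT = ("s1_value", "s2_value", "s3_value")
_COST_AT_GUESS = {1: 0, 2: 10, 3: 25, 4: 45}
_CONDITION_NAMES = {c.name for c in CONDITIONS}


class SchemaError(ValueError):
    def __init__(self, errors):
        self.errors = errors
        preview = "; ".join(f"row {r}: {rule}: {msg}"
                            for r, rule, msg in errors[:5])
        more = "" if len(errors) <= 5 else f" (+{len(errors) - 5} more)"
        super().__init__(f"{len(errors)} schema violation(s): {preview}{more}")


@dataclass
class GameplayDataset:
    """Trial records plus a per-subject demographics table keyed by uid."""

    trials: pd.DataFrame
    demographics: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["uid"]))

    def __post_init__(self) -> None:
        missing = set(TRIAL_COLUMNS) - set(self.trials.columns)
        if missing:
            raise ValueError(f"trials missing columns: {sorted(missing)}")
        self.trials = self.trials[TRIAL_COLUMNS].reset_index(drop=True)

    @property
    def n_subjects(self) -> int:
        return self.trials["uid"].nunique()

    def gameplay_keys(self) -> list:
        """Unique (uid, gameplay) pairs, the bootstrap/CV resampling unit."""
        return list(
            self.trials[["uid", "gameplay"]]
            .drop_duplicates().itertuples(index=False, name=None))

    def subset_gameplays(self, keys) -> "GameplayDataset":
        keyset = set(keys)
        mask = [
            k in keyset
            for k in zip(self.trials["uid"], self.trials["gameplay"])
        ]
        uids = {k[0] for k in keyset}
        demo = self.demographics[self.demographics["uid"].isin(uids)] \
            if len(self.demographics) else self.demographics
        return GameplayDataset(self.trials[mask].copy(), demo.copy())

    def subset_subjects(self, uids) -> "GameplayDataset":
        uids = set(uids)
        demo = self.demographics[self.demographics["uid"].isin(uids)] \
            if len(self.demographics) else self.demographics
        return GameplayDataset(
            self.trials[self.trials["uid"].isin(uids)].copy(), demo.copy())

    def validate(self, strict: bool = True):
        errors = validate_trials(self.trials)
        if errors and strict:
            raise SchemaError(errors)
        return errors


def _expected_sample_value(row, k: int):
    """Board value that sample event k must have revealed."""
    srow = row[f"s{k}_row"]
    prior_a = 1 + sum(1 for m in range(1, k) if row[f"s{m}_row"] == "A")
    prior_b = sum(1 for m in range(1, k) if row[f"s{m}_row"] == "B")
    if srow == "A":
        return (row["a1"], row["a2"])[prior_a] if prior_a < 2 else None
    return (row["b1"], row["b2"])[prior_b] if prior_b < 2 else None


def validate_trials(trials: pd.DataFrame) -> list:
    """All schema-rule violations as (row_index, rule, message) tuples."""
    errors = []

    def check(mask, rule, msg):
        for idx in trials.index[np.asarray(mask)]:
            errors.append((int(idx), rule, msg))

    cards = trials[["a1", "a2", "b1", "b2"]]
    check(~cards.isin(range(1, 11)).all(axis=1).to_numpy(),
          "card-range", "board values must be integers 1..10")
    check(~trials["condition"].isin(_CONDITION_NAMES).to_numpy(),
          "condition", f"condition must be one of {sorted(_CONDITION_NAMES)}")
    check(~trials["offered_row"].isin(["A", "B"]).to_numpy(),
          "offer", "offered_row must be A or B")
    tt_expected = np.where(trials["offered_row"] == "A", "AA", "AB")
    check((trials["trial_type"] != tt_expected).to_numpy(),
          "trial-type", "trial_type inconsistent with offered_row")
    ns = trials["n_samples"]
    check((~ns.isin([0, 1, 2, 3])).to_numpy(), "n-samples",
          "n_samples must be 0..3")
    check((trials["guess_stage"] != ns + 1).to_numpy(), "guess-stage",
          "guess_stage must equal n_samples + 1")
    cost_expected = trials["guess_stage"].map(_COST_AT_GUESS)
    check((trials["total_cost"] != cost_expected).to_numpy(), "cost-schedule",
          "total_cost must follow the 10/15/20 schedule")
    check((~trials["chosen_row"].isin(["A", "B"])).to_numpy(), "chosen-row",
          "chosen_row must be A or B")

    # row-wise rules (winner, sample-event consistency)
    for idx, row in trials.iterrows():
        try:
            cond = Condition.from_name(row["condition"])
        except Exception:
            continue
        try:
            board = Board((int(row["a1"]), int(row["a2"])),
                          (int(row["b1"]), int(row["b2"])))
        except Exception:
            continue
        win = board.winner(cond)
        if win == "TIE":
            errors.append((int(idx), "tie", "tied boards are re-dealt and "
                           "must not appear"))
        elif row["winning_row"] != win:
            errors.append((int(idx), "winner",
                           f"winning_row should be {win}"))
        else:
            correct = row["chosen_row"] == win
            expect = (60 if correct else -50) - row["total_cost"]
            if row["points"] != expect:
                errors.append((int(idx), "points",
                               f"points should be {expect}"))
        n = int(row["n_samples"]) if row["n_samples"] in (0, 1, 2, 3) else 0
        for k in range(1, 4):
            srow, sval = row[f"s{k}_row"], row[f"s{k}_value"]
            if k <= n:
                if k == 1 and srow != row["offered_row"]:
                    errors.append((int(idx), "sample-row",
                                   "first sample must be the offered card"))
                    continue
                expected = _expected_sample_value(row, k)
                if srow not in ("A", "B") or expected is None:
                    errors.append((int(idx), "sample-row",
                                   f"sample {k} row invalid"))
                elif not pd.isna(sval) and int(sval) != expected:
                    errors.append((int(idx), "sample-value",
                                   f"sample {k} value should be {expected}"))
            elif not (pd.isna(srow) or srow is None) \
                    or not pd.isna(sval):
                errors.append((int(idx), "sample-null",
                               f"sample {k} must be null (only {n} samples)"))
    return errors


def write_dataset(dataset: GameplayDataset, path, demographics_path=None):
    """Write trials (and optionally demographics) as CSV."""
    path = Path(path)
    out = dataset.trials.copy()
    for col in _NULLABLE_INT:
        out[col] = out[col].astype("Int64")
    out.to_csv(path, index=False)
    if demographics_path is not None and len(dataset.demographics):
        dataset.demographics.to_csv(demographics_path, index=False)


def read_dataset(path, demographics_path=None,
                 strict: bool = True) -> GameplayDataset:
    """Read and validate a trials CSV (plus optional demographics CSV).

    In strict mode any violation raises ``SchemaError`` listing every bad
    row; lenient mode keeps the data and attaches no judgment.
    """
    trials = pd.read_csv(path)
    for col in _NULLABLE_INT:
        trials[col] = trials[col].astype("Int64")
    for col in ("s1_row", "s2_row", "s3_row"):
        trials[col] = trials[col].where(pd.notna(trials[col]), None)
    demo = (pd.read_csv(demographics_path)
            if demographics_path is not None else None)
    dataset = GameplayDataset(
        trials=trials,
        demographics=demo if demo is not None
        else pd.DataFrame(columns=["uid"]))
    dataset.validate(strict=strict)
    return dataset
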