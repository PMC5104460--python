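"""Reduced and full softmax choice models of stage-1 and stage-2 behavior.

The reduced model (beta1-beta3 plus the softmax gain tau) compares the
presented card value to the average card value, derives an uncertainty
signal, and softmaxes over the stage's full option set. The full model adds
three bias parameters: an approach bonus for the unsampleable option
(beta4), a devaluation of re-sampling the seen row on AA trials (beta5), and
a preference for sampling the currently favored row at stage 2 (beta6).

Directions are handled by card inversion: in SMALL conditions card value v
enters the model as 11 - v, so the reduced model is exactly symmetric across
the BIG/SMALL members of a pair.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .task_engine import CARD_VALUES, Condition, Direction, Operation

__all__ = [
    "MEAN_FIRST_CARD",
    "ModelParams",
    "FitResult",
    "PopulationFit",
    "effective_card",
    "omega",
    "choice_probabilities",
    "option_values",
    "stage1_values",
    "stage2_values",
    "predict_stage1",
    "predict_stage2",
    "predict_aggregate",
    "fit_aggregate",
    "crossvalidate",
    "hierarchical_fit",
    "DEFAULT_BOXES",
]

#: Expected value of the first card under the uniform 1..10 deal.
MEAN_FIRST_CARD = float(np.mean(CARD_VALUES))


class IllegalOptionError(ValueError):
    """A sampling value was requested for a row that is not purchasable."""


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the choice model.

    The reduced model is the special case beta4 = beta5 = beta6 = 0. ``tau``
    is a softmax gain (p proportional to exp(value * tau)); tau = 0 yields
    uniform choice.
    """

    beta1: float
    beta2: float
    beta3: float
    tau: float
    beta4: float = 0.0
    beta5: float = 0.0
    beta6: float = 0.0
    stage: int | None = None
    pair: Operation | None = None

    @property
    def is_reduced(self) -> bool:
        return self.beta4 == self.beta5 == self.beta6 == 0.0

    def as_vector(self, full: bool, stage: int) -> np.ndarray:
        return np.array([self.beta1, self.beta2, self.beta3, self.tau]
                        + ([self.beta4, self.beta5] if full and stage == 1 else [])
                        + ([self.beta6] if full and stage == 2 else []))

    @classmethod
    def from_vector(cls, x, full: bool, stage: int,
                    pair: Operation | None = None) -> "ModelParams":
        b4 = b5 = b6 = 0.0
        if full and stage == 1:
            b4, b5 = x[4], x[5]
        elif full and stage == 2:
            b6 = x[4]
        return cls(beta1=float(x[0]), beta2=float(x[1]), beta3=float(x[2]),
                   tau=float(x[3]), beta4=float(b4), beta5=float(b5),
                   beta6=float(b6), stage=stage, pair=pair)


def effective_card(value: int, direction: Direction) -> float:
    """Direction-invariant card value: BIG keeps v, SMALL maps v -> 11 - v."""
    if direction is Direction.BIG:
        return float(value)
    return 11.0 - float(value)


def omega(v_a: float, v_b: float) -> float:
    """Uncertainty in choosing between A and B.

    Negative squared deviation of the logistic choice probability from 0.5:
    0 when the options are equal, -0.25 at certainty.
    """
    return -float((expit(v_b - v_a) - 0.5) ** 2)


def choice_probabilities(values: dict, tau: float) -> dict:
    """Softmax with gain tau over an option->value map."""
    if not values:
        raise ValueError("empty option set")
    keys = list(values)
    v = np.array([values[k] for k in keys], dtype=float) * tau
    v -= v.max()
    e = np.exp(v)
    p = e / e.sum()
    return dict(zip(keys, p))


def stage1_values(card_eff: float, trial_type: str,
                  params: ModelParams) -> dict:
    """Option values at stage 1: {'A', 'B', 'sampleA'|'sampleB'}.

    ``card_eff`` is the effective (direction-inverted) first-card value.
    The beta4 approach bonus goes to the option that cannot be sampled; it
    feeds into omega, so it also reshapes the value of sampling.
    """
    if trial_type not in ("AA", "AB"):
        raise ValueError(f"trial_type must be AA or AB, got {trial_type!r}")
    v_a = params.beta1 * (card_eff - MEAN_FIRST_CARD)
    v_b = params.beta1 * (MEAN_FIRST_CARD - card_eff)
    if trial_type == "AB":
        v_a += params.beta4 * card_eff
    else:
        v_b += params.beta4 * MEAN_FIRST_CARD
    w = omega(v_a, v_b)
    v_sample = params.beta2 + params.beta3 * w
    if trial_type == "AA":
        v_sample -= params.beta5 * card_eff
        return {"A": v_a, "B": v_b, "sampleA": v_sample}
    return {"A": v_a, "B": v_b, "sampleB": v_sample}


def stage2_values(c1_eff: float, c2_eff: float, params: ModelParams) -> dict:
    """Option values at stage 2 on AB trials: {'A', 'B', 'sampleA', 'sampleB'}."""
    v_a = params.beta1 * (c1_eff - c2_eff)
    v_b = params.beta1 * (c2_eff - c1_eff)
    w = omega(v_a, v_b)
    base = params.beta2 + params.beta3 * w
    return {
        "A": v_a,
        "B": v_b,
        "sampleA": base + params.beta6 * (c1_eff - c2_eff),
        "sampleB": base + params.beta6 * (c2_eff - c1_eff),
    }


def option_values(*, stage: int, trial_type: str | None = None,
                  card_eff: float | None = None, c1_eff: float | None = None,
                  c2_eff: float | None = None, params: ModelParams) -> dict:
    """Dispatch to the stage-specific value computation."""
    if stage == 1:
        return stage1_values(card_eff, trial_type, params)
    if stage == 2:
        return stage2_values(c1_eff, c2_eff, params)
    raise ValueError(f"model covers stages 1 and 2 only, got {stage}")


# ---------------------------------------------------------------------------
# aggregate-level prediction and fitting


def predict_stage1(params: ModelParams, direction: Direction,
                   trial_type: str) -> pd.DataFrame:
    """Predicted stage-1 option probabilities per raw card value (1..10)."""
    rows = []
    sample_key = "sampleA" if trial_type == "AA" else "sampleB"
    for card in CARD_VALUES:
        vals = stage1_values(effective_card(card, direction), trial_type,
                             params)
        p = choice_probabilities(vals, params.tau)
        rows.append({"card": card, "p_choose_a": p["A"], "p_choose_b": p["B"],
                     "p_sample": p[sample_key]})
    return pd.DataFrame(rows).set_index("card")


def predict_stage2(params: ModelParams, direction: Direction) -> pd.DataFrame:
    """Predicted stage-2 AB option probabilities per raw card pair (i, j)."""
    rows = []
    for i in CARD_VALUES:
        for j in CARD_VALUES:
            vals = stage2_values(effective_card(i, direction),
                                 effective_card(j, direction), params)
            p = choice_probabilities(vals, params.tau)
            rows.append({"i": i, "j": j, "p_choose_a": p["A"],
                         "p_choose_b": p["B"], "p_sample_a": p["sampleA"],
                         "p_sample_b": p["sampleB"]})
    return pd.DataFrame(rows).set_index(["i", "j"])


def predict_aggregate(params: ModelParams, pair: Operation,
                      stage: int) -> dict:
    """Model probabilities for every observed cell layout of one pair.

    Returns a dict keyed by (direction, trial_type) at stage 1 or direction
    at stage 2, each a prediction frame aligned with the empirical tables.
    """
    if stage == 1:
        return {(d, tt): predict_stage1(params, d, tt)
                for d in Direction for tt in ("AA", "AB")}
    return {d: predict_stage2(params, d) for d in Direction}


@dataclass
class FitResult:
    params: ModelParams
    objective: float
    n_restarts: int
    converged: bool
    full: bool
    stage: int
    pair: Operation
    fold_sse: list = field(default_factory=list)
    boxes: dict = field(default_factory=dict)


#: Random-restart boxes for the derivative-free search (artifact decision,
#: logged with every fit).
DEFAULT_BOXES = {"beta1": (-5.0, 5.0), "beta2": (-5.0, 5.0),
                 "beta3": (-5.0, 5.0), "tau": (0.0, 10.0),
                 "beta4": (-5.0, 5.0), "beta5": (-5.0, 5.0),
                 "beta6": (-5.0, 5.0)}


def _param_names(full: bool, stage: int):
    names = ["beta1", "beta2", "beta3", "tau"]
    if full and stage == 1:
        names += ["beta4", "beta5"]
    elif full and stage == 2:
        names += ["beta6"]
    return names


def _observed_stage1_cells(tables, pair: Operation):
    """Occupied stage-1 cells as flat arrays for the vectorized objective."""
    c_eff, is_ab, obs, n = [], [], [], []
    for d in Direction:
        cond = Condition(pair, d)
        for tt in ("AA", "AB"):
            for card in CARD_VALUES:
                row = tables.stage1_cell(cond, tt, card)
                if row is None or row["n"] == 0:
                    continue
                c_eff.append(effective_card(card, d))
                is_ab.append(tt == "AB")
                obs.append([row["n_choose_a"] / row["n"],
                            row["n_choose_b"] / row["n"],
                            row["n_sample"] / row["n"]])
                n.append(row["n"])
    return {"stage": 1, "c_eff": np.array(c_eff),
            "is_ab": np.array(is_ab, bool),
            "obs": np.array(obs), "n": np.array(n, float)}


def _observed_stage2_cells(tables, pair: Operation):
    c1, c2, obs, n = [], [], [], []
    for d in Direction:
        cond = Condition(pair, d)
        for i in CARD_VALUES:
            for j in CARD_VALUES:
                row = tables.stage2_cell(cond, i, j)
                if row is None or row["n"] == 0:
                    continue
                c1.append(effective_card(i, d))
                c2.append(effective_card(j, d))
                obs.append([row["n_choose_a"] / row["n"],
                            row["n_choose_b"] / row["n"],
                            row["n_sample_a"] / row["n"],
                            row["n_sample_b"] / row["n"]])
                n.append(row["n"])
    return {"stage": 2, "c1": np.array(c1), "c2": np.array(c2),
            "obs": np.array(obs), "n": np.array(n, float)}


def _predict_cells(x, cells, full: bool):
    """Vectorized model probabilities for every cell, shape (n_cells, k)."""
    b1, b2, b3, tau = x[0], x[1], x[2], x[3]
    if cells["stage"] == 1:
        b4 = x[4] if full else 0.0
        b5 = x[5] if full else 0.0
        c, is_ab = cells["c_eff"], cells["is_ab"]
        v_a = b1 * (c - MEAN_FIRST_CARD) + np.where(is_ab, b4 * c, 0.0)
        v_b = b1 * (MEAN_FIRST_CARD - c) + np.where(
            is_ab, 0.0, b4 * MEAN_FIRST_CARD)
        w = -((expit(v_b - v_a) - 0.5) ** 2)
        v_s = b2 + b3 * w - np.where(is_ab, 0.0, b5 * c)
        v = np.column_stack([v_a, v_b, v_s])
    else:
        b6 = x[4] if full else 0.0
        diff = cells["c1"] - cells["c2"]
        v_a = b1 * diff
        w = -((expit(-2.0 * v_a) - 0.5) ** 2)
        base = b2 + b3 * w
        v = np.column_stack([v_a, -v_a, base + b6 * diff, base - b6 * diff])
    v = v * tau
    v = v - v.max(axis=1, keepdims=True)
    e = np.exp(v)
    return e / e.sum(axis=1, keepdims=True)


def sse_objective(x, cells, full: bool, stage: int, weighted: bool = False):
    """Sum of squared errors between observed and predicted cell probabilities."""
    pred = _predict_cells(np.asarray(x, float), cells, full)
    sq = ((cells["obs"] - pred) ** 2).sum(axis=1)
    if weighted:
        sq = sq * cells["n"]
    return float(sq.sum())


def fit_aggregate(tables, stage: int, pair: Operation, full: bool = False,
                  n_restarts: int = 50, seed: int | None = None,
                  weighted: bool = False, boxes: dict | None = None,
                  maxiter: int = 2000) -> FitResult:
    """Fit the model to aggregate tables by multi-start Nelder-Mead on SSE."""
    boxes = dict(DEFAULT_BOXES, **(boxes or {}))
    names = _param_names(full, stage)
    cells = (_observed_stage1_cells(tables, pair) if stage == 1
             else _observed_stage2_cells(tables, pair))
    if not cells:
        raise ValueError("no occupied cells to fit")
    rng = np.random.default_rng(seed)
    lo = np.array([boxes[n][0] for n in names])
    hi = np.array([boxes[n][1] for n in names])

    def objective(x):
        # soft box penalty keeps the derivative-free search inside the
        # documented parameter boxes (the SSE has a weak tau/beta ridge)
        excess = np.maximum(0.0, lo - x) + np.maximum(0.0, x - hi)
        return (sse_objective(x, cells, full, stage, weighted)
                + 10.0 * float((excess ** 2).sum()))

    best = None
    any_converged = False
    for _ in range(n_restarts):
        x0 = rng.uniform(lo, hi)
        res = minimize(objective, x0,
                       method="Nelder-Mead",
                       options={"maxiter": maxiter, "xatol": 1e-6,
                                "fatol": 1e-9})
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if not any_converged:
        warnings.warn("no restart converged; returning best incumbent")
    x = best.x
    if x[3] < 0:
        # exact mirror degeneracy (V, tau) -> (-V, -tau): canonicalize to
        # non-negative softmax gain
        x = -x
    params = ModelParams.from_vector(x, full, stage, pair)
    sse = sse_objective(x, cells, full, stage, weighted)
    return FitResult(params=params, objective=float(sse),
                     n_restarts=n_restarts, converged=any_converged,
                     full=full, stage=stage, pair=pair,
                     boxes={n: boxes[n] for n in names})


def crossvalidate(dataset, stage: int, pair: Operation, k: int = 10,
                  seed: int | None = None, n_restarts: int = 10,
                  conditions=None) -> pd.DataFrame:
    """10-fold nested cross-validation of reduced vs full model.

    Gameplays are partitioned into k folds; for each fold both models are fit
    on the aggregate of the other k-1 folds and scored (SSE) on the held-out
    fold's aggregate. Returns one row per (fold, model).
    """
    from .bias_statistics import aggregate_tables

    conditions = conditions or [Condition(pair, d) for d in Direction]
    plays = dataset.gameplay_keys()
    if k > len(plays):
        raise ValueError(f"k={k} exceeds {len(plays)} gameplays")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(plays))
    folds = np.array_split(order, k)
    records = []
    for fold_idx, test_ids in enumerate(folds):
        test_keys = [plays[i] for i in test_ids]
        train = dataset.subset_gameplays([p for p in plays
                                          if p not in set(test_keys)])
        test = dataset.subset_gameplays(test_keys)
        train_tables = aggregate_tables(train, conditions)
        test_tables = aggregate_tables(test, conditions)
        for full in (False, True):
            fit = fit_aggregate(train_tables, stage, pair, full=full,
                                n_restarts=n_restarts,
                                seed=int(rng.integers(2 ** 31)))
            test_cells = (_observed_stage1_cells(test_tables, pair)
                          if stage == 1
                          else _observed_stage2_cells(test_tables, pair))
            sse = sse_objective(fit.params.as_vector(full, stage), test_cells,
                                full, stage)
            records.append({"fold": fold_idx, "model": "full" if full
                            else "reduced", "train_sse": fit.objective,
                            "test_sse": sse})
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# hierarchical (empirical Bayes) population fit


@dataclass
class PopulationFit:
    subject_params: pd.DataFrame  # one row per uid, columns = parameter names
    mean: np.ndarray
    covariance: np.ndarray
    names: list
    correlations: dict  # ("beta4","beta5") etc -> r
    n_iterations: int
    converged: bool

    def corr(self, p1: str, p2: str) -> float:
        return self.correlations[tuple(sorted((p1, p2)))]


#: Hierarchical parameter vector. The softmax gain tau is fixed to 1 and
#: absorbed into the betas: per-subject tau is only weakly identified and a
#: free gain injects shared scaling noise into every beta pair, corrupting
#: the between-subject correlation estimates the fit exists to measure.
_HIER_NAMES = ["beta1", "beta2", "beta3", "beta4", "beta5", "beta6"]


def _subject_design(trials: pd.DataFrame, pair: Operation):
    """Extract per-trial decision arrays for one subject within one pair.

    Stage-1 decisions on every trial, plus stage-2 decisions on AB trials
    that reached stage 2 (the modelled decisions only).
    """
    s1_card, s1_tt, s1_choice = [], [], []
    s2_c1, s2_c2, s2_choice = [], [], []
    for row in trials.itertuples():
        cond = Condition.from_name(row.condition)
        if cond.operation is not pair:
            continue
        card_eff = effective_card(row.a1, cond.direction)
        tt = row.trial_type
        if row.guess_stage == 1:
            choice = 0 if row.chosen_row == "A" else 1
        else:
            choice = 2
        s1_card.append(card_eff)
        s1_tt.append(tt)
        s1_choice.append(choice)
        if tt == "AB" and row.n_samples >= 1:
            c2_eff = effective_card(row.s1_value, cond.direction)
            if row.guess_stage == 2:
                ch = 0 if row.chosen_row == "A" else 1
            elif row.n_samples >= 2:
                ch = 2 if row.s2_row == "A" else 3
            else:
                continue
            s2_c1.append(card_eff)
            s2_c2.append(c2_eff)
            s2_choice.append(ch)
    return ((np.array(s1_card), np.array(s1_tt), np.array(s1_choice)),
            (np.array(s2_c1), np.array(s2_c2), np.array(s2_choice)))


def _neg_log_lik(theta, design):
    """Trial-level negative log likelihood for one subject.

    theta = (beta1..beta6, log_tau); stage-1 options (A, B, sample), stage-2
    options (A, B, sampleA, sampleB).
    """
    b1, b2, b3, b4, b5, b6 = theta
    tau = 1.0
    (s1_card, s1_tt, s1_choice), (s2_c1, s2_c2, s2_choice) = design
    nll = 0.0
    if len(s1_card):
        is_ab = s1_tt == "AB"
        v_a = b1 * (s1_card - MEAN_FIRST_CARD)
        v_b = -v_a
        v_a = v_a + np.where(is_ab, b4 * s1_card, 0.0)
        v_b = v_b + np.where(is_ab, 0.0, b4 * MEAN_FIRST_CARD)
        w = -((expit(v_b - v_a) - 0.5) ** 2)
        v_s = b2 + b3 * w - np.where(is_ab, 0.0, b5 * s1_card)
        v = np.column_stack([v_a, v_b, v_s]) * tau
        v -= v.max(axis=1, keepdims=True)
        logp = v - np.log(np.exp(v).sum(axis=1, keepdims=True))
        nll -= logp[np.arange(len(s1_choice)), s1_choice].sum()
    if len(s2_c1):
        diff = s2_c1 - s2_c2
        v_a = b1 * diff
        v_b = -v_a
        w = -((expit(v_b - v_a) - 0.5) ** 2)
        base = b2 + b3 * w
        v = np.column_stack([v_a, v_b, base + b6 * diff,
                             base - b6 * diff]) * tau
        v -= v.max(axis=1, keepdims=True)
        logp = v - np.log(np.exp(v).sum(axis=1, keepdims=True))
        nll -= logp[np.arange(len(s2_choice)), s2_choice].sum()
    return nll


def _nearest_psd(m: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    sym = (m + m.T) / 2
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() >= eps:
        return sym
    warnings.warn("covariance update not PSD; projecting")
    vals = np.clip(vals, eps, None)
    return (vecs * vals) @ vecs.T


def _numeric_hessian(f, x, h=1e-3):
    n = len(x)
    hess = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            xpp = x.copy(); xpp[i] += h; xpp[j] += h
            xpm = x.copy(); xpm[i] += h; xpm[j] -= h
            xmp = x.copy(); xmp[i] -= h; xmp[j] += h
            xmm = x.copy(); xmm[i] -= h; xmm[j] -= h
            hess[i, j] = hess[j, i] = (
                f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * h * h)
    _ = f0
    return hess


def hierarchical_fit(dataset, pair: Operation, max_iter: int = 12,
                     tol: float = 1e-3, laplace: bool = True,
                     init_mean: np.ndarray | None = None,
                     verbose: bool = False) -> PopulationFit:
    """Iterative empirical-Bayes fit of per-subject parameters.

    Alternates per-subject MAP estimation under a Gaussian population prior
    on (beta1..beta6) with updates of the population mean and
    covariance (scatter of the MAPs plus, optionally, the mean Laplace
    posterior covariance). Reports the pairwise correlations of the bias
    parameters beta4, beta5, beta6.
    """
    names = _HIER_NAMES
    trials = dataset.trials
    designs = {}
    for uid, sub in trials.groupby("uid"):
        design = _subject_design(sub, pair)
        if len(design[0][0]):
            designs[uid] = design
    if len(designs) < 2:
        raise ValueError("need at least two subjects with trials in this pair")
    uids = sorted(designs)
    dim = len(names)

    mu = np.zeros(dim) if init_mean is None else np.asarray(init_mean, float)
    if init_mean is None:
        mu[0] = 0.5   # beta1
    sigma = np.eye(dim) * 0.5

    thetas = np.tile(mu, (len(uids), 1))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        sigma_inv = np.linalg.inv(sigma)

        def map_objective(theta, design):
            d = theta - mu
            return _neg_log_lik(theta, design) + 0.5 * d @ sigma_inv @ d

        lap_cov = np.zeros((dim, dim))
        for k, uid in enumerate(uids):
            res = minimize(map_objective, thetas[k], args=(designs[uid],),
                           method="Nelder-Mead",
                           options={"maxiter": 800, "xatol": 1e-4,
                                    "fatol": 1e-6})
            thetas[k] = res.x
            if laplace:
                hess = _numeric_hessian(
                    lambda x: map_objective(x, designs[uid]), res.x)
                try:
                    lap_cov += np.linalg.inv(_nearest_psd(hess, 1e-6))
                except np.linalg.LinAlgError:
                    lap_cov += np.linalg.inv(sigma_inv)
        new_mu = thetas.mean(axis=0)
        scatter = np.cov(thetas, rowvar=False, bias=True)
        new_sigma = scatter + (lap_cov / len(uids) if laplace else 0.0)
        new_sigma = _nearest_psd(new_sigma)
        delta = max(np.abs(new_mu - mu).max(),
                    np.abs(new_sigma - sigma).max())
        mu, sigma = new_mu, new_sigma
        if verbose:  # pragma: no cover
            print(f"iter {it}: delta={delta:.5f}")
        if delta < tol:
            converged = True
            break

    # Correlations are taken from the scatter of the per-subject MAP
    # estimates: the Laplace term stabilizes the EM covariance but its
    # per-subject uncertainty (uncorrelated across parameters) would dilute
    # the between-subject correlation signal if included here.
    corr = {}
    idx = {n: i for i, n in enumerate(names)}
    scatter = np.cov(thetas, rowvar=False)
    for p1, p2 in (("beta4", "beta5"), ("beta4", "beta6"),
                   ("beta5", "beta6")):
        i, j = idx[p1], idx[p2]
        denom = math.sqrt(scatter[i, i] * scatter[j, j])
        corr[(p1, p2)] = scatter[i, j] / denom if denom > 0 else 0.0
    subject_params = pd.DataFrame(thetas, index=pd.Index(uids, name="uid"),
                                  columns=names)
    return PopulationFit(subject_params=subject_params, mean=mu,
                         covariance=sigma, names=names, correlations=corr,
                         n_iterations=it, converged=converged)
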