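"""Approach-avoidance model of the companion risky-choice task.

Subjects choose between a certain amount and a 50/50 gamble on three trial
types (gain, mixed, loss). The choice rule is a softmax of the utility
difference, shifted by a value-independent bias beta that compresses the
probability range to (beta, 1) when beta >= 0 and to (0, 1 + beta) when
beta < 0. beta is fit separately for gain trials (beta_gain) and loss trials
(beta_loss); mixed trials carry no bias term. The difference
beta_gain - beta_loss is the approach-avoid index used for the median split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

__all__ = [
    "TrialType",
    "GambleTrial",
    "GambleParams",
    "utility",
    "p_gamble",
    "fit_gamble_subject",
    "fit_gamble_population",
    "split_by_approach_index",
    "InvalidParameterError",
]


class InvalidParameterError(ValueError):
    pass


GAIN, MIXED, LOSS = "GAIN", "MIXED", "LOSS"
TrialType = (GAIN, MIXED, LOSS)


@dataclass(frozen=True)
class GambleTrial:
    trial_type: str
    certain: float
    outcome1: float
    outcome2: float
    chose_gamble: bool | None = None

    def __post_init__(self) -> None:
        if self.trial_type not in TrialType:
            raise ValueError(f"unknown trial type {self.trial_type!r}")
        if self.trial_type == GAIN and not (
                self.certain > 0 and min(self.outcome1, self.outcome2) == 0
                and max(self.outcome1, self.outcome2) > self.certain):
            raise ValueError("GAIN trial: certain gain vs {larger gain, 0}")
        if self.trial_type == LOSS and not (
                self.certain < 0 and max(self.outcome1, self.outcome2) == 0
                and min(self.outcome1, self.outcome2) < self.certain):
            raise ValueError("LOSS trial: certain loss vs {larger loss, 0}")
        if self.trial_type == MIXED and not (
                self.certain == 0 and min(self.outcome1, self.outcome2) < 0
                < max(self.outcome1, self.outcome2)):
            raise ValueError("MIXED trial: certain zero vs {gain, loss}")


@dataclass(frozen=True)
class GambleParams:
    """mu: choice sensitivity; beta_*: value-independent biases in (-1, 1);
    alpha/lam: power-utility curvature and loss aversion."""

    mu: float
    beta_gain: float
    beta_loss: float
    alpha: float = 1.0
    lam: float = 1.0
    at_boundary: bool = False

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise InvalidParameterError("mu must be >= 0")
        for b in (self.beta_gain, self.beta_loss):
            if abs(b) >= 1:
                raise InvalidParameterError("|beta| must be < 1")
        if self.alpha <= 0 or self.lam <= 0:
            raise InvalidParameterError("alpha and lam must be positive")


def utility(x, alpha: float = 1.0, lam: float = 1.0):
    """Power-law value function with loss aversion."""
    x = np.asarray(x, dtype=float)
    return np.where(x >= 0, np.abs(x) ** alpha, -lam * np.abs(x) ** alpha)


def _utilities(trial: GambleTrial, params: GambleParams):
    u_c = float(utility(trial.certain, params.alpha, params.lam))
    u_g = 0.5 * float(utility(trial.outcome1, params.alpha, params.lam)) \
        + 0.5 * float(utility(trial.outcome2, params.alpha, params.lam))
    return u_c, u_g


def p_gamble(trial: GambleTrial, params: GambleParams) -> float:
    """Probability of accepting the gamble.

    P = (1 - beta) * sigma(mu * dU) + beta  for beta >= 0  (bounds (beta, 1))
    P = (1 + beta) * sigma(mu * dU)         for beta < 0   (bounds (0, 1+beta))
    with dU = U_gamble - U_certain, beta = beta_gain on gain trials,
    beta_loss on loss trials, 0 on mixed trials.
    """
    u_c, u_g = _utilities(trial, params)
    base = float(expit(params.mu * (u_g - u_c)))
    beta = {GAIN: params.beta_gain, LOSS: params.beta_loss,
            MIXED: 0.0}[trial.trial_type]
    if beta >= 0:
        return (1.0 - beta) * base + beta
    return (1.0 + beta) * base


def _p_gamble_arrays(trials: pd.DataFrame, x, fit_curvature: bool):
    if fit_curvature:
        mu, bg, bl, alpha, lam = x
    else:
        mu, bg, bl = x
        alpha, lam = 1.0, 1.0
    u_c = utility(trials["certain"].to_numpy(), alpha, lam)
    u_g = 0.5 * utility(trials["outcome1"].to_numpy(), alpha, lam) \
        + 0.5 * utility(trials["outcome2"].to_numpy(), alpha, lam)
    base = expit(mu * (u_g - u_c))
    tt = trials["trial_type"].to_numpy()
    beta = np.where(tt == GAIN, bg, np.where(tt == LOSS, bl, 0.0))
    return np.where(beta >= 0, (1 - beta) * base + beta, (1 + beta) * base)


_BETA_EDGE = 0.999


def fit_gamble_subject(trials: pd.DataFrame, n_restarts: int = 10,
                       seed: int | None = None,
                       fit_curvature: bool = False) -> GambleParams:
    """Maximum-likelihood fit of one subject's gamble choices.

    ``trials`` needs columns trial_type, certain, outcome1, outcome2,
    chose_gamble. Degenerate responders (all-gamble / all-certain) are fit
    anyway but flagged ``at_boundary`` when any beta lands on its bound.
    """
    if len(trials) < 1:
        raise ValueError("need at least one trial")
    y = trials["chose_gamble"].to_numpy().astype(bool)

    def nll(x):
        p = np.clip(_p_gamble_arrays(trials, x, fit_curvature), 1e-12,
                    1 - 1e-12)
        return -float(np.log(np.where(y, p, 1 - p)).sum())

    bounds = [(1e-4, 50.0), (-_BETA_EDGE, _BETA_EDGE),
              (-_BETA_EDGE, _BETA_EDGE)]
    if fit_curvature:
        bounds += [(0.2, 2.0), (0.2, 5.0)]
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        x0 = np.array([rng.uniform(lo, hi) for lo, hi in bounds])
        res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    x = best.x
    at_boundary = bool(abs(x[1]) >= _BETA_EDGE - 1e-6
                       or abs(x[2]) >= _BETA_EDGE - 1e-6)
    if at_boundary:
        warnings.warn("beta estimate at parameter boundary "
                      "(degenerate responder?)")
    if fit_curvature:
        return GambleParams(mu=x[0], beta_gain=x[1], beta_loss=x[2],
                            alpha=x[3], lam=x[4], at_boundary=at_boundary)
    return GambleParams(mu=x[0], beta_gain=x[1], beta_loss=x[2],
                        at_boundary=at_boundary)


def fit_gamble_population(gambles: pd.DataFrame, seed: int | None = None,
                          n_restarts: int = 10) -> pd.DataFrame:
    """Fit every subject in a gamble dataset; one row per uid."""
    rng = np.random.default_rng(seed)
    rows = []
    for uid, sub in gambles.groupby("uid"):
        params = fit_gamble_subject(sub, n_restarts=n_restarts,
                                    seed=int(rng.integers(2 ** 31)))
        rows.append({"uid": uid, "mu": params.mu,
                     "beta_gain": params.beta_gain,
                     "beta_loss": params.beta_loss,
                     "approach_index": params.beta_gain - params.beta_loss,
                     "at_boundary": params.at_boundary})
    return pd.DataFrame(rows)


def split_by_approach_index(fits: pd.DataFrame):
    """Median split on beta_gain - beta_loss.

    Returns ``(high_uids, low_uids)``; ties at the median go to the low
    group.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fitted subjects")
    index = fits["approach_index"] if "approach_index" in fits \
        else fits["beta_gain"] - fits["beta_loss"]
    med = float(index.median())
    high = fits.loc[index > med, "uid"].tolist()
    low = fits.loc[index <= med, "uid"].tolist()
    return high, low
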