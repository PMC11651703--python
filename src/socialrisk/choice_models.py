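"""The four nested choice models as safe-choice probabilities and likelihoods.

All models share a power-utility valuation of each lottery,

    U = p_high * v_high**alpha + (1 - p_high) * v_low**alpha,

with risk preference ``alpha`` (written rho in some treatments; < 1 risk
averse, 1 neutral, > 1 seeking) and a softmax/logistic choice rule with
inverse temperature ``beta``:

* ``solo_rp``  — P(safe) = logistic(beta * (U_safe - U_risky)); the pure
  individual risk-preference model.
* ``ocu``      — adds other-conferred utility: an additive bonus ``ocu`` on
  the option unanimously chosen by the two other players, signed by the
  trial's indicator delta (+1 info_safe, -1 info_risky, 0 otherwise).
* ``ocu_free`` — a value-free heuristic on unanimous trials: P(safe) =
  w_follow on info_safe and w_oppose = 1 - w_follow on info_risky; solo and
  mixed trials fall back to the solo rule.
* ``hybrid``   — the full simplex mixture w_follow + w_oppose + w_utility = 1
  combining the heuristic routes with the OCU probability.

The heuristic weights bound the hybrid safe-choice probability: on info_safe
trials it lies in [w_follow, 1 - w_oppose], on info_risky trials in
[w_oppose, 1 - w_follow], whatever the gambles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .task_design import Session, Trial, session_to_frame

__all__ = [
    "AgentParameters",
    "ModelSpec",
    "MODELS",
    "get_model",
    "gamble_utility",
    "p_safe_solo",
    "p_safe_ocu",
    "p_safe_hybrid",
    "normalized_ocu",
    "p_safe_table",
    "neg_log_likelihood",
    "PROB_CLAMP",
]

#: Safe-choice probabilities are clamped to [PROB_CLAMP, 1 - PROB_CLAMP]
#: inside likelihoods so extreme heuristic weights (w_follow = 1 with one
#: discordant choice) cannot produce an infinite negative log likelihood.
PROB_CLAMP = 1e-9

_SIMPLEX_TOL = 1e-10


@dataclass(frozen=True)
class AgentParameters:
    """Subject-level parameters of the hybrid model (supersets the nested ones).

    ``beta`` inverse temperature (> 0), ``alpha`` risk-preference exponent
    (> 0), ``ocu`` other-conferred utility (utility units, any sign), and the
    mixture weights on the unit simplex.
    """

    beta: float
    alpha: float
    ocu: float = 0.0
    w_follow: float = 0.0
    w_oppose: float = 0.0
    w_utility: float = 1.0

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        w = (self.w_follow, self.w_oppose, self.w_utility)
        if any(x < -_SIMPLEX_TOL or x > 1 + _SIMPLEX_TOL for x in w):
            raise ValueError(f"weights must lie in [0, 1], got {w}")
        if abs(sum(w) - 1.0) > 1e-8:
            raise ValueError(f"weights must sum to 1, got {w} (sum {sum(w)})")

    @property
    def weights(self) -> tuple[float, float, float]:
        return (self.w_follow, self.w_oppose, self.w_utility)


@dataclass(frozen=True)
class ModelSpec:
    """Roster of one nested model: which parameters are free.

    ``hier_params`` are the hierarchically pooled subject-level parameters
    (on their sampling scale: log_beta, log_alpha, ocu); ``n_weight_free`` is
    the number of free simplex coordinates estimated per individual.
    ``n_group_params`` is the group-level free-parameter count used in the
    iBIC penalty (2 hyperparameters per pooled parameter + free weights);
    ``n_individual_params`` the per-subject count used for individual-level
    model comparison.
    """

    name: str
    hier_params: tuple[str, ...]
    n_weight_free: int

    @property
    def n_group_params(self) -> int:
        return 2 * len(self.hier_params) + self.n_weight_free

    @property
    def n_individual_params(self) -> int:
        return len(self.hier_params) + self.n_weight_free

    def constrain(self, beta, alpha, ocu, w_follow, w_oppose, w_utility):
        """Project arbitrary parameter arrays onto this model's subspace."""
        zero = np.zeros_like(np.asarray(beta, dtype=float))
        one = zero + 1.0
        if self.name == "solo_rp":
            return beta, alpha, zero, zero, zero, one
        if self.name == "ocu":
            return beta, alpha, ocu, zero, zero, one
        if self.name == "ocu_free":
            wf = np.asarray(w_follow, dtype=float)
            return beta, alpha, zero, wf, 1.0 - wf, zero
        return beta, alpha, ocu, w_follow, w_oppose, w_utility


MODELS: dict[str, ModelSpec] = {
    "solo_rp": ModelSpec("solo_rp", ("log_beta", "log_alpha"), 0),
    "ocu": ModelSpec("ocu", ("log_beta", "log_alpha", "ocu"), 0),
    "ocu_free": ModelSpec("ocu_free", ("log_beta", "log_alpha"), 1),
    "hybrid": ModelSpec("hybrid", ("log_beta", "log_alpha", "ocu"), 2),
}

_ALIASES = {"solo": "solo_rp", "ocu_based": "ocu"}


def get_model(name: str | ModelSpec) -> ModelSpec:
    if isinstance(name, ModelSpec):
        return name
    key = str(name).lower()
    key = _ALIASES.get(key, key)
    try:
        return MODELS[key]
    except KeyError:
        raise ValueError(f"unknown model {name!r}; choose from {sorted(MODELS)}") from None


def gamble_utility(p_high, v_high, v_low, alpha):
    """Power utility of a two-outcome lottery: p*vh**a + (1-p)*vl**a."""
    v_high = np.asarray(v_high, dtype=float)
    v_low = np.asarray(v_low, dtype=float)
    if np.any(v_high <= 0) or np.any(v_low <= 0):
        raise ValueError("payoffs must be strictly positive")
    p = np.asarray(p_high, dtype=float)
    a = np.asarray(alpha, dtype=float)
    if np.any(a <= 0):
        raise ValueError("alpha must be > 0")
    out = p * v_high**a + (1.0 - p) * v_low**a
    return out if out.ndim else float(out)


def _utility_diff(pair, alpha):
    u_safe = gamble_utility(pair.p_high, pair.v_high_safe, pair.v_low_safe, alpha)
    u_risky = gamble_utility(pair.p_high, pair.v_high_risky, pair.v_low_risky, alpha)
    return u_safe - u_risky


def _logistic(x):
    # stable logistic; fine for the argument ranges the task produces
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=float)))


def p_safe_solo(pair, params: AgentParameters) -> float:
    """P(choose safer) under the solo risk-preference model."""
    return float(_logistic(params.beta * _utility_diff(pair, params.alpha)))


def p_safe_ocu(trial: Trial, params: AgentParameters) -> float:
    """P(choose safer) under the other-conferred-utility model.

    Reduces exactly to :func:`p_safe_solo` when ``delta == 0`` or
    ``params.ocu == 0``.
    """
    du = _utility_diff(trial.pair, params.alpha) + trial.delta * params.ocu
    return float(_logistic(params.beta * du))


def p_safe_hybrid(trial: Trial, params: AgentParameters) -> float:
    """P(choose safer) under the full heuristic/utility mixture."""
    p_ocu = p_safe_ocu(trial, params)
    if trial.trial_type == "info_safe":
        return params.w_follow + params.w_utility * p_ocu
    if trial.trial_type == "info_risky":
        return params.w_oppose + params.w_utility * p_ocu
    return p_ocu


def normalized_ocu(beta, ocu):
    """Map OCU to its realized choice-probability contribution, logistic(beta*ocu).

    0.5 means no contribution; values approach 1 (or 0) as the conferred
    utility dominates (or repels) choice.
    """
    beta = np.asarray(beta, dtype=float)
    if np.any(beta <= 0):
        raise ValueError("beta must be > 0")
    out = _logistic(beta * np.asarray(ocu, dtype=float))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# vectorized table interface (used by simulation and inference)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialArrays:
    """Column view of a trial table, shaped (n_trials,)."""

    p_high: np.ndarray
    v_high_safe: np.ndarray
    v_low_safe: np.ndarray
    v_high_risky: np.ndarray
    v_low_risky: np.ndarray
    delta: np.ndarray
    is_info_safe: np.ndarray
    is_info_risky: np.ndarray

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TrialArrays":
        tt = frame["trial_type"].to_numpy()
        return cls(
            p_high=frame["p_high"].to_numpy(dtype=float),
            v_high_safe=frame["v_high_safe"].to_numpy(dtype=float),
            v_low_safe=frame["v_low_safe"].to_numpy(dtype=float),
            v_high_risky=frame["v_high_risky"].to_numpy(dtype=float),
            v_low_risky=frame["v_low_risky"].to_numpy(dtype=float),
            delta=frame["delta"].to_numpy(dtype=float),
            is_info_safe=(tt == "info_safe"),
            is_info_risky=(tt == "info_risky"),
        )

    def __len__(self) -> int:
        return len(self.p_high)


def p_safe_table(trials: TrialArrays, beta, alpha, ocu, w_follow, w_oppose, w_utility):
    """Hybrid-model safe-choice probabilities for a whole trial table.

    Parameter arrays broadcast against the trailing trial axis, so shapes
    like (n_subjects, 1) against (n_trials,) give a (n_subjects, n_trials)
    probability matrix in one call. The nested models are the obvious
    parameter restrictions (see :meth:`ModelSpec.constrain`).
    """
    beta = np.asarray(beta, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    ocu = np.asarray(ocu, dtype=float)
    u_safe = trials.p_high * trials.v_high_safe**alpha + (1.0 - trials.p_high) * trials.v_low_safe**alpha
    u_risky = trials.p_high * trials.v_high_risky**alpha + (1.0 - trials.p_high) * trials.v_low_risky**alpha
    p_ocu = _logistic(beta * (u_safe - u_risky + trials.delta * ocu))
    w_follow = np.asarray(w_follow, dtype=float)
    w_oppose = np.asarray(w_oppose, dtype=float)
    w_utility = np.asarray(w_utility, dtype=float)
    p = np.where(
        trials.is_info_safe,
        w_follow + w_utility * p_ocu,
        np.where(trials.is_info_risky, w_oppose + w_utility * p_ocu, p_ocu),
    )
    return p


def _params_to_arrays(params: AgentParameters):
    return (params.beta, params.alpha, params.ocu,
            params.w_follow, params.w_oppose, params.w_utility)


def neg_log_likelihood(
    model: str | ModelSpec,
    session: Session | pd.DataFrame,
    choices: Sequence[int] | np.ndarray,
    params: AgentParameters,
    trial_filter: Callable[[pd.DataFrame], np.ndarray] | str | None = None,
    clamp: float = PROB_CLAMP,
) -> float:
    """Bernoulli negative log likelihood of observed choices under a model.

    ``trial_filter`` restricts scoring to a subset of trials — either a trial
    type name (e.g. ``"solo"``) or a callable mapping the trial frame to a
    boolean mask. Probabilities are clamped to ``[clamp, 1 - clamp]``.
    """
    spec = get_model(model)
    if isinstance(session, Session):
        frame = session_to_frame(session)
    elif isinstance(session, pd.DataFrame):
        frame = session
    else:
        raise TypeError("session must be a Session or trial DataFrame")
    choices = np.asarray(choices, dtype=float)
    if len(choices) != len(frame):
        raise ValueError(f"{len(choices)} choices for {len(frame)} trials")

    if trial_filter is not None:
        if callable(trial_filter):
            mask = np.asarray(trial_filter(frame), dtype=bool)
        else:
            mask = (frame["trial_type"] == str(trial_filter).lower()).to_numpy()
        frame = frame.loc[mask]
        choices = choices[mask]

    arrays = TrialArrays.from_frame(frame)
    constrained = spec.constrain(*_params_to_arrays(params))
    p = p_safe_table(arrays, *constrained)
    p = np.clip(p, clamp, 1.0 - clamp)
    return float(-np.sum(choices * np.log(p) + (1.0 - choices) * np.log(1.0 - p)))
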