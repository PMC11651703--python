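"""Gambling-task construction: lottery menus, probabilities, trial types, sessions.

The task presents, on every trial, a pair of two-outcome lotteries that share
the same high-payoff probability; the "riskier" member of the pair has a wider
payoff spread (strictly greater payoff variance). A session crosses a
per-subject random selection of lottery menus with six win probabilities and
four trial types:

* ``solo`` — the subject chooses alone,
* ``info_safe`` — two other players both chose the safer gamble,
* ``info_risky`` — both chose the riskier gamble,
* ``info_mix`` — the two others split.

The unanimity indicator ``delta`` is +1 on info_safe, -1 on info_risky and 0
otherwise; it is the only representation of the social display the choice
models consume.

Choice coding convention used throughout the package: ``choice = 1`` means the
safer gamble was chosen, ``choice = 0`` the riskier one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TRIAL_TYPES",
    "DELTA_BY_TYPE",
    "PROBABILITIES",
    "HOLT_LAURY_TEMPLATE",
    "DEFAULT_MENU_SCALES",
    "GamblePair",
    "Trial",
    "Session",
    "make_menu_set",
    "build_session",
    "session_to_frame",
    "sessions_to_frame",
]

TRIAL_TYPES = ("solo", "info_safe", "info_risky", "info_mix")
DELTA_BY_TYPE = {"solo": 0, "info_safe": 1, "info_risky": -1, "info_mix": 0}

#: High-payoff probability levels crossed with every menu.
PROBABILITIES = (0.40, 0.50, 0.60, 0.70, 0.80, 0.90)

#: Classic Holt–Laury payoff quadruple (v_high_safe, v_low_safe,
#: v_high_risky, v_low_risky) used as the base menu template.
HOLT_LAURY_TEMPLATE = (2.00, 1.60, 3.85, 0.10)

#: Multiplicative scalings producing the default family of eight menus.
DEFAULT_MENU_SCALES = (1.0, 1.25, 1.5, 1.75, 2.0, 2.25, 2.5, 2.75)


class ConfigurationError(ValueError):
    """Raised when a task/design configuration violates its invariants."""


def _lottery_variance(p_high: float, v_high: float, v_low: float) -> float:
    m = p_high * v_high + (1.0 - p_high) * v_low
    return p_high * (v_high - m) ** 2 + (1.0 - p_high) * (v_low - m) ** 2


@dataclass(frozen=True)
class GamblePair:
    """A safer and a riskier two-outcome lottery sharing one win probability."""

    menu_id: int
    p_high: float
    v_high_safe: float
    v_low_safe: float
    v_high_risky: float
    v_low_risky: float

    def __post_init__(self) -> None:
        vals = (self.v_high_safe, self.v_low_safe, self.v_high_risky, self.v_low_risky)
        if any(v <= 0 for v in vals):
            raise ConfigurationError(f"payoffs must be positive, got {vals}")
        if not (self.v_high_risky > self.v_high_safe and self.v_low_risky < self.v_low_safe):
            raise ConfigurationError(
                "riskier gamble must have a wider spread: "
                f"need v_high_risky > v_high_safe and v_low_risky < v_low_safe, got {vals}"
            )
        if not 0.0 < self.p_high < 1.0:
            raise ConfigurationError(f"p_high must lie in (0, 1), got {self.p_high}")

    @property
    def var_safe(self) -> float:
        return _lottery_variance(self.p_high, self.v_high_safe, self.v_low_safe)

    @property
    def var_risky(self) -> float:
        return _lottery_variance(self.p_high, self.v_high_risky, self.v_low_risky)


@dataclass(frozen=True)
class Trial:
    trial_index: int
    pair: GamblePair
    trial_type: str
    delta: int = field(init=False)

    def __post_init__(self) -> None:
        if self.trial_type not in TRIAL_TYPES:
            raise ConfigurationError(f"unknown trial type {self.trial_type!r}")
        object.__setattr__(self, "delta", DELTA_BY_TYPE[self.trial_type])


@dataclass(frozen=True)
class Session:
    subject_id: str
    trials: tuple[Trial, ...]
    rng_seed: int | None = None

    def __len__(self) -> int:
        return len(self.trials)


def make_menu_set(
    n_menus: int = 8,
    payoff_config: Sequence[float] | None = None,
    rng: np.random.Generator | None = None,
    scales: Sequence[float] | None = None,
) -> list[tuple[float, float, float, float]]:
    """Build ``n_menus`` payoff quadruples from a base template.

    Menus are multiplicative scalings of ``payoff_config`` (default: the
    Holt–Laury quadruple). Scaling preserves the spread ordering and the
    variance dominance of the riskier lottery at every probability level.

    Parameters
    ----------
    n_menus : number of menus to produce (>= 1).
    payoff_config : base (v_high_safe, v_low_safe, v_high_risky, v_low_risky).
    rng : unused by the deterministic default family; accepted so custom
        template generators can be slotted in with the same signature.
    scales : one multiplier per menu; defaults to ``DEFAULT_MENU_SCALES``.
    """
    if n_menus < 1:
        raise ConfigurationError("n_menus must be >= 1")
    base = tuple(payoff_config) if payoff_config is not None else HOLT_LAURY_TEMPLATE
    if len(base) != 4:
        raise ConfigurationError("payoff template must have four entries")
    vhs, vls, vhr, vlr = base
    if not (vhr > vhs and vlr < vls) or min(base) <= 0:
        raise ConfigurationError(f"invalid payoff template {base}: spread ordering violated")
    if scales is None:
        scales = DEFAULT_MENU_SCALES
    if len(scales) < n_menus:
        raise ConfigurationError(f"need at least {n_menus} scales, got {len(scales)}")
    menus = [tuple(round(s * v, 6) for v in base) for s in scales[:n_menus]]
    # scaling cannot break the ordering, but a custom template might sit on
    # the boundary after rounding — validate each menu at one probability
    for m in menus:
        GamblePair(0, 0.5, *m)
    return menus


def build_session(
    menus: Sequence[Sequence[float]],
    subject_id: str,
    rng: np.random.Generator,
    n_select: int = 4,
    probabilities: Sequence[float] = PROBABILITIES,
    trial_types: Sequence[str] = TRIAL_TYPES,
) -> Session:
    """Assemble one subject's randomized session.

    ``n_select`` menus are drawn without replacement from ``menus`` and fully
    crossed with the probability levels and trial types; the resulting trials
    (default 4 x 6 x 4 = 96) are then shuffled into a subject-unique order.
    Every (menu, probability) pair appears exactly once per trial type, so the
    four trial types are exactly balanced.
    """
    if len(menus) < n_select:
        raise ConfigurationError(f"need at least {n_select} menus, got {len(menus)}")
    chosen = rng.choice(len(menus), size=n_select, replace=False)
    cells = [
        (int(mi), float(p), tt)
        for mi in chosen
        for p in probabilities
        for tt in trial_types
    ]
    order = rng.permutation(len(cells))
    trials = []
    for t, k in enumerate(order):
        mi, p, tt = cells[k]
        pair = GamblePair(mi, p, *menus[mi])
        trials.append(Trial(trial_index=t, pair=pair, trial_type=tt))
    return Session(subject_id=str(subject_id), trials=tuple(trials))


_COLUMNS = [
    "subject_id",
    "trial_index",
    "menu_id",
    "p_high",
    "v_high_safe",
    "v_low_safe",
    "v_high_risky",
    "v_low_risky",
    "trial_type",
    "delta",
]


def session_to_frame(session: Session) -> pd.DataFrame:
    """One row per trial, in presentation order, using the standard schema."""
    rows = [
        (
            session.subject_id,
            t.trial_index,
            t.pair.menu_id,
            t.pair.p_high,
            t.pair.v_high_safe,
            t.pair.v_low_safe,
            t.pair.v_high_risky,
            t.pair.v_low_risky,
            t.trial_type,
            t.delta,
        )
        for t in session.trials
    ]
    return pd.DataFrame(rows, columns=_COLUMNS)


def sessions_to_frame(sessions: Sequence[Session]) -> pd.DataFrame:
    return pd.concat([session_to_frame(s) for s in sessions], ignore_index=True)
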