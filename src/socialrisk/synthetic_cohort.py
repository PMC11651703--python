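"""Synthetic cohorts: agent populations, choice simulation, exclusion rules.

The generator stands in for participant data. It emulates a three-group
design — non-lesion controls (``NC``) and two lesion-like groups (``INSULA``,
``DACC``) — in which the lesion-like groups have lower inverse temperature
(noisier utility-based choice) and a simplex region shifted toward the
follow heuristic and away from the utility route. Per-agent parameters are
drawn hierarchically (log-normal beta and alpha, normal OCU, uniform-simplex
weights rejection-sampled into a per-group range box) and choices are
Bernoulli draws from the chosen model's safe-choice probabilities over a
fresh randomized 96-trial session.

Two a-priori behavioral exclusion rules mirror the study design:

1. *probability-monotonicity*: a subject whose riskier-choice proportion at
   the 90% win level is strictly lower than at the 40% level is excluded
   (they chose the larger high payoff less often as winning became more
   likely);
2. *solo-invariance*: a subject who chose all-safe or all-risky on every
   solo trial is excluded (bi-directional social influence is impossible).

``simulate_until_valid`` resamples an agent's parameters and re-simulates
whenever its simulated behavior trips an exclusion rule, so the returned
cohort has exactly the requested number of included subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .choice_models import AgentParameters, ModelSpec, TrialArrays, get_model, p_safe_table
from .task_design import Session, build_session, make_menu_set, session_to_frame

__all__ = [
    "GroupSpec",
    "ChoiceDataset",
    "DEFAULT_GROUPS",
    "sample_simplex_box",
    "sample_agents",
    "simulate_choices",
    "apply_exclusions",
    "simulate_until_valid",
    "simulate_cohort",
]


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class GroupSpec:
    """Population-level description of one synthetic group.

    ``mean_log_beta``/``sd_log_beta`` etc. are the hyper mean and SD of the
    sampling distributions (beta and alpha log-normal, OCU normal);
    ``weight_box`` gives inclusive [lo, hi] bounds per mixture weight within
    which uniform-simplex draws are accepted.
    """

    label: str
    n_subjects: int
    mean_log_beta: float = np.log(2.0)
    sd_log_beta: float = 0.8
    mean_log_alpha: float = float(np.log(0.85))
    sd_log_alpha: float = 0.3
    mean_ocu: float = 0.2
    sd_ocu: float = 0.4
    weight_box: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "w_follow": (0.0, 1.0),
            "w_oppose": (0.0, 1.0),
            "w_utility": (0.0, 1.0),
        }
    )

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if min(self.sd_log_beta, self.sd_log_alpha, self.sd_ocu) < 0:
            raise ValueError("hyper SDs must be >= 0")
        for name, (lo, hi) in self.weight_box.items():
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"weight range for {name} must satisfy 0 <= lo <= hi <= 1")


#: Default three-group study conditions. The lesion-like groups have lower
#: inverse temperature and a heuristic-shifted simplex region; controls are
#: utility-dominant. Sample sizes follow the analyzed cohort (28/10/6).
DEFAULT_GROUPS: tuple[GroupSpec, ...] = (
    GroupSpec(
        label="NC",
        n_subjects=28,
        mean_log_beta=float(np.log(3.0)),
        sd_log_beta=0.5,
        weight_box={"w_follow": (0.0, 0.4), "w_oppose": (0.0, 0.35), "w_utility": (0.45, 1.0)},
    ),
    GroupSpec(
        label="INSULA",
        n_subjects=10,
        mean_log_beta=float(np.log(1.2)),
        sd_log_beta=0.5,
        weight_box={"w_follow": (0.25, 0.85), "w_oppose": (0.0, 0.4), "w_utility": (0.05, 0.55)},
    ),
    GroupSpec(
        label="DACC",
        n_subjects=6,
        mean_log_beta=float(np.log(1.2)),
        sd_log_beta=0.5,
        weight_box={"w_follow": (0.25, 0.85), "w_oppose": (0.0, 0.4), "w_utility": (0.05, 0.55)},
    ),
)


@dataclass
class ChoiceDataset:
    """Trial table with choices plus (for simulated data) the ground truth."""

    frame: pd.DataFrame
    truth: dict[str, AgentParameters] = field(default_factory=dict)
    groups: dict[str, str] = field(default_factory=dict)
    resample_counts: dict[str, int] = field(default_factory=dict)

    @property
    def subject_ids(self) -> list[str]:
        return list(dict.fromkeys(self.frame["subject_id"]))

    def subject_frame(self, subject_id: str) -> pd.DataFrame:
        return self.frame[self.frame["subject_id"] == subject_id]

    def truth_records(self) -> dict[str, dict]:
        """JSON-ready sidecar of true parameters keyed by subject id."""
        return {
            sid: {
                "beta": p.beta, "alpha": p.alpha, "ocu": p.ocu,
                "w_follow": p.w_follow, "w_oppose": p.w_oppose, "w_utility": p.w_utility,
                "group": self.groups.get(sid, ""),
            }
            for sid, p in self.truth.items()
        }


def _box_feasible(box: Mapping[str, tuple[float, float]]) -> bool:
    los = [box.get(k, (0.0, 1.0))[0] for k in ("w_follow", "w_oppose", "w_utility")]
    his = [box.get(k, (0.0, 1.0))[1] for k in ("w_follow", "w_oppose", "w_utility")]
    return sum(los) <= 1.0 <= sum(his)


def sample_simplex_box(
    rng: np.random.Generator,
    box: Mapping[str, tuple[float, float]] | None = None,
    size: int = 1,
    max_rejections: int = 200_000,
) -> np.ndarray:
    """Uniform draws from the unit 2-simplex, rejection-sampled into a box.

    Returns an array of shape (size, 3) ordered (w_follow, w_oppose,
    w_utility). Without a box this is an exact Dirichlet(1, 1, 1).
    """
    if box is None:
        box = {}
    keys = ("w_follow", "w_oppose", "w_utility")
    lo = np.array([box.get(k, (0.0, 1.0))[0] for k in keys])
    hi = np.array([box.get(k, (0.0, 1.0))[1] for k in keys])
    if not _box_feasible(box):
        raise ValueError(f"weight range box {dict(box)} does not intersect the unit simplex")
    out = np.empty((size, 3))
    filled = 0
    drawn = 0
    while filled < size:
        batch = max(4 * (size - filled), 256)
        w = rng.dirichlet(np.ones(3), size=batch)
        ok = np.all((w >= lo) & (w <= hi), axis=1)
        take = w[ok][: size - filled]
        out[filled : filled + len(take)] = take
        filled += len(take)
        drawn += batch
        if drawn > max_rejections and filled == 0:
            raise ValueError(
                f"weight range box {dict(box)} admitted no draws in {drawn} attempts; "
                "the feasible simplex region is empty or vanishingly small"
            )
    return out


def sample_agents(spec: GroupSpec, rng: np.random.Generator) -> list[AgentParameters]:
    """Draw ``spec.n_subjects`` agents from the group's hyper-distributions."""
    n = spec.n_subjects
    log_beta = rng.normal(spec.mean_log_beta, spec.sd_log_beta, size=n)
    log_alpha = rng.normal(spec.mean_log_alpha, spec.sd_log_alpha, size=n)
    ocu = rng.normal(spec.mean_ocu, spec.sd_ocu, size=n)
    w = sample_simplex_box(rng, spec.weight_box, size=n)
    return [
        AgentParameters(
            beta=float(np.exp(log_beta[i])),
            alpha=float(np.exp(log_alpha[i])),
            ocu=float(ocu[i]),
            w_follow=float(w[i, 0]),
            w_oppose=float(w[i, 1]),
            w_utility=float(w[i, 2]),
        )
        for i in range(n)
    ]


def _simulate_one(
    agent: AgentParameters,
    model: ModelSpec,
    session: Session,
    rng: np.random.Generator,
) -> pd.DataFrame:
    frame = session_to_frame(session)
    arrays = TrialArrays.from_frame(frame)
    constrained = model.constrain(
        agent.beta, agent.alpha, agent.ocu, agent.w_follow, agent.w_oppose, agent.w_utility
    )
    p = p_safe_table(arrays, *constrained)
    frame = frame.copy()
    frame["choice"] = (rng.random(len(frame)) < p).astype(int)
    return frame


def simulate_choices(
    agents: Sequence[AgentParameters],
    model: str | ModelSpec,
    rng: np.random.Generator,
    menus: Sequence[Sequence[float]] | None = None,
    sessions: Sequence[Session] | None = None,
    group_label: str = "",
    id_prefix: str = "sub",
    id_offset: int = 0,
) -> ChoiceDataset:
    """Simulate one Bernoulli choice per trial for every agent.

    Each agent receives a fresh randomized session built from ``menus``
    (default menu set) unless explicit ``sessions`` are supplied — the latter
    reproduces the "same gamble sequences" style of recovery study.
    """
    spec = get_model(model)
    if menus is None:
        menus = make_menu_set()
    frames, truth, groups = [], {}, {}
    for i, agent in enumerate(agents):
        sid = f"{id_prefix}{id_offset + i:03d}"
        session = (
            sessions[i]
            if sessions is not None
            else build_session(menus, sid, rng)
        )
        if sessions is not None and session.subject_id != sid:
            session = replace(session, subject_id=sid)
        frames.append(_simulate_one(agent, spec, session, rng))
        frames[-1]["subject_id"] = sid
        truth[sid] = agent
        groups[sid] = group_label
    frame = pd.concat(frames, ignore_index=True)
    if group_label:
        frame.insert(1, "group", group_label)
    return ChoiceDataset(frame=frame, truth=truth, groups=groups)


def _exclusion_flags(sub: pd.DataFrame, p_lo: float = 0.40, p_hi: float = 0.90,
                     solo_only: bool = False) -> tuple[bool, bool]:
    scope = sub[sub["trial_type"] == "solo"] if solo_only else sub
    risky = 1.0 - scope["choice"]
    at_lo = risky[scope["p_high"].round(2) == round(p_lo, 2)]
    at_hi = risky[scope["p_high"].round(2) == round(p_hi, 2)]
    if len(at_lo) == 0 or len(at_hi) == 0:
        raise ValueError(
            f"subject {sub['subject_id'].iloc[0]!r} lacks trials at the "
            f"{p_lo:.0%} or {p_hi:.0%} probability level"
        )
    # strict decrease excludes; an exact tie keeps the subject
    monotone_violation = float(at_hi.mean()) < float(at_lo.mean())
    solo = sub[sub["trial_type"] == "solo"]["choice"]
    solo_invariant = len(solo) > 0 and (solo.min() == solo.max())
    return monotone_violation, solo_invariant


def apply_exclusions(
    dataset: ChoiceDataset | pd.DataFrame,
    solo_only: bool = False,
) -> tuple[ChoiceDataset, pd.DataFrame]:
    """Apply both a-priori exclusion rules; return (kept dataset, report).

    The report has one row per subject with boolean columns
    ``rule_monotonicity`` (riskier-choice proportion at the 90% level
    strictly below the 40% level, over all trials by default) and
    ``rule_solo_invariant`` (all-safe or all-risky on solo trials), plus the
    combined ``excluded`` flag. ``solo_only=True`` restricts rule 1 to solo
    trials (sensitivity-analysis variant).
    """
    ds = dataset if isinstance(dataset, ChoiceDataset) else ChoiceDataset(frame=dataset)
    rows = []
    for sid in ds.subject_ids:
        mono, invariant = _exclusion_flags(ds.subject_frame(sid), solo_only=solo_only)
        rows.append((sid, mono, invariant, mono or invariant))
    report = pd.DataFrame(
        rows, columns=["subject_id", "rule_monotonicity", "rule_solo_invariant", "excluded"]
    )
    keep_ids = set(report.loc[~report["excluded"], "subject_id"])
    kept = ChoiceDataset(
        frame=ds.frame[ds.frame["subject_id"].isin(keep_ids)].reset_index(drop=True),
        truth={k: v for k, v in ds.truth.items() if k in keep_ids},
        groups={k: v for k, v in ds.groups.items() if k in keep_ids},
        resample_counts=dict(ds.resample_counts),
    )
    return kept, report


def simulate_until_valid(
    spec: GroupSpec,
    model: str | ModelSpec,
    rng: np.random.Generator,
    max_tries: int = 100,
    menus: Sequence[Sequence[float]] | None = None,
    sessions: Sequence[Session] | None = None,
    id_prefix: str | None = None,
    id_offset: int = 0,
    beta_values: Sequence[float] | None = None,
) -> ChoiceDataset:
    """Simulate exactly ``spec.n_subjects`` subjects who all pass exclusions.

    Whenever a simulated subject trips a rule, a brand-new parameter set is
    drawn and its behavior re-simulated (up to ``max_tries`` per slot; the
    per-subject resample counts are recorded on the dataset).
    ``beta_values``, if given, pins each slot's inverse temperature to a
    supplied value (only alpha/OCU/weights are redrawn on resampling), which
    mirrors recovery protocols that reuse empirical betas.
    """
    if max_tries < 1:
        raise ValueError("max_tries must be >= 1")
    model = get_model(model)
    if menus is None:
        menus = make_menu_set()
    prefix = id_prefix if id_prefix is not None else f"{spec.label.lower()}_"
    frames, truth, groups, counts = [], {}, {}, {}
    one = replace(spec, n_subjects=1)
    for slot in range(spec.n_subjects):
        sid = f"{prefix}{id_offset + slot:03d}"
        for attempt in range(1, max_tries + 1):
            agent = sample_agents(one, rng)[0]
            if beta_values is not None:
                agent = AgentParameters(
                    beta=float(beta_values[slot]), alpha=agent.alpha, ocu=agent.ocu,
                    w_follow=agent.w_follow, w_oppose=agent.w_oppose, w_utility=agent.w_utility,
                )
            session = sessions[slot] if sessions is not None else build_session(menus, sid, rng)
            if session.subject_id != sid:
                session = replace(session, subject_id=sid)
            sub = _simulate_one(agent, model, session, rng)
            sub["subject_id"] = sid
            mono, invariant = _exclusion_flags(sub)
            if not (mono or invariant):
                frames.append(sub)
                truth[sid] = agent
                groups[sid] = spec.label
                counts[sid] = attempt - 1
                break
        else:
            raise SimulationError(
                f"subject slot {sid}: no simulated parameter set passed the exclusion "
                f"rules in {max_tries} tries (group {spec.label!r}); the group spec "
                "may be concentrated on degenerate behavior"
            )
    frame = pd.concat(frames, ignore_index=True)
    frame.insert(1, "group", spec.label)
    return ChoiceDataset(frame=frame, truth=truth, groups=groups, resample_counts=counts)


def simulate_cohort(
    groups: Sequence[GroupSpec] = DEFAULT_GROUPS,
    model: str | ModelSpec = "hybrid",
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    max_tries: int = 100,
) -> ChoiceDataset:
    """Full multi-group cohort, every subject passing the exclusion rules."""
    if rng is None:
        rng = np.random.default_rng(seed)
    parts = [simulate_until_valid(g, model, rng, max_tries=max_tries) for g in groups]
    frame = pd.concat([p.frame for p in parts], ignore_index=True)
    ds = ChoiceDataset(frame=frame)
    for p in parts:
        ds.truth.update(p.truth)
        ds.groups.update(p.groups)
        ds.resample_counts.update(p.resample_counts)
    return ds
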