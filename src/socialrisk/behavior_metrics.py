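"""Model-agnostic behavioral measures: choice curves and conformity profiles.

The conformity profile summarizes each subject's reaction to unanimous
social information without reference to any fitted model: ``c_safe`` is the
proportion of safe choices when both others chose safe, ``c_risky`` the
proportion of risky choices when both others chose risky. A purely
utility-driven subject whose conformity to safe and risky information trades
off lands near the line c_risky = 1 - c_safe; subjects who follow (or
oppose) others regardless of the gambles sit away from it. The scalar

    distance = |c_safe + c_risky - 1| / sqrt(2)

is the orthogonal distance to that line (unsigned; maximum 1/sqrt(2)) and
serves as the model-free index of heuristic social-information use against
which the fitted follow/oppose weights are validated.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .choice_models import AgentParameters
from .resampling_stats import robust_correlation
from .synthetic_cohort import ChoiceDataset

__all__ = ["choice_curve", "conformity_profile", "validate_weights"]


def _frame(dataset) -> pd.DataFrame:
    return dataset.frame if isinstance(dataset, ChoiceDataset) else dataset


def choice_curve(dataset, trial_filter: str | None = None) -> pd.DataFrame:
    """Per-subject safe-choice proportion at each probability level.

    Long format: one row per (subject, p_high) with columns ``p_safe`` and,
    when present in the data, the subject's group label. Group curves are the
    mean of subject curves:

    >>> curve.groupby(["group", "p_high"])["p_safe"].mean()  # doctest: +SKIP
    """
    frame = _frame(dataset)
    if trial_filter is not None:
        frame = frame[frame["trial_type"] == trial_filter.lower()]
    keys = ["subject_id"] + (["group"] if "group" in frame.columns else [])
    out = (
        frame.groupby(keys + ["p_high"], sort=True)["choice"]
        .mean()
        .rename("p_safe")
        .reset_index()
    )
    return out


def conformity_profile(dataset, min_trials: int = 5) -> pd.DataFrame:
    """Per-subject conformity rates and distance to the c_risky = 1 - c_safe line.

    Cells with fewer than ``min_trials`` trials yield NaN for the affected
    quantities (excluded pairwise downstream).
    """
    frame = _frame(dataset)
    rows = []
    for sid, sub in frame.groupby("subject_id", sort=False):
        safe_info = sub[sub["trial_type"] == "info_safe"]["choice"]
        risky_info = sub[sub["trial_type"] == "info_risky"]["choice"]
        solo = sub[sub["trial_type"] == "solo"]["choice"]
        if len(safe_info) == 0 or len(risky_info) == 0:
            raise ValueError(f"subject {sid!r} lacks unanimous info trials")
        c_safe = safe_info.mean() if len(safe_info) >= min_trials else np.nan
        c_risky = 1.0 - risky_info.mean() if len(risky_info) >= min_trials else np.nan
        rows.append({
            "subject_id": sid,
            "group": sub["group"].iloc[0] if "group" in sub.columns else "",
            "c_safe": c_safe,
            "c_risky": c_risky,
            "solo_safe_rate": solo.mean() if len(solo) else np.nan,
            "distance": abs(c_safe + c_risky - 1.0) / np.sqrt(2.0),
        })
    return pd.DataFrame(rows).set_index("subject_id")


def validate_weights(
    profiles: pd.DataFrame,
    median_params: Mapping[str, AgentParameters],
    n_iter: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Robust correlations between the conformity distance and fitted weights.

    Returns one row per weight (follow, oppose) with the skipped Pearson r
    and its bootstrap p. On cohorts where the heuristic weights drive
    behavior the distance correlates positively with w_follow and negatively
    with w_oppose; the values are reported, not asserted.
    """
    rows = []
    for k, attr in (("w_follow", "w_follow"), ("w_oppose", "w_oppose")):
        sids = [s for s in profiles.index if s in median_params]
        d = profiles.loc[sids, "distance"].to_numpy(dtype=float)
        w = np.array([getattr(median_params[s], attr) for s in sids])
        ok = np.isfinite(d) & np.isfinite(w)
        res = robust_correlation(d[ok], w[ok], n_iter=n_iter, seed=seed)
        rows.append({
            "weight": k, "r": res.r, "p": res.p_value,
            "n": res.n, "n_outliers": res.n_outliers,
        })
    return pd.DataFrame(rows).set_index("weight")
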