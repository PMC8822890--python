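"""Session-grid enumeration, feasibility classification and summaries.

The study design sweeps work-interval durations 15-300 s and rest durations
15-300 s (both in 15-s steps) crossed with 2-20 repetitions, keeps the
configurations whose total duration n*work + (n-1)*rest lies between 30 s
(the shortest session with a computable NP) and 90 min, and solves, for
each athlete profile and each of the two exhaustion models, the work power
that drives the session to exhaustion.  A session is classified
*impossible* when that solved power strictly exceeds the athlete's maximal
power over the work-interval duration — the model is demanding a personal
best be beaten on every repetition.  Under the default ranges the filter
keeps exactly 6198 plans.

Summaries report the percentage of impossible sessions overall and within
subsets sharing the same prescribed intensity (% of MAP, binned), work
duration, total work time, or rest duration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import coggan, skiba
from .exceptions import HiitSimError
from .profiles import AthleteProfile
from .skiba import SessionPlan

__all__ = [
    "SKIBA",
    "COGGAN_MODIFIED",
    "MODELS",
    "GROUP_VARIABLES",
    "SessionRecord",
    "generate_plans",
    "classify_session",
    "run_grid",
    "records_to_frame",
    "overall_fraction",
    "summarize",
]

SKIBA = "skiba"
COGGAN_MODIFIED = "coggan_modified"
MODELS = (SKIBA, COGGAN_MODIFIED)

GROUP_VARIABLES = (
    "intensity_pct_map_bin",
    "work_duration",
    "total_work_time",
    "rest_duration",
)

DEFAULT_WORK_DURATIONS = tuple(range(15, 301, 15))
DEFAULT_REPS = tuple(range(2, 21))
DEFAULT_REST_DURATIONS = tuple(range(15, 301, 15))
DEFAULT_MIN_TOTAL_S = 30.0
DEFAULT_MAX_TOTAL_S = 5400.0
DEFAULT_REST_FRACTION = 0.5


@dataclass(frozen=True)
class SessionRecord:
    """Feasibility result for one (model, profile, plan) cell."""

    model: str
    profile: str
    plan: SessionPlan
    solved_power: float
    pmax_work: float
    ratio: float  # 100 * solved_power / pmax_work
    impossible: bool
    intensity_pct_map: float
    total_work_time: float
    error: str | None = None


def generate_plans(
    work_durations: Sequence[float] = DEFAULT_WORK_DURATIONS,
    reps: Sequence[int] = DEFAULT_REPS,
    rest_durations: Sequence[float] = DEFAULT_REST_DURATIONS,
    rest_power: float = 0.0,
    min_total: float = DEFAULT_MIN_TOTAL_S,
    max_total: float = DEFAULT_MAX_TOTAL_S,
) -> list[SessionPlan]:
    """Enumerate the session grid, keeping totals in [min_total, max_total].

    Deterministic ordering: work duration, then repetitions, then rest
    duration, each ascending.  ``rest_power`` is a placeholder; the
    classifier replaces it with the profile-specific recovery power.
    """
    plans = []
    for work in work_durations:
        for n in reps:
            for rest in rest_durations:
                total = n * work + (n - 1) * rest
                if min_total <= total <= max_total:
                    plans.append(
                        SessionPlan(
                            n_reps=int(n),
                            work_duration=float(work),
                            rest_duration=float(rest),
                            rest_power=float(rest_power),
                        )
                    )
    return plans


def classify_session(
    plan: SessionPlan,
    profile: AthleteProfile,
    model: str,
    rest_fraction: float = DEFAULT_REST_FRACTION,
) -> SessionRecord:
    """Solve one session's exhaustion power and test it for feasibility.

    The recovery power is set to ``rest_fraction`` of the profile's MAP
    (default 50%, the customary active-recovery intensity).  The session is
    impossible when the solved work power strictly exceeds the profile's
    maximal power over the work-interval duration; a ratio of exactly 100%
    (e.g. a single continuous bout under the NP = Pmax criterion) remains
    possible.  Solver errors annotate the record instead of aborting a grid.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    if profile.map is None:
        raise ValueError(f"profile {profile.name!r} has no 5-min power (MAP)")
    plan = SessionPlan(
        n_reps=plan.n_reps,
        work_duration=plan.work_duration,
        rest_duration=plan.rest_duration,
        rest_power=rest_fraction * profile.map,
    )
    pmax_work = profile.pmax(plan.work_duration)
    try:
        if model == SKIBA:
            solved = skiba.solve_exhaustion_power(plan, profile.cp, profile.wprime)
        else:
            solved = coggan.solve_exhaustion_power(plan, profile)
    except HiitSimError as exc:
        return SessionRecord(
            model=model,
            profile=profile.name,
            plan=plan,
            solved_power=math.nan,
            pmax_work=pmax_work,
            ratio=math.nan,
            impossible=False,
            intensity_pct_map=math.nan,
            total_work_time=plan.total_work_time,
            error=f"{type(exc).__name__}: {exc}",
        )
    return SessionRecord(
        model=model,
        profile=profile.name,
        plan=plan.with_work_power(solved),
        solved_power=solved,
        pmax_work=pmax_work,
        ratio=100.0 * solved / pmax_work,
        # strictly greater, with a microwatt guard so a root-finder landing a
        # rounding error above an exactly-attainable bound stays "possible"
        impossible=solved > pmax_work + 1e-6,
        intensity_pct_map=100.0 * solved / profile.map,
        total_work_time=plan.total_work_time,
    )


def run_grid(
    profiles: Iterable[AthleteProfile],
    models: Sequence[str] = MODELS,
    plans: Sequence[SessionPlan] | None = None,
    rest_fraction: float = DEFAULT_REST_FRACTION,
    progress=None,
) -> list[SessionRecord]:
    """Classify every (model, profile, plan) combination, deterministically.

    ``progress``, if given, is called with a status string once per
    (model, profile) pair.
    """
    if plans is None:
        plans = generate_plans()
    records: list[SessionRecord] = []
    for model in models:
        for profile in profiles:
            if progress is not None:
                progress(f"{model}: {profile.name} ({len(plans)} sessions)")
            for plan in plans:
                records.append(classify_session(plan, profile, model, rest_fraction))
    return records


def records_to_frame(records: Sequence[SessionRecord] | pd.DataFrame) -> pd.DataFrame:
    """Tidy session-level table, one row per record."""
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame(
        {
            "model": [r.model for r in records],
            "profile": [r.profile for r in records],
            "n_reps": [r.plan.n_reps for r in records],
            "work_s": [r.plan.work_duration for r in records],
            "rest_s": [r.plan.rest_duration for r in records],
            "rest_power_w": [r.plan.rest_power for r in records],
            "solved_power_w": [r.solved_power for r in records],
            "pmax_work_w": [r.pmax_work for r in records],
            "ratio_pct": [r.ratio for r in records],
            "intensity_pct_map": [r.intensity_pct_map for r in records],
            "total_s": [r.plan.total_duration for r in records],
            "total_work_s": [r.total_work_time for r in records],
            "impossible": [r.impossible for r in records],
            "error": [r.error for r in records],
        }
    )


def overall_fraction(
    records: Sequence[SessionRecord] | pd.DataFrame, model: str, profile: str
) -> float:
    """Percentage of impossible sessions for one (model, profile) pair."""
    frame = records_to_frame(records)
    sel = frame[(frame["model"] == model) & (frame["profile"] == profile)]
    if sel.empty:
        raise ValueError(f"no records for model={model!r}, profile={profile!r}")
    return 100.0 * float(sel["impossible"].sum()) / float(len(sel))


def summarize(
    records: Sequence[SessionRecord] | pd.DataFrame,
    group_variable: str,
    intensity_bin_width: float = 5.0,
) -> pd.DataFrame:
    """Impossible-session percentages within subsets of one session parameter.

    ``intensity_pct_map_bin`` groups by half-open prescribed-intensity bins
    [k*w, (k+1)*w) in % of MAP (``group_value`` is the bin's left edge); the
    duration variables group by their exact grid values.  Grouping is per
    (model, profile).
    """
    if group_variable not in GROUP_VARIABLES:
        raise ValueError(
            f"unknown group_variable {group_variable!r}; expected one of {GROUP_VARIABLES}"
        )
    frame = records_to_frame(records).copy()
    if group_variable == "intensity_pct_map_bin":
        frame["group_value"] = (
            np.floor(frame["intensity_pct_map"] / intensity_bin_width) * intensity_bin_width
        )
    else:
        column = {
            "work_duration": "work_s",
            "total_work_time": "total_work_s",
            "rest_duration": "rest_s",
        }[group_variable]
        frame["group_value"] = frame[column]
    grouped = (
        frame.groupby(["model", "profile", "group_value"], as_index=False)
        .agg(n_sessions=("impossible", "size"), n_impossible=("impossible", "sum"))
        .sort_values(["model", "profile", "group_value"], ignore_index=True)
    )
    grouped["n_impossible"] = grouped["n_impossible"].astype(int)
    grouped["pct_impossible"] = 100.0 * grouped["n_impossible"] / grouped["n_sessions"]
    grouped.insert(2, "group_variable", group_variable)
    return grouped
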