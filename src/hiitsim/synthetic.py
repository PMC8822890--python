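"""Parametric synthetic power-duration profiles.

A minimal, deterministic generator for monotone-decreasing power-duration
curves, so every pipeline stage can be exercised and swept without the
built-in reference athletes.  The curve is anchored at the 5-min power
(MAP) and pieced from two regimes:

* short efforts (t < 300 s) follow a hyperbolic anaerobic-reserve law,
  P(t) = MAP + W'_syn * (1/t - 1/300);
* long efforts (t >= 300 s) decay log-linearly,
  P(t) = MAP * (1 + slope/100 * log10(t/300)),
  with ``endurance_slope`` in % of MAP per log10-decade of duration
  (negative; flatter = more enduring).

The two branches meet continuously at P(300) = MAP.  This surrogate is not
a physiological model — it exists to produce valid profiles whose endurance
and anaerobic reserve can be dialed independently.  CP and W' are filled by
the standard linear work-duration fit over the 2-15 min window, exactly as
they would be estimated for a real athlete.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import grid as grid_mod
from .exceptions import ProfileValidationError
from .profiles import AthleteProfile, _ols_work_fit

__all__ = [
    "REFERENCE_DURATIONS",
    "SyntheticProfileSpec",
    "power_at",
    "generate_profile",
    "endurance_sweep",
]

# The 17 tabulation durations (1 s .. 4 h) used by the reference profiles.
REFERENCE_DURATIONS = (
    1, 15, 30, 45, 60, 120, 180, 240, 300,
    600, 1200, 1800, 2700, 3600, 5400, 7200, 14400,
)

MAP_ANCHOR_S = 300.0


@dataclass(frozen=True)
class SyntheticProfileSpec:
    """Parameters of a synthetic athlete.

    ``map``: 5-min power, W.  ``endurance_slope``: % of MAP lost per
    log10-decade of duration beyond 5 min (< 0).  ``wprime_syn``: anaerobic
    reserve shaping the sub-5-min hyperbola, J.
    """

    map: float
    endurance_slope: float
    wprime_syn: float
    body_mass: float = 70.0
    name: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.map > 0:
            raise ProfileValidationError(f"map must be > 0, got {self.map}")
        if not self.endurance_slope < 0:
            raise ProfileValidationError(
                f"endurance_slope must be negative, got {self.endurance_slope}"
            )
        if not self.wprime_syn > 0:
            raise ProfileValidationError(f"wprime_syn must be > 0, got {self.wprime_syn}")


def power_at(spec: SyntheticProfileSpec, duration: float) -> float:
    """Evaluate the two-regime synthetic curve at ``duration`` seconds."""
    t = float(duration)
    if not t > 0:
        raise ValueError(f"duration must be > 0, got {t}")
    if t < MAP_ANCHOR_S:
        return spec.map + spec.wprime_syn * (1.0 / t - 1.0 / MAP_ANCHOR_S)
    return spec.map * (1.0 + spec.endurance_slope / 100.0 * np.log10(t / MAP_ANCHOR_S))


def generate_profile(
    spec: SyntheticProfileSpec,
    durations: Sequence[float] = REFERENCE_DURATIONS,
    cp_window: tuple[float, float] = (120.0, 900.0),
) -> AthleteProfile:
    """Tabulate the synthetic curve and fit CP/W' over ``cp_window``.

    Deterministic given the spec.  Raises when the parameters drive the
    long-duration branch non-positive inside the tabulated range.
    """
    powers = [power_at(spec, t) for t in durations]
    if powers[-1] <= 0:
        raise ProfileValidationError(
            f"endurance_slope {spec.endurance_slope} drives power to "
            f"{powers[-1]:.1f} W at {durations[-1]} s"
        )
    cp, wprime = _ols_work_fit(durations, powers, cp_window)
    return AthleteProfile.from_nodes(
        name=spec.name,
        body_mass=spec.body_mass,
        nodes=zip(durations, powers),
        cp=cp,
        wprime=wprime,
    )


def endurance_sweep(
    slopes: Sequence[float],
    base_spec: SyntheticProfileSpec,
    models: Sequence[str] = grid_mod.MODELS,
    plans=None,
    rest_fraction: float = grid_mod.DEFAULT_REST_FRACTION,
) -> pd.DataFrame:
    """Impossible-session percentage as a function of endurance slope.

    Regenerates the profile and re-runs the session grid for every slope in
    ``slopes`` (other spec parameters held at ``base_spec``); returns a tidy
    table of (slope, model, pct_impossible).  Flatter (less negative)
    slopes emulate more enduring athletes.
    """
    if plans is None:
        plans = grid_mod.generate_plans()
    rows = []
    for slope in slopes:
        spec = replace(base_spec, endurance_slope=float(slope), name=f"slope{slope:+g}")
        profile = generate_profile(spec)
        records = grid_mod.run_grid([profile], models=models, plans=plans,
                                    rest_fraction=rest_fraction)
        for model in models:
            rows.append(
                {
                    "slope": float(slope),
                    "model": model,
                    "pct_impossible": grid_mod.overall_fraction(records, model, profile.name),
                }
            )
    return pd.DataFrame(rows)
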