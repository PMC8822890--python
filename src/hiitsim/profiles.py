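"""Athlete power-duration profiles.

A profile is a tabulated mean-maximal power curve — the best average
mechanical power (W) an athlete can sustain for each of a set of effort
durations — together with the two-parameter critical-power constants:

* ``cp`` — critical power, the asymptote of the hyperbolic power-duration
  relationship P = W'/t + CP, conventionally the boundary between the heavy
  and severe intensity domains;
* ``wprime`` — W', the finite work capacity (J) available above CP.

Power at durations between tabulated nodes is interpolated linearly in
power versus the natural logarithm of duration; mean-maximal curves are
locally close to log-linear, and no extrapolation beyond the tabulated
range is ever performed.

Derived landmarks: FTP (functional threshold power) is the 60-min power and
MAP (maximal aerobic power) is simplified to the best 5-min power, both
read off the curve.  Three built-in reference profiles — a Time-Trialist,
an All-Rounder and a Sprinter, 70 kg elite male cyclists spanning the
endurance/anaerobic-reserve trade-off — ship with the package.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .exceptions import (
    DurationOutOfRangeError,
    InsufficientDataError,
    ProfileValidationError,
)

__all__ = [
    "AthleteProfile",
    "load_profile",
    "load_builtin",
    "builtin_names",
    "reference_profiles",
    "pmax",
    "estimate_cp_wprime",
    "FTP_DURATION_S",
    "MAP_DURATION_S",
]

FTP_DURATION_S = 3600.0
MAP_DURATION_S = 300.0


@dataclass(frozen=True)
class AthleteProfile:
    """A validated power-duration profile with CP/W' constants.

    ``durations`` are strictly increasing (s); ``powers`` strictly
    decreasing (W mechanical).  ``ftp`` and ``map`` are filled from the
    curve when the 3600 s / 300 s marks lie inside the tabulated range and
    are ``None`` otherwise.
    """

    name: str
    body_mass: float
    durations: tuple[float, ...]
    powers: tuple[float, ...]
    cp: float
    wprime: float
    ftp: float | None = field(default=None)
    map: float | None = field(default=None)

    @classmethod
    def from_nodes(
        cls,
        name: str,
        body_mass: float,
        nodes: Iterable[tuple[float, float]],
        cp: float,
        wprime: float,
    ) -> "AthleteProfile":
        """Validate ``(duration, power)`` nodes and build a profile."""
        node_list = [(float(d), float(p)) for d, p in nodes]
        if len(node_list) < 2:
            raise ProfileValidationError("a profile needs at least 2 (duration, power) nodes")
        for (d1, p1), (d2, p2) in zip(node_list, node_list[1:]):
            if d2 <= d1:
                raise ProfileValidationError(
                    f"node durations must strictly increase: {d1} s -> {d2} s"
                )
            if p2 >= p1:
                raise ProfileValidationError(
                    f"node powers must strictly decrease: {p1} W at {d1} s -> {p2} W at {d2} s"
                )
        if not cp > 0:
            raise ProfileValidationError(f"cp must be positive, got {cp}")
        if not wprime > 0:
            raise ProfileValidationError(f"wprime must be positive, got {wprime}")
        durations = tuple(d for d, _ in node_list)
        powers = tuple(p for _, p in node_list)
        profile = cls(
            name=str(name),
            body_mass=float(body_mass),
            durations=durations,
            powers=powers,
            cp=float(cp),
            wprime=float(wprime),
        )
        ftp = map_ = None
        if durations[0] <= FTP_DURATION_S <= durations[-1]:
            ftp = profile.pmax(FTP_DURATION_S)
        if durations[0] <= MAP_DURATION_S <= durations[-1]:
            map_ = profile.pmax(MAP_DURATION_S)
        object.__setattr__(profile, "ftp", ftp)
        object.__setattr__(profile, "map", map_)
        return profile

    @property
    def nodes(self) -> tuple[tuple[float, float], ...]:
        return tuple(zip(self.durations, self.powers))

    def pmax(self, duration: float) -> float:
        """Maximal mean power (W) over ``duration`` seconds.

        Exact at tabulated nodes; log-linear in duration between them.
        Raises :class:`DurationOutOfRangeError` outside the tabulated range
        — a mean-maximal curve is never extrapolated.
        """
        d = float(duration)
        if not (self.durations[0] <= d <= self.durations[-1]):
            raise DurationOutOfRangeError(
                f"duration {d} s outside tabulated range "
                f"[{self.durations[0]}, {self.durations[-1]}] s for profile {self.name!r}"
            )
        return float(
            np.interp(np.log(d), np.log(self.durations), self.powers)
        )

    def to_config(self) -> dict:
        """Round-trippable profile-description document (see :func:`load_profile`)."""
        return {
            "name": self.name,
            "body_mass_kg": self.body_mass,
            "cp_w": self.cp,
            "wprime_j": self.wprime,
            "nodes": [
                {"duration_s": d, "power_w": p} for d, p in self.nodes
            ],
        }


def load_profile(source: Mapping | str | Path) -> AthleteProfile:
    """Load a profile from a config mapping or a YAML document path.

    Schema: ``name``, ``body_mass_kg``, ``cp_w``, ``wprime_j`` and
    ``nodes`` — a list of ``{duration_s, power_w}`` mappings (or
    ``[duration, power]`` pairs), at least two of them.
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = dict(source)
    if not isinstance(doc, Mapping):
        raise ProfileValidationError("profile document must be a mapping")
    missing = [k for k in ("name", "body_mass_kg", "cp_w", "wprime_j", "nodes") if k not in doc]
    if missing:
        raise ProfileValidationError(f"profile document missing fields: {', '.join(missing)}")
    nodes = []
    for entry in doc["nodes"]:
        if isinstance(entry, Mapping):
            nodes.append((entry["duration_s"], entry["power_w"]))
        else:
            d, p = entry
            nodes.append((d, p))
    return AthleteProfile.from_nodes(
        name=doc["name"],
        body_mass=doc["body_mass_kg"],
        nodes=nodes,
        cp=doc["cp_w"],
        wprime=doc["wprime_j"],
    )


_BUILTIN_FILES = {
    "time_trialist": "time_trialist.yaml",
    "all_rounder": "all_rounder.yaml",
    "sprinter": "sprinter.yaml",
}


def builtin_names() -> tuple[str, ...]:
    """Names of the built-in reference profiles."""
    return tuple(_BUILTIN_FILES)


def load_builtin(name: str) -> AthleteProfile:
    """Load a built-in reference profile by name (case/hyphen insensitive)."""
    key = name.strip().lower().replace("-", "_").replace(" ", "_")
    if key not in _BUILTIN_FILES:
        raise KeyError(
            f"unknown built-in profile {name!r}; available: {', '.join(_BUILTIN_FILES)}"
        )
    resource = importlib.resources.files("hiitsim.data") / _BUILTIN_FILES[key]
    return load_profile(yaml.safe_load(resource.read_text(encoding="utf-8")))


def reference_profiles() -> tuple[AthleteProfile, ...]:
    """The three built-in reference profiles, endurance-first ordering."""
    return tuple(load_builtin(n) for n in builtin_names())


def pmax(profile: AthleteProfile, duration: float) -> float:
    """Functional alias for :meth:`AthleteProfile.pmax`."""
    return profile.pmax(duration)


def _ols_work_fit(
    durations: Sequence[float], powers: Sequence[float], window: tuple[float, float]
) -> tuple[float, float]:
    t = np.asarray(durations, dtype=float)
    p = np.asarray(powers, dtype=float)
    lo, hi = window
    mask = (t >= lo) & (t <= hi)
    if int(mask.sum()) < 2:
        raise InsufficientDataError(
            f"need >=2 nodes in the {lo}-{hi} s window, found {int(mask.sum())}"
        )
    slope, intercept = np.polyfit(t[mask], p[mask] * t[mask], deg=1)
    return float(slope), float(intercept)


def estimate_cp_wprime(
    profile: AthleteProfile, window: tuple[float, float] = (120.0, 900.0)
) -> tuple[float, float]:
    """Estimate (CP, W') by the linear work-duration fit.

    Ordinary least squares of total work W = P·t against duration t over
    the profile nodes inside ``window`` (inclusive, default 2-15 min): the
    slope estimates CP and the intercept estimates W'.  This is the
    classical field method for the two-parameter critical-power model; it
    reproduces (CP, W') exactly when the in-window nodes follow the
    hyperbola P = W'/t + CP.
    """
    return _ols_work_fit(profile.durations, profile.powers, window)
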