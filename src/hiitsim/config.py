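"""Run configuration for the end-to-end grid experiment.

The defaults reproduce the full study configuration: the three built-in
reference profiles, both exhaustion models, the 15-300 s / 2-20 rep /
15-300 s grid with the [30 s, 90 min] total-duration filter, recovery at
50% of MAP, and 5 %MAP intensity bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import grid as grid_mod
from .profiles import AthleteProfile, builtin_names, load_builtin, load_profile
from .skiba import SessionPlan

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Everything needed to run and summarize one session grid."""

    profiles: tuple[str, ...] = field(default_factory=builtin_names)
    models: tuple[str, ...] = grid_mod.MODELS
    work_durations: tuple[float, ...] = grid_mod.DEFAULT_WORK_DURATIONS
    reps: tuple[int, ...] = grid_mod.DEFAULT_REPS
    rest_durations: tuple[float, ...] = grid_mod.DEFAULT_REST_DURATIONS
    min_total_s: float = grid_mod.DEFAULT_MIN_TOTAL_S
    max_total_s: float = grid_mod.DEFAULT_MAX_TOTAL_S
    rest_fraction: float = grid_mod.DEFAULT_REST_FRACTION
    intensity_bin_width: float = 5.0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        for model in self.models:
            if model not in grid_mod.MODELS:
                raise ValueError(
                    f"models: unknown model {model!r}; expected subset of {grid_mod.MODELS}"
                )
        if not 0 <= self.rest_fraction:
            raise ValueError(f"rest_fraction: must be >= 0, got {self.rest_fraction}")
        if not self.intensity_bin_width > 0:
            raise ValueError(
                f"intensity_bin_width: must be > 0, got {self.intensity_bin_width}"
            )
        if self.min_total_s > self.max_total_s:
            raise ValueError(
                f"min_total_s/max_total_s: empty filter [{self.min_total_s}, {self.max_total_s}]"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, Mapping):
            raise ValueError("config document must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config fields: {', '.join(sorted(unknown))}")
        doc = {
            k: tuple(v) if isinstance(v, (list, tuple)) else v for k, v in doc.items()
        }
        return cls(**doc)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["profiles"] = list(self.profiles)
        d["models"] = list(self.models)
        d["work_durations"] = list(self.work_durations)
        d["reps"] = list(self.reps)
        d["rest_durations"] = list(self.rest_durations)
        return d

    def resolve_profiles(self) -> list[AthleteProfile]:
        """Built-in names load from package data; anything else is a YAML path."""
        resolved = []
        for entry in self.profiles:
            key = str(entry).strip().lower().replace("-", "_").replace(" ", "_")
            if key in builtin_names():
                resolved.append(load_builtin(key))
            else:
                resolved.append(load_profile(Path(entry)))
        return resolved

    def plans(self) -> list[SessionPlan]:
        return grid_mod.generate_plans(
            work_durations=self.work_durations,
            reps=self.reps,
            rest_durations=self.rest_durations,
            min_total=self.min_total_s,
            max_total=self.max_total_s,
        )
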