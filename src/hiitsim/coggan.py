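"""Coggan training metrics and the Coggan-Modified exhaustion criterion.

Normalized Power (NP, written PN in parts of the cycling literature) is the
fourth-root of the mean fourth power of 30-s rolling-average power, meant to
weight a variable effort the way the physiological strain does:

    NP = ( mean_i( mean(P[i:i+30])^4 ) )^(1/4),   i = 0 .. T-30.

From NP the Intensity Factor IF = NP/FTP and the Training Stress Score
TSS = (NP/FTP)^2 * T/3600 follow, with FTP the best one-hour power and T the
session duration in seconds.  TSS is kept on this natural scale (a one-hour
effort at FTP scores 1.0); multiply by 100 for the conventional display
scale.

The Coggan model carries no exhaustion concept; the Coggan-Modified
criterion supplies one by requiring the session TSS to equal the maximal
TSS attainable over its duration, which reduces to

    NP(session) = Pmax(T),

the athlete's best mean power over the total session duration.  Because NP
is continuous and strictly increasing in the work power of an
all-out/recovery interval session, the work power satisfying the criterion
is found by root bracketing.  Internally the solver expands NP^4 as an exact
quartic polynomial in the work power (every 30-s window mean is affine in
it), which Brent's method then solves; tests confirm the root against the
direct 4-step NP computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .exceptions import (
    DurationOutOfRangeError,
    ModelDomainError,
    NoSolutionError,
    SeriesTooShortError,
)
from .profiles import AthleteProfile
from .skiba import SessionPlan

__all__ = [
    "WINDOW_S",
    "PowerSeries",
    "CogganMetrics",
    "build_power_series",
    "normalized_power",
    "intensity_factor",
    "tss",
    "tss_max",
    "session_metrics",
    "solve_exhaustion_power",
]

WINDOW_S = 30  # rolling-average window for NP, in 1-Hz samples


@dataclass(frozen=True)
class PowerSeries:
    """A 1-Hz mechanical power trace; at least 30 s so NP is computable."""

    samples: np.ndarray

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise ValueError("power series must be one-dimensional")
        if samples.size < WINDOW_S:
            raise SeriesTooShortError(
                f"series of {samples.size} s is shorter than the {WINDOW_S} s "
                "window required to compute Normalized Power"
            )
        if np.any(samples < 0):
            raise ValueError("power samples must be >= 0")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> int:
        return int(self.samples.size)

    @classmethod
    def from_csv(cls, path) -> "PowerSeries":
        frame = pd.read_csv(path)
        if "power_w" not in frame.columns:
            raise ValueError("power CSV must have a 'power_w' column")
        return cls(frame["power_w"].to_numpy(dtype=float))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"time_s": np.arange(1, self.duration + 1), "power_w": self.samples}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class CogganMetrics:
    """Session summary: Normalized Power, Intensity Factor, Training Stress Score."""

    pn: float
    if_: float
    tss: float


def build_power_series(plan: SessionPlan) -> PowerSeries:
    """Realize a session plan as its 1-Hz power trace.

    n_reps blocks at the work power interleaved with n_reps - 1 blocks at
    the rest power; durations must be whole seconds.
    """
    if plan.work_power is None:
        raise ValueError("plan.work_power is unset; solve or set it first")
    total = plan.total_duration
    if total < WINDOW_S:
        raise SeriesTooShortError(
            f"session of {total} s is shorter than the {WINDOW_S} s "
            "required to compute Normalized Power"
        )
    blocks = []
    for dur, power, _is_work in plan.segments():
        n = int(round(dur))
        if abs(dur - n) > 1e-9:
            raise ValueError(f"segment duration {dur} s is not a whole number of seconds")
        blocks.append(np.full(n, power, dtype=float))
    return PowerSeries(np.concatenate(blocks))


def _window_means(samples: np.ndarray) -> np.ndarray:
    """Means of every fully-contained 30-sample window at 1-sample step."""
    csum = np.concatenate([[0.0], np.cumsum(samples, dtype=float)])
    return (csum[WINDOW_S:] - csum[:-WINDOW_S]) / WINDOW_S


def normalized_power(series: PowerSeries | np.ndarray) -> float:
    """Normalized Power via the 4-step algorithm.

    (1) 30-s rolling-average windows at 1-s step, fully contained in the
    series; (2) each window mean to the fourth power; (3) mean of those;
    (4) fourth root.
    """
    samples = series.samples if isinstance(series, PowerSeries) else np.asarray(series, float)
    if samples.size < WINDOW_S:
        raise SeriesTooShortError(
            f"series of {samples.size} s is shorter than the {WINDOW_S} s window"
        )
    means = _window_means(samples)
    return float(np.mean(means**4) ** 0.25)


def intensity_factor(pn: float, ftp: float) -> float:
    """IF = NP/FTP."""
    if not ftp > 0:
        raise ModelDomainError(f"ftp must be positive, got {ftp}")
    return pn / ftp


def tss(duration: float, pn: float, ftp: float) -> float:
    """Training Stress Score (NP/FTP)^2 * T/3600; 1.0 = one hour at FTP."""
    if not duration > 0:
        raise ModelDomainError(f"duration must be positive, got {duration}")
    if not ftp > 0:
        raise ModelDomainError(f"ftp must be positive, got {ftp}")
    return (pn / ftp) ** 2 * duration / 3600.0


def tss_max(duration: float, pmax_t: float, ftp: float) -> float:
    """Largest TSS attainable over ``duration``: the all-out effort at Pmax(T)."""
    return tss(duration, pmax_t, ftp)


def session_metrics(series: PowerSeries, ftp: float) -> CogganMetrics:
    """NP, IF and TSS of a power series against a given FTP."""
    pn = normalized_power(series)
    return CogganMetrics(
        pn=pn, if_=intensity_factor(pn, ftp), tss=tss(series.duration, pn, ftp)
    )


def solve_exhaustion_power(
    plan: SessionPlan, profile: AthleteProfile, tol: float = 1e-3
) -> float:
    """Work power making the session NP equal Pmax over the session duration.

    The exhaustion condition NP = Pmax(T) is solved for the work power P by
    Brent's method on NP^4 - Pmax^4, with NP^4 expanded exactly as a quartic
    in P (each 30-s window mean is rest_power*(1-b) + b*P, b the window's
    work-time fraction).  ``tol`` bounds |NP(P*) - Pmax(T)| in watts.
    """
    total = plan.total_duration
    if total < WINDOW_S:
        raise SeriesTooShortError(
            f"session of {total} s is shorter than the {WINDOW_S} s "
            "required to compute Normalized Power"
        )
    if abs(total - round(total)) > 1e-9:
        raise ValueError(f"total duration {total} s is not a whole number of seconds")
    target = profile.pmax(total)  # raises DurationOutOfRangeError beyond the table
    if target <= plan.rest_power:
        raise NoSolutionError(
            f"Pmax({total:.0f} s) = {target:.1f} W does not exceed the rest power "
            f"{plan.rest_power} W; the session NP cannot reach the target"
        )

    # Work-time fraction of every 30-s window, from the work indicator trace.
    indicator = np.concatenate(
        [
            np.full(int(round(dur)), 1.0 if is_work else 0.0)
            for dur, _power, is_work in plan.with_work_power(1.0).segments()
        ]
    )
    rest_power = plan.rest_power
    b = _window_means(indicator)
    a = rest_power * (1.0 - b)
    # NP^4 = mean((a + b P)^4): exact quartic coefficients in P.
    coeffs = np.array(
        [
            np.mean(b**4),
            4.0 * np.mean(a * b**3),
            6.0 * np.mean(a**2 * b**2),
            4.0 * np.mean(a**3 * b),
            np.mean(a**4) - target**4,
        ]
    )

    def residual(power: float) -> float:
        return float(np.polyval(coeffs, power))

    lo = rest_power
    hi = 10.0 * profile.pmax(plan.work_duration)
    for _ in range(200):
        if residual(hi) >= 0:
            break
        hi *= 2.0
    else:
        raise NoSolutionError(f"no NP = Pmax root below {hi} W for plan {plan}")
    return float(brentq(residual, lo, hi, xtol=max(tol * 0.1, 1e-9)))
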