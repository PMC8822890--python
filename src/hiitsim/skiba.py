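"""Skiba W'-balance model: depletion, reconstitution, and the exhaustion solver.

The model tracks the remaining anaerobic work capacity W'_balance through an
interval session.  Riding above critical power drains the reserve linearly,

    W'(t_i) = W'(t_{i-1}) - (P_i - CP) * (t_i - t_{i-1}),          P_i >= CP,

while riding below CP refills the deficit exponentially toward the full
reserve W'_0, at a rate proportional to both (CP - P) and the expended
fraction of the reserve:

    W'(t_i) = W'_0 - [W'_0 - W'(t_{i-1})] * exp((P_i - CP) (t_i - t_{i-1}) / W'_0).

Exhaustion is declared when W'_balance reaches zero.

For an n-rep session of constant work power P (duration t_w) alternating
with constant recovery power P_r < CP (duration t_r), composing the two
updates gives a geometric recursion for the end-of-bout deficit, so the work
power that drives W'_balance to exactly zero at the end of the last work
bout has the closed form

    P* = CP + W'_0 * (1 - lam) / (t_w * (1 - lam^n)),
    lam = exp((P_r - CP) * t_r / W'_0),

which degenerates to the continuous critical-power relation
P* = CP + W'_0/(n t_w) as t_r -> 0 and to P* = CP + W'_0/t_w for n = 1.
A bisection search over the 1-Hz simulation is provided as an independent
route to the same power.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np
import pandas as pd

from .exceptions import ModelDomainError, NoSolutionError

__all__ = [
    "SessionPlan",
    "WPrimeTrajectory",
    "deplete_step",
    "recover_step",
    "simulate_wbal",
    "solve_exhaustion_power",
    "solve_exhaustion_power_bisect",
]


@dataclass(frozen=True)
class SessionPlan:
    """One HIIT configuration: n_reps work bouts split by n_reps-1 rest bouts.

    The session is the alternating sequence work, rest, ..., work — it ends
    on the last work bout, with no trailing rest, so
    ``total_duration = n_reps*work_duration + (n_reps-1)*rest_duration``.
    ``work_power`` may be left unset and filled in later by a solver.
    """

    n_reps: int
    work_duration: float
    rest_duration: float
    rest_power: float
    work_power: float | None = None

    def __post_init__(self) -> None:
        if int(self.n_reps) != self.n_reps or self.n_reps < 1:
            raise ValueError(f"n_reps must be an integer >= 1, got {self.n_reps}")
        if not self.work_duration > 0:
            raise ValueError(f"work_duration must be > 0, got {self.work_duration}")
        if self.rest_duration < 0:
            raise ValueError(f"rest_duration must be >= 0, got {self.rest_duration}")
        if self.rest_power < 0:
            raise ValueError(f"rest_power must be >= 0, got {self.rest_power}")

    @property
    def total_duration(self) -> float:
        return self.n_reps * self.work_duration + (self.n_reps - 1) * self.rest_duration

    @property
    def total_work_time(self) -> float:
        """Total time spent at the work intensity."""
        return self.n_reps * self.work_duration

    def with_work_power(self, power: float) -> "SessionPlan":
        return replace(self, work_power=float(power))

    def segments(self) -> Iterator[tuple[float, float, bool]]:
        """Yield (duration, power, is_work) segments in session order."""
        if self.work_power is None:
            raise ValueError("work_power is unset; solve or set it first")
        for rep in range(self.n_reps):
            yield self.work_duration, self.work_power, True
            if rep < self.n_reps - 1:
                yield self.rest_duration, self.rest_power, False


@dataclass
class WPrimeTrajectory:
    """W'-balance time series; stops at the first zero crossing if reached."""

    times: np.ndarray
    wbal: np.ndarray
    exhaustion_time: float | None = None

    @property
    def exhausted(self) -> bool:
        return self.exhaustion_time is not None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "wbal_j": self.wbal})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def deplete_step(wbal: float, power: float, cp: float, dt: float) -> float:
    """Linear W' drain over dt seconds at supra-CP power.

    May return a negative balance; callers detect exhaustion from the sign.
    """
    if power < cp:
        raise ModelDomainError(
            f"deplete_step requires power >= cp ({power} W < {cp} W); use recover_step"
        )
    if not dt > 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    return wbal - (power - cp) * dt


def recover_step(wbal: float, wprime: float, power: float, cp: float, dt: float) -> float:
    """Exponential W' refill over dt seconds at sub-CP power.

    The deficit (wprime - wbal) decays by exp((power - cp)·dt/wprime); the
    balance approaches but never exceeds the full reserve.
    """
    if power >= cp:
        raise ModelDomainError(
            f"recover_step requires power < cp ({power} W >= {cp} W); use deplete_step"
        )
    if not 0 <= wbal <= wprime:
        raise ValueError(f"wbal must lie in [0, wprime]=[0, {wprime}], got {wbal}")
    if not dt > 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    return wprime - (wprime - wbal) * math.exp((power - cp) * dt / wprime)


def _segment_balance(plan: SessionPlan, cp: float, wprime: float, dt: float | None):
    """W'-balance samples, not stopped at zero (recovery formula tolerates a
    negative running balance, which keeps the composition exact for solver
    probes above the true exhaustion power).

    With ``dt`` None only segment-boundary values are produced (segment-exact
    composition); otherwise samples every ``dt`` seconds, assuming segment
    durations are integer multiples of ``dt``.
    """
    times = [0.0]
    values = [wprime]
    t = 0.0
    w = wprime
    for dur, power, _is_work in plan.segments():
        if dt is None:
            ks = np.array([dur])
        else:
            n = int(round(dur / dt))
            ks = np.arange(1, n + 1) * dt
        if power >= cp:
            seg = w - (power - cp) * ks
        else:
            seg = wprime - (wprime - w) * np.exp((power - cp) * ks / wprime)
        times.extend((t + ks).tolist())
        values.extend(seg.tolist())
        t += dur
        w = float(seg[-1])
    return np.asarray(times), np.asarray(values)


def simulate_wbal(
    plan: SessionPlan, cp: float, wprime: float, dt: float = 1.0
) -> WPrimeTrajectory:
    """Simulate W'-balance through a session with ``work_power`` set.

    Alternates linear depletion and exponential reconstitution at ``dt``
    resolution.  The trajectory stops at the first zero crossing; the
    crossing time is located by linear interpolation inside the step (exact,
    since crossings can only occur during constant-power work segments).
    """
    if plan.work_power is None:
        raise ValueError("plan.work_power is unset; solve or set it first")
    if plan.n_reps > 1 and plan.rest_power >= cp:
        raise ModelDomainError(
            f"recovery undefined above CP: rest_power {plan.rest_power} W >= cp {cp} W"
        )
    if plan.work_power <= cp:
        raise ModelDomainError(
            f"work_power must exceed cp ({plan.work_power} W <= {cp} W)"
        )
    times, wbal = _segment_balance(plan, cp, wprime, dt)
    below = np.nonzero(wbal <= 0.0)[0]
    if below.size == 0:
        return WPrimeTrajectory(times=times, wbal=wbal, exhaustion_time=None)
    i = int(below[0])
    # Linear interpolation between the bracketing samples; exact because the
    # crossing happens while depleting linearly.
    t0, t1 = times[i - 1], times[i]
    w0, w1 = wbal[i - 1], wbal[i]
    te = t1 if w1 == 0.0 else t0 + (t1 - t0) * w0 / (w0 - w1)
    return WPrimeTrajectory(
        times=np.append(times[:i], te),
        wbal=np.append(wbal[:i], 0.0),
        exhaustion_time=float(te),
    )


def solve_exhaustion_power(plan: SessionPlan, cp: float, wprime: float) -> float:
    """Closed-form work power that depletes W' exactly at the last work bout's end."""
    if plan.n_reps > 1 and plan.rest_power >= cp:
        raise ModelDomainError(
            f"recovery undefined above CP: rest_power {plan.rest_power} W >= cp {cp} W"
        )
    n = int(plan.n_reps)
    x = (plan.rest_power - cp) * plan.rest_duration / wprime  # log of the deficit retention
    if n == 1 or x == 0.0:
        return cp + wprime / (n * plan.work_duration)
    # (1 - lam)/(1 - lam^n) written with expm1 for stability near lam = 1.
    return cp + wprime * math.expm1(x) / (plan.work_duration * math.expm1(n * x))


def solve_exhaustion_power_bisect(
    plan: SessionPlan,
    cp: float,
    wprime: float,
    tol: float = 1e-3,
    bracket: tuple[float, float] = None,
    dt: float | None = 1.0,
) -> float:
    """Bisection on the simulated end-of-session balance (independent of the
    closed form).

    The balance at the end of the last work bout is strictly decreasing in
    work power, so bisection on its sign converges to the exhaustion power.
    ``dt`` sets the simulation resolution (default 1 Hz); ``None`` uses the
    segment-exact composition.
    """
    if plan.n_reps > 1 and plan.rest_power >= cp:
        raise ModelDomainError(
            f"recovery undefined above CP: rest_power {plan.rest_power} W >= cp {cp} W"
        )

    def end_balance(power: float) -> float:
        _, wbal = _segment_balance(plan.with_work_power(power), cp, wprime, dt)
        return float(wbal[-1])

    lo, hi = bracket if bracket is not None else (cp + 1e-6, 1e4)
    if end_balance(lo) < 0 or end_balance(hi) > 0:
        raise NoSolutionError(
            f"exhaustion power not bracketed by [{lo}, {hi}] W for plan {plan}"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if end_balance(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
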