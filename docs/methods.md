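# Methods

## Scope and procedure

`hiitsim` asks a feasibility question of two HIIT prescription models: for
a given interval-session structure, what constant work power does the
model say is needed to reach exhaustion exactly at the end of the last
work interval — and is that power one the athlete can actually produce?
A session is classified *impossible* when the solved power strictly
exceeds the athlete's maximal mean power over the work-interval duration,
i.e. the model demands a personal best be beaten on every repetition.

The default experiment crosses work durations 15–300 s and rest durations
15–300 s (both 15-s steps) with 2–20 repetitions, keeps the combinations
whose total duration n·t_w + (n−1)·t_r lies in the inclusive interval
[30 s, 5400 s] — 6198 plans (the session ends on the final work bout; no
trailing rest) — and solves each plan under both models for three
built-in reference athletes whose power-duration curves are tabulated at
17 durations from 1 s to 4 h. The 30-s floor is the shortest series on
which Normalized Power is computable; 90 min is a practical ceiling for
interval sessions.

## Athlete profiles

A profile is a strictly monotone table of (duration, best mean mechanical
power) nodes plus the critical-power constants CP and W′, which are
treated as given inputs alongside the table. (The classical 2–15-min
linear work–duration fit is provided as `estimate_cp_wprime`; on the
built-in tables' sparse printed nodes it lands at a different point than
the quoted constants — e.g. ≈318 W / 16 kJ vs the Time-Trialist's
304 W / 21.5 kJ, which derive from a denser underlying curve — so the fit
is an estimator, not the source of the constants.)

Between nodes, power is interpolated **linearly in power versus
ln(duration)**; at the nodes the table is reproduced exactly, and the
curve is never extrapolated (out-of-range durations raise). Log-linear
interpolation is the minimal monotone scheme for a mean-maximal curve,
but it is also the dominant approximation in the package: a true
power-duration curve is typically convex in log-time, so the chord
overestimates power at off-node durations, which in turn undercounts
impossible sessions at the off-node work durations (75, 90, 105, 135,
150, 165, 210, 225, 255, 270, 285 s). This shifts the headline
percentages by up to roughly two percentage points for the
highest-endurance profile; the qualitative orderings are unaffected.

FTP is the curve's 60-min power and MAP its 5-min power, both in
mechanical watts; recovery intensity defaults to 0.5·MAP, a customary
active-recovery level. With the built-in profiles this is always below
CP, so recovery is always a reconstitution phase.

## Skiba solver

Composing the linear depletion and exponential reconstitution updates
over the alternating constant-power segments gives a geometric recursion
for the end-of-bout deficit, hence the closed form
P* = CP + W′₀(1−λ)/(t_w(1−λⁿ)) with λ = exp((P_r−CP)t_r/W′₀). The
implementation uses `expm1` so the λ→1 (vanishing rest) limit
P* → CP + W′₀/(n·t_w) is numerically stable; n = 1 reduces to the
continuous critical-power relation. An independent bisection over the
1-Hz W′-balance simulation (tolerance 10⁻³ W, bracket [CP + 10⁻⁶ W,
10⁴ W]) is kept as a cross-check and agrees with the closed form to
within 0.01 W on randomized plans. Segment updates are exact for
piecewise-constant power, so step size only affects sampling, not the
end-state. The simulated trajectory stops at the first zero crossing
(located by linear interpolation inside the step — exact, since crossings
happen during linear depletion); solver probes above the true exhaustion
power let the balance run negative internally rather than clamping, which
keeps the composition invertible.

## Coggan-Modified solver

NP follows the 4-step algorithm: 30-sample rolling means at 1-s step over
a 1-Hz trace, every window fully contained (T − 29 windows, no padding);
fourth power; mean; fourth root. TSS is kept on its natural scale
((NP/FTP)²·T/3600, so one hour at FTP scores 1.0); the CLI also prints
the ×100 display convention. The exhaustion condition NP = Pmax(T) is
solved for the work power P: every window mean is affine in P
(rest_power·(1−b) + b·P, with b the window's work-time fraction), so
NP⁴ − Pmax⁴ is an exact quartic polynomial in P whose coefficients are
computed once per plan; Brent's method then finds the root in
[rest_power, 10·Pmax(t_w)] (bracket doubled if needed). The root is
verified in tests against the direct NP computation on the realized
trace; the default tolerance bounds |NP(P*) − Pmax(T)| by 10⁻³ W.

One subtlety of fully-contained windowing: the window means under-weight
the first and last 29 samples, so NP can fall below the raw sample mean
when high power sits at the series edges. The invariant that always holds
— and the one the property tests assert — is NP ≥ mean of the window
means (power-mean inequality), with NP strictly above the sample mean for
interior-varying traces like the solved interval sessions.

## Classification and summaries

Impossibility uses a strict comparison, solved power > Pmax(t_w), with a
one-microwatt guard so a root-finder landing a rounding error above an
exactly attainable bound (the single-bout NP identity, where the ratio is
exactly 100%) stays "possible". Solver failures on pathological plans are
recorded as annotated rows rather than aborting a grid run. Summaries
report impossible percentages overall and within subsets by prescribed
intensity (%MAP, half-open bins of 5 %MAP by default — the bin width is a
package choice), work duration, total work time and rest duration. The
pipeline contains no randomness; re-runs are bit-identical.

## Synthetic profiles

The generator produces monotone power-duration curves from three dials —
MAP (5-min power, W), an endurance slope (% of MAP per log₁₀-decade of
duration, negative; flatter = more enduring) and a synthetic anaerobic
reserve W′ (J) — via a hyperbolic branch P = MAP + W′(1/t − 1/300) below
300 s and a log-linear branch P = MAP(1 + slope/100·log₁₀(t/300)) above,
continuous at the 300-s anchor. It is a deliberately simple surrogate,
not a physiological model: it exists so that profile validation, the
CP/W′ estimator (whose work fit below 300 s recovers the branch's
asymptote MAP − W′/300 and W′ exactly) and the endurance sweep can be
exercised over a controlled parameter space. Default sweep conditions
(MAP 390 W, W′ 25 kJ, slopes −14…−5 %/decade, 70 kg) sit in the range of
the built-in elite reference profiles. Passing sweeps show the *models'*
sensitivity to the curve shape — more endurance ⇒ more impossible
sessions — not anything about real athletes' physiology; the surrogate
has no basal-metabolism, efficiency or day-to-day variability structure.

## Problem sizes and runtime

The full default experiment (6198 plans × 3 profiles × 2 models) runs in
a few seconds: the Skiba side is closed-form and the Coggan side one
quartic root per session. The test suite's oracle-equivalence check uses
1000 randomized plans (1–8 reps, 10–240 s bouts) with a fixed seed
recorded in the test; the endurance sweep in the tests thins the grid to
30-s steps and every other repetition count (832 plans) purely to keep
the property check snappy.

## Known limitations

* Interpolation of the tabulated curves is the accuracy floor for any
  percentage tied to off-node work durations (see above); node-exact
  quantities are unaffected.
* The NP window alignment (fully-contained, 1-s step) is one of several
  defensible conventions; percentages shift slightly under others.
* Recovery above CP has no defined reconstitution in the W′-balance model
  and is rejected rather than modeled (it cannot occur at the default
  0.5·MAP recovery with the built-in profiles).
* The feasibility criterion only flags sessions that break the athlete's
  absolute power-duration limit; sessions that are merely implausible
  (yet below the limit) are not identified.
* Metabolic↔mechanical conversion (gross efficiency, basal rate) is out
  of scope; all powers are mechanical watts as a power meter reports.
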