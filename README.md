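# hiitsim

Can a training model prescribe a workout that is physically impossible?
`hiitsim` simulates High-Intensity Interval Training (HIIT) sessions in
cycling under the two models practitioners most commonly use to gauge
session difficulty — the **Skiba W′-balance model** and the **Coggan**
Normalized-Power framework extended with an exhaustion criterion
(**Coggan-Modified**) — and flags the prescriptions that would require an
athlete to beat their own personal best on every work interval.

It is aimed at exercise physiologists, sport scientists and coaching-tool
developers who want to probe where these models' assumptions break down
before trusting them for prescription in the severe and extreme intensity
domains.

## The models

**Skiba W′-balance.** The two-parameter critical-power model writes the
power-duration relationship as P = W′/t_lim + CP: CP (W) is the highest
sustainable power, W′ (J) the finite work capacity above it. Riding above
CP drains the balance linearly,

```
W′(tᵢ) = W′(tᵢ₋₁) − (Pᵢ − CP)·(tᵢ − tᵢ₋₁),
```

riding below CP refills the deficit exponentially toward the full reserve
W′₀,

```
W′(tᵢ) = W′₀ − [W′₀ − W′(tᵢ₋₁)]·exp((Pᵢ − CP)·(tᵢ − tᵢ₋₁)/W′₀),
```

and exhaustion is declared when W′ = 0. For an n-rep session (work
duration t_w, recovery power P_r < CP for t_r) the work power that
depletes W′ exactly at the end of the last interval has the closed form

```
P* = CP + W′₀·(1 − λ) / (t_w·(1 − λⁿ)),    λ = exp((P_r − CP)·t_r/W′₀).
```

**Coggan-Modified.** Normalized Power is the fourth-root of the mean
fourth power of 30-s rolling-average power; IF = NP/FTP and
TSS = (NP/FTP)²·T/3600 (natural scale: one hour at FTP ⇒ TSS = 1).
Equating the session TSS with the maximal TSS attainable over its
duration T yields the exhaustion condition **NP = Pmax(T)** — the session's
NP must equal the athlete's best mean power over T — which `hiitsim`
solves for the work power by root bracketing (NP is strictly increasing
in it).

**Feasibility.** A session is *impossible* when the solved work power
strictly exceeds Pmax(work-interval duration). The default experiment
sweeps work and rest durations 15–300 s (15-s steps) and 2–20
repetitions, keeps the 6198 configurations whose total duration
n·t_w + (n−1)·t_r falls in [30 s, 90 min], sets recovery at 50% of MAP
(best 5-min power), and classifies every session for three built-in
reference athletes — a Time-Trialist, an All-Rounder and a Sprinter —
whose tabulated power-duration curves span the endurance/anaerobic-reserve
trade-off.

## Worked example

```
$ hiitsim profiles list
time_trialist: Time-Trialist, CP 304 W, W' 21.5 kJ, FTP 281 W, MAP 382 W
all_rounder: All-Rounder, CP 293 W, W' 27.1 kJ, FTP 264 W, MAP 391 W
sprinter: Sprinter, CP 259 W, W' 32.3 kJ, FTP 227 W, MAP 375 W

$ hiitsim wbal --profile time_trialist --reps 2 --work 15 --rest 300 --out wbal.csv
solved exhaustion work power: 1491.9 W
exhaustion at t = 330.0 s
wrote wbal.csv
```

Two 15-s intervals with 5 min of recovery at 191 W: to drain the
Time-Trialist's 21.5 kJ reserve by the end of the second interval, the
Skiba model demands 1492 W — but this athlete's best 15-s power is 777 W.
The same session through the library, under both models:

```python
from hiitsim import load_builtin, SessionPlan, classify_session

tt = load_builtin("time_trialist")
for model in ("skiba", "coggan_modified"):
    r = classify_session(SessionPlan(2, 15, 300, 0), tt, model)
    print(f"{model}: solved {r.solved_power:.0f} W vs Pmax(15 s) {r.pmax_work:.0f} W "
          f"-> ratio {r.ratio:.0f}% {'IMPOSSIBLE' if r.impossible else 'possible'}")
```

```
skiba: solved 1492 W vs Pmax(15 s) 777 W -> ratio 192% IMPOSSIBLE
coggan_modified: solved 1610 W vs Pmax(15 s) 777 W -> ratio 207% IMPOSSIBLE
```

`hiitsim grid` runs the full experiment (session-level CSV, per-parameter
summary CSVs and a run manifest), `hiitsim report sessions.csv` prints the
impossible-session percentages per model and profile, and `hiitsim np`
computes NP/IF/TSS for any 1-Hz power CSV.

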