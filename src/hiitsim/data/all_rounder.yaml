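# Fictitious elite cyclist: baseline profile.
name: All-Rounder
body_mass_kg: 70
cp_w: 293
wprime_j: 27100
nodes:
  - {duration_s: 1, power_w: 1115}
  - {duration_s: 15, power_w: 876}
  - {duration_s: 30, power_w: 719}
  - {duration_s: 45, power_w: 623}
  - {duration_s: 60, power_w: 561}
  - {duration_s: 120, power_w: 454}
  - {duration_s: 180, power_w: 419}
  - {duration_s: 240, power_w: 402}
  - {duration_s: 300, power_w: 391}
  - {duration_s: 600, power_w: 341}
  - {duration_s: 1200, power_w: 307}
  - {duration_s: 1800, power_w: 290}
  - {duration_s: 2700, power_w: 274}
  - {duration_s: 3600, power_w: 264}
  - {duration_s: 5400, power_w: 249}
  - {duration_s: 7200, power_w: 239}
  - {duration_s: 14400, power_w: 214}
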