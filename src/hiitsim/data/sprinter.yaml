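# Fictitious elite cyclist: high anaerobic reserve, low endurance.
name: Sprinter
body_mass_kg: 70
cp_w: 259
wprime_j: 32300
nodes:
  - {duration_s: 1, power_w: 1251}
  - {duration_s: 15, power_w: 968}
  - {duration_s: 30, power_w: 782}
  - {duration_s: 45, power_w: 665}
  - {duration_s: 60, power_w: 589}
  - {duration_s: 120, power_w: 457}
  - {duration_s: 180, power_w: 411}
  - {duration_s: 240, power_w: 389}
  - {duration_s: 300, power_w: 375}
  - {duration_s: 600, power_w: 317}
  - {duration_s: 1200, power_w: 276}
  - {duration_s: 1800, power_w: 257}
  - {duration_s: 2700, power_w: 239}
  - {duration_s: 3600, power_w: 227}
  - {duration_s: 5400, power_w: 211}
  - {duration_s: 7200, power_w: 199}
  - {duration_s: 14400, power_w: 172}
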