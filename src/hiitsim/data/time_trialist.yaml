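# Fictitious elite cyclist: high endurance, low anaerobic reserve.
name: Time-Trialist
body_mass_kg: 70
cp_w: 304
wprime_j: 21500
nodes:
  - {duration_s: 1, power_w: 978}
  - {duration_s: 15, power_w: 777}
  - {duration_s: 30, power_w: 647}
  - {duration_s: 45, power_w: 567}
  - {duration_s: 60, power_w: 516}
  - {duration_s: 120, power_w: 431}
  - {duration_s: 180, power_w: 403}
  - {duration_s: 240, power_w: 390}
  - {duration_s: 300, power_w: 382}
  - {duration_s: 600, power_w: 342}
  - {duration_s: 1200, power_w: 315}
  - {duration_s: 1800, power_w: 301}
  - {duration_s: 2700, power_w: 289}
  - {duration_s: 3600, power_w: 281}
  - {duration_s: 5400, power_w: 269}
  - {duration_s: 7200, power_w: 261}
  - {duration_s: 14400, power_w: 241}
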