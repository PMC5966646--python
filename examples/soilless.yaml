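# Soilless (hydroponic) scenario: irrigation water at 96.1 mg/L Si(OH)4
# (= 28 mg/L elemental Si), cool 20 degC season.
mode: soilless
si_water: 96.1
environment:
  days: 119
  par_day: 400.0
  co2: 400.0
  tair_day: 20.0
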