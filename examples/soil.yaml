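# Reference soil-mode scenario: pH 7, OM 6%, soil 25 degC, irrigation water
# at 5 mg/L Si(OH)4, PAR 400 umol/m2/s for 12 h/day, CO2 400 ppm, air 30 degC.
mode: soil
si_water: 5.0
soil:
  ph: 7.0
  om: 6.0
  temperature: 25.0
environment:
  days: 119
  par_day: 400.0
  co2: 400.0
  tair_day: 30.0
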