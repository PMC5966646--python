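# silisim

A simulator of silicon bioavailability in soil, transpiration-driven Si
uptake, and accumulation/allocation in greenhouse tomato, for both soil and
soilless (hydroponic) cultivation.

The model composes:

- **Chemistry** (`silisim.chem`) — silicate species conversions (Si,
  Si(OH)₄, SiO₂, Na₂SiO₃; mM ↔ mg L⁻¹) conserving moles of Si, plus
  solubility/polymerization classification of orthosilicic acid (soluble
  < 1.8 mM, polymerizing ≥ 2.0 mM).
- **Soil availability** (`silisim.soil`) — bioavailable Si(OH)₄ in soil
  pore water from a cubic temperature response, a Michaelis–Menten
  organic-matter response (Km = 2.5 % w/w), and a cubic pH response,
  scaling the gap between the irrigation-water floor and the 192.18 mg L⁻¹
  polymerization ceiling; per-area availability via the profile's water
  volume (default 30 cm × 25 % w/w × 1200 kg m⁻³ = 90 L m⁻²). The cubics
  are clamped to physical ranges (they go negative outside ~8.6–31.5 °C and
  above pH ~9.1, and slightly exceed 1 near pH 6.8).
- **Crop growth** (`silisim.growth`) — transpiration linear in dry biomass
  (`rate = biomass × 8.5714 / 10279801` L m⁻² s⁻¹) and a pluggable
  `GrowthDriver`; the default reduced canopy driver (light-limited growth ×
  CO₂ saturation × temperature suitability × canopy interception × logistic
  ceiling) is calibrated so the reference scenario (PAR 400 µmol m⁻² s⁻¹
  for 12 h/day, CO₂ 400 ppm, 30 °C, 3 plants m⁻²) ends the 119-day season
  at ≈1370 g dry mass per plant.
- **Si uptake** (`silisim.uptake`) — uptake = concentration × transpired
  volume × SiSi, booked as SiO₂ mass against a running cap of 1 % of dry
  biomass, and allocated to organs by transpiration share (leaf 90 %, stem
  5 %, fruit 2.5 %, root 2.5 %).
- **Simulator** (`silisim.sim`) — explicit-Euler season runs (default
  dt = 1800 s) in `soil` mode (source = soil availability, non-depleting)
  or `soilless` mode (source = irrigation-water Si(OH)₄), plus cartesian
  scenario sweeps.
- **Environment generator** (`silisim.envgen`) — square-wave PAR
  photoperiods, day/night temperatures, constant CO₂, optional seeded
  noise; or read your own CSV (`time_s, par, tair_c, co2_ppm`).

The model is valid for unstressed crops only: salinity, drought, or
pathogen stress reduce real biomass below the simulated value and lead to
overestimated Si uptake.

## Command line

```sh
# unit/species conversions
silisim convert 1.8 mM "Si(OH)4" --json
silisim convert 28 mg/L Si --to-species Na2SiO3

# soil availability (point and pH x OM grid)
silisim availability --temp 25 --ph 7 --om 6 --si-water 5
silisim availability-grid --temp 15 --temp 25 --si-water 5 --out grids/

# synthetic environment CSV
silisim make-env --days 119 --tair-day 30 --out env.csv

# season simulation and scenario sweep
silisim simulate --config examples/soil.yaml --out run/
silisim grid --config examples/soilless.yaml --axis si_water=0:96:5 --out sweep/
```

A minimal config (YAML or JSON):

```yaml
mode: soil            # or: soilless
si_water: 5.0         # mg/L Si(OH)4 in irrigation water
soil: {ph: 7.0, om: 6.0, temperature: 25.0}
environment: {days: 119, par_day: 400, co2: 400, tair_day: 30}
```

Every file-producing run writes a `manifest.json` (version, config
snapshot, input digests, outputs, wall time) beside its outputs. Exit
codes: 0 success, 2 validation error, 1 runtime error.

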