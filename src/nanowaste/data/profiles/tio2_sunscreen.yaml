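# Nano-TiO2 in sunscreen lotion, assessed for 2011.
# Production derives from the 2008 suncare market: 547e6 units, 65.4 % of
# which were sun-protection items, at 200 g per unit (71.5e3 Mg at 3 s.f.).
product_id: tio2_sunscreen
enm_type: TiO2
assessment_year: 2011
x_production:
  value: 71.5e+3
  unit: Mg/year
  sources: [Datamonitor 2009]
production:
  basis: market_units
  reference_year: 2008
  market_units: 547.0e+6
  sector_fraction: 0.654
  unit_mass: {value: 200, unit: g}
  sources: [Datamonitor 2009, Mueller and Nowack 2008]
retention_time_years: 3
F_pen:
  value: 0.1
  sources: [Boxall et al. 2007]
F_eol:
  value: [0.1, 0.2]
  sources: [estimated leftover lotion in the flacon]
C_NM:
  value: [2, 10]
  unit: percent
  sources: [Mueller and Nowack 2008, Boxall et al. 2007, Gottschalk et al. 2010]
F_NM:
  value: 1.0
  sources: [leftover lotion retains its full TiO2 load]
matrix:
  - material: Lotion cream
    state: liquid
    nanostructure: suspended_in_liquid
  - material: Plastic flacon
    state: solid
    nanostructure: surface_bound
treatment_shares:
  LF: 1.0
exposure_factors:
  amount_on_market: medium
  emission_magnitude: medium
  receptor_proximity: low
  duration: high
  notes: >
    Leftover lotion in landfilled flacons releases TiO2 into leachate and,
    by sorption, soil. Human proximity is indirect (water and food);
    metal-oxide release from a landfill body continues for decades.
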