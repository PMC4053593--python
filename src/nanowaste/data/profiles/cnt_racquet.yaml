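# Carbon nanotubes in tennis racquets, assessed for 2011.
# Production is the 2006 carbon-fibre tonnage for racquet manufacture; the
# market has been flat, so a point retention time of 5 years stands in for
# the 2-6 year lifespan range (kept below for documentation).
product_id: cnt_racquet
enm_type: CNT
assessment_year: 2011
x_production:
  value: 1650
  unit: Mg/year
  sources: [Compositesworld 2006]
production:
  basis: production_mass
  reference_year: 2006
  value: 1650
  unit: Mg/year
  annual_growth: 0.0
  sources: [Compositesworld 2006]
retention_time_years: 5
retention_time_range: [2, 6]
F_pen:
  value: [0.2, 0.5]
  sources: [estimated market penetration of nano-enabled racquets]
F_eol:
  value: [0.95, 1.0]
  sources: [Gottschalk et al. 2010, Meyer et al. 2011, Franco et al. 2007]
C_NM:
  value: 1.49
  unit: g/kg
  sources: [Nanoledge 2007]
F_NM:
  value: 1.0
  sources: [Franco et al. 2007, Meyer et al. 2011]
matrix:
  - material: Carbon-fibre/graphite composite
    state: solid
    nanostructure: suspended_in_solid
treatment_shares:
  IN: 1.0
controls:
  IN:
    name: state-of-the-art flue gas cleaning
    effectiveness: high
exposure_factors:
  amount_on_market: low
  emission_magnitude: low
  receptor_proximity: medium
  duration: low
  notes: >
    Combustion above 1000 C oxidises both the graphite matrix and the CNTs;
    state-of-the-art flue gas cleaning removes most non-combusted CNTs, so
    only minor amounts reach the air near the (urban) incinerator.
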