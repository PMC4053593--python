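# Nanosilver in polyester textile, assessed for 2011.
# Production figure is the published 2005 polyester output (back-cast basis:
# 24.5e6 Mg in 2004 grown at 7.2 %/year, rounded to 3 s.f. as printed).
product_id: nanosilver_textile
enm_type: Ag
assessment_year: 2011
x_production:
  value: 26.3e+6
  unit: Mg/year
  sources: [Aizenshtein 2006]
production:
  basis: production_mass
  reference_year: 2004
  value: 24.5e+6
  unit: Mg/year
  annual_growth: 0.072
  sources: [Aizenshtein 2006]
retention_time_years: 6
F_pen:
  value: 0.001
  sources: [Conde 2009]
F_eol:
  value: 0.9
  sources: [Meyer et al. 2011, Gottschalk et al. 2010]
C_NM:
  value: [100, 240]
  unit: mg/kg
  sources: [Mueller and Nowack 2008, Walser et al. 2011]
# Upstream (manufacturing-use) concentration range; the 238.5 g/Mg upper
# endpoint is the body-text figure behind the 2.6-6.3 Mg usage estimate.
C_NM_manufacture:
  value: [100, 238.5]
  unit: g/Mg
  sources: [Mueller and Nowack 2008, Walser et al. 2011]
F_NM:
  value: [0.33, 0.99]
  sources: [Gottschalk et al. 2010, Walser et al. 2011]
matrix:
  - material: Cotton/polyester textile
    state: solid
    nanostructure: surface_bound
treatment_shares:
  RC: 0.05
  IN: 0.95
controls:
  RC:
    name: ventilation and air filtration
    effectiveness: partial
exposure_factors:
  amount_on_market: high
  emission_magnitude: low
  receptor_proximity: high
  duration: medium
  notes: >
    Recycling (shredding into insulation material) liberates surface-bound
    nanosilver into the air of facilities typically sited in populated areas;
    hall filtration is not fully effective at the nanoscale. Significant
    market growth is expected but does not enter the rating.
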