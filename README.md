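# nanowaste

Environmental exposure assessment for engineered nanomaterials (ENMs) in
solid waste.

Consumer nanoproducts — nanosilver T-shirts, TiO₂ sunscreens, carbon-nanotube
sports gear — eventually enter ordinary waste streams, where nothing flags
them as nano-enabled. `nanowaste` is a library and command-line tool for waste
engineers and environmental risk assessors who need a first, transparent
estimate of how much ENM mass enters a waste management system and where it
can escape. It implements a five-step assessment:

1. **Quantification** by market product analysis. The nanowaste mass entering
   the waste stream in year *t* for product *p* is

   *X*<sub>t,p</sub> = *x*<sub>t−rt,p</sub> · *F*<sub>pen,p</sub> · *F*<sub>eol,p</sub>

   and the ENM mass it contains is

   *NM*<sub>t,p</sub> = *X*<sub>t,p</sub> · *C*<sub>NM,p</sub> · *F*<sub>NM,p</sub>

   where *x*<sub>t−rt,p</sub> is the production put on the market *rt*
   (retention-time) years earlier, *F*<sub>pen</sub> the market penetration of
   the nano-enabled variant, *F*<sub>eol</sub> the fraction of virgin product
   reaching end of life, *C*<sub>NM</sub> the ENM concentration and
   *F*<sub>NM</sub> the ENM fraction surviving the use phase. Every parameter
   is a `[low, high]` interval with literature provenance; chains are evaluated
   with endpoint interval arithmetic, optionally refined by seeded Monte-Carlo
   sampling. Manufacturing by-product masses are estimated from packaged
   generation-rate tables (waste mass per mass of ENM produced).
2. **Matrix and treatment lookup** in a packaged, extensible knowledge base of
   end-of-life nanoproducts (waste fraction entered; reuse, recycling,
   biotreatment, use-on-land, incineration, landfill), plus the definitional
   rule that separates *nanowaste* (collectable material that is or contains
   ENMs) from *nanopollution* (ENMs released beyond collection, e.g. washed
   into wastewater).
3. **Nanostructure release-proneness**: surface films, surface-bound ENMs,
   suspensions in liquids or solids and enclosed airborne ENMs are prone to
   release; material nanostructured in the bulk is not.
4. **Fate routing**: each treatment maps to the transformation processes it
   exerts (combustion, mechanical abrasion, dissolution/precipitation, …) and
   to air/water/soil release pathways qualified as primary, indirect, residual
   stream or negligible; control measures such as flue-gas cleaning downgrade
   the primary pathway.
5. **Exposure rating**: four ordinal factors (amount on market, post-control
   emission magnitude, receptor proximity, duration) combine by a
   precautionary rounded mean into a low/medium/high rating that always
   carries its factor trace.

## Worked example

Three fully parameterised case-study profiles ship with the package. Assessing
the nanosilver-textile case:

```sh
nanowaste assess $(python -c "from importlib import resources; \
  print(resources.files('nanowaste.data') / 'profiles/nanosilver_textile.yaml')")
```

prints

```
Assessment of nanosilver_textile (Ag), year 2011
  nanowaste mass X:  23.7 × 10^3 Mg/year
  contained ENM NM:  0.781-5.62 Mg/year
  IN: 22.5 × 10^3 Mg/year  [processes: combustion; release: air=primary, soil=residual_stream]
  RC: 1180 Mg/year  [processes: abrasion_mechanical_erosion; release: air=primary, soil=indirect, water=indirect]
  exposure: MEDIUM (mean 2.25; amount=high, emission=low, proximity=high, duration=medium)
  config 317317bac797bb6c, nanowaste 0.1.0
```

Reading: of 26.3 × 10⁶ Mg of polyester produced in 2005, 0.1 % was
nano-enabled and 90 % survives the use phase, so 23.7 × 10³ Mg of nanosilver
textiles reached the 2011 waste stream, containing 0.78–5.6 Mg of nanosilver
(100–240 mg/kg, of which 33–99 % survives washing). The stream splits 5 %
recycling / 95 % incineration; shredding during recycling liberates
surface-bound silver to air (filtration is only partially effective), which,
with a large market in populated areas, rates the potential exposure
**medium**. The same pipeline is available from Python:

```python
import nanowaste as nw
report = nw.assess(nw.packaged_profile("cnt_racquet"))
print(report.quantification.enm_mass)   # 0.467-1.229 Mg/year of CNT
print(report.exposure.level)            # ExposureLevel.LOW
```

Write your own product as a small YAML profile (keys `x_production`,
`retention_time_years`, `F_pen`, `F_eol`, `C_NM`, `F_NM`, `matrix`,
`treatment_shares`, `exposure_factors`) and run `nanowaste validate`,
`quantify`, `fate` or `assess` on it; `nanowaste fixtures --seed N` generates
synthetic schema-valid profiles for testing.

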