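# Methods

## Model

`nanowaste` estimates the flow of engineered nanomaterials (ENMs) through a
solid-waste management system by market product analysis. For a nanoproduct
*p* assessed in year *t*:

```
X_t,p  = x_{t-rt,p} · F_pen,p · F_eol,p        [Mg/year]
NM_t,p = X_t,p · C_NM,p · F_NM,p               [Mg/year]
```

`x` is the production put on the market `rt` years earlier (the retention
time, i.e. the use-phase duration), `F_pen` the market share of the
nano-enabled variant, `F_eol` the fraction of virgin product mass reaching
end of life, `C_NM` the ENM concentration in the product, and `F_NM` the
fraction of the initially contained ENM still present at end of life after
use-phase losses (washing, wear). The nanowaste mass `X` then splits across
the local treatment mix (e.g. 5 % recycling / 95 % incineration); each
treatment exerts a characteristic subset of the eight transformation
processes (photochemical transformation, oxidation, reduction,
dissolution/precipitation, adsorption/desorption, combustion,
bio-transformation/biodegradation, mechanical abrasion) and releases ENMs to
air, water and/or soil along qualitatively weighted pathways. A final ordinal
rubric rates potential exposure low/medium/high.

Key assumptions:

* **Nonnegative product chains.** All quantities are masses, counts or
  fractions; negative inputs are rejected, never clamped. Because every
  factor is nonnegative, the interval product attains its extrema at the
  paired endpoints, so the `[low, high]` envelope of a chain is exactly the
  product of the endpoint envelopes.
* **Independent parameters.** Envelopes (and the optional Monte-Carlo
  refinement) treat parameters as independent; correlated sampling is out of
  scope.
* **Point retention time.** Where a lifespan is only known as a range, a
  single representative `rt` selects the production year; the range is stored
  for documentation but does not enter the arithmetic, because the production
  series are too flat (or too coarsely known) for the distinction to matter
  at the reported precision.
* **Qualitative fate.** No quantitative transfer coefficients are applied to
  compartments — the routing layer is a structured qualitative statement
  (primary / indirect / residual-stream / negligible), not a mass balance.

## Units and numerical choices

The unit registry is closed and hand-defined: masses (Mg, kg, g, mg), an
annual mass rate (Mg/year), market counts, mass-per-mass concentrations
(mg/kg, g/kg, kg/Mg, g/Mg, percent, g/g) and one volume-per-mass by-product
rate (L/g). Only these units occur in nanowaste inventories, so a general
dimensional-algebra engine would add failure modes without adding reach.
Concentrations normalise internally to a dimensionless g/g mass fraction, so
a mass×concentration product keeps the mass unit. Conversion round-trips are
identities to 1 part in 10¹²  (property-tested).

Full precision is carried end to end; rounding happens only in the reporting
layer. The default display is 3 significant figures (half rounded away from
zero), with engineering notation from 10⁴ upward ("23.7 × 10^3") matching
inventory-table style. A per-cell truncate-to-integer mode exists because
published tables occasionally truncate rather than round (313.5 → "313");
it is an explicit flag, never a global default.

Monte-Carlo propagation samples each interval independently and uniformly —
the literature supplies ranges with no distributional shape, and uniform is
the maximum-entropy choice on a bounded interval. Seeds are explicit function
arguments everywhere (no global RNG state); for fixed seed the summary is
bit-reproducible. For monotone nonnegative chains every sample lies inside
the analytic envelope, which the tests verify together with convergence of
the sample extrema toward the envelope endpoints as n grows.

## Case-study parameterisation

The packaged profiles carry the published inventory values, intervals spanning
all cited sources where sources disagree:

| | nanosilver textile | TiO₂ sunscreen | CNT racquet |
|---|---|---|---|
| x (Mg/year) | 26.3 × 10⁶ (2005) | 71.5 × 10³ (2008) | 1 650 (2006) |
| rt (years) | 6 | 3 | 5 (range 2–6) |
| F_pen | 0.001 | 0.1 | 0.2–0.5 |
| F_eol | 0.9 | 0.1–0.2 | 0.95–1 |
| C_NM | 100–240 mg/kg | 2–10 % | 1.49 g/kg |
| F_NM | 0.33–0.99 | 1 | 1 |

Two derivations feed the `x` inputs and are reproduced by the production
helpers: the 2005 polyester figure is the 2004 output (24.5 × 10⁶ Mg) grown
at 7.2 %/year, and the sunscreen mass converts 547 × 10⁶ market units
(65.4 % sun protection, 200 g each) to 71 547.6 Mg. In both cases the chain
input is the 3-significant-figure production figure, as inventory tables
print it — compounding the unrounded 26.264 × 10⁶ Mg forward would shift the
textile result from 23.7 × 10³ to 23.6 × 10³ Mg, i.e. the published chains
round production before applying the end-of-life factors, and the profiles
follow that convention. The textile `F_NM` envelope spans both cited sources
(0.33 from one, 0.55–0.99 from another); the separate manufacturing-use
concentration (100–238.5 g/Mg) feeds only the upstream usage estimate
(2.6–6.3 Mg of nanosilver), not the waste chain.

## Fate-routing defaults

The treatment→process and treatment→(compartment, qualifier) tables ship as
CSV data and are overridable per scenario, since routing depends on the local
waste management system. Defaults: recycling releases primarily to air
(shredding dust) with indirect water/soil via deposition; landfill primarily
to water (leachate) with indirect soil binding; incineration primarily to air
plus a residual stream (bottom ash); biotreatment and use-on-land primarily
to soil; collection/storage to air. Reuse asserts no transformation and no
release — no reuse release pathway is documented. Two qualitative modifiers:

* A nanostructure that is not release-prone (nanostructured in the bulk)
  downgrades every pathway to negligible. This is the deliberate reading of
  the release-proneness categorisation: bulk nanostructure is the one
  location class absent from the prone-to-release list. Products with bulk
  nanostructure still appear in the knowledge base with treatments attached,
  so the downgrade is prominent in the route's notes rather than silent.
* High-effectiveness controls (state-of-the-art flue-gas cleaning) downgrade
  the primary pathway to negligible. Partial controls (ordinary hall
  filtration, not fully effective against nanoscale particles) leave
  qualifiers unchanged and are recorded for the exposure step. The qualifier
  scale has no "minor" grade, so "efficient removal, only minor emission"
  maps to negligible — the least severe grade — and controls can never
  increase severity (exhaustively verified).

Reported incineration removal efficiencies for nanoparticles conflict
(near-100 % down to below 50 % for the smallest sizes), so control
effectiveness is a user-set ordinal input, not a built-in constant.

## Exposure rubric

The published case ratings are narrative; the package makes them computable
with a deliberately simple rule: map low/medium/high to 1/2/3 for the four
factors (amount on market, post-control emission magnitude, receptor
proximity, duration — frequency is folded into duration since treatment
plants operate continuously), average, and round half-values *up*
(precautionary). The packaged factor sets — textile (high, low, high,
medium), sunscreen (medium, medium, low, high), racquet (low, low, medium,
low) — are calibrated readings of the three case narratives and reproduce
their ratings (medium, medium, low). Expected market growth is noted in the
narrative but excluded from scoring: the rating describes the assessed year,
not a forecast. Both the rule and the factor sets are data; every rating
carries its factor trace so users can substitute their own rubric and audit
any rating.

## Synthetic fixtures

`generate_fixtures` emulates the *structure* of real product profiles —
sub-unit-interval fractions, mg/kg concentrations over four decades,
normalised treatment shares, valid enum draws — under a fixed seed, and every
generated profile passes the loader's schema validation. It does not emulate
real parameter correlations (e.g. high-penetration products tending to low
concentrations) or the provenance structure of real inventories; passing
property tests on fixtures therefore demonstrates schema closure, arithmetic
invariants (monotonicity, NM ≤ X × peak concentration) and pipeline
robustness, not the realism of any particular mass estimate.

## Problem sizes

Everything in this package is desk-scale: each case study is a product of at
most five intervals. The test suite uses 10⁵–2×10⁵ Monte-Carlo samples for
envelope-containment checks and 1 000 random interval pairs against a
100×100 grid oracle; the acceptance script uses 10⁴ samples for its seeded
containment check. These sizes put the stochastic checks' resolution well
below the printed precision of the reproduced figures.

## Known limitations

* Global, single-year snapshots; no stock-and-flow dynamics, no regional
  disaggregation, no forecasting beyond compound growth.
* Release routing is qualitative; residual streams (bottom ash, leachate
  sludge, digestate) are flagged, not quantified.
* The exposure rubric is ordinal and coarse by design; it identifies
  hotspots, it does not predict concentrations (no PEC, no dose–response,
  no risk characterisation).
* Interval envelopes treat worst cases as co-occurring; the Monte-Carlo
  refinement narrows this conservatism but inherits the independence and
  uniformity assumptions.
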