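# Methods

## Model

The package implements the IPCC Tier 1 soil-carbon inventory method for the
0–30 cm layer. Each land stratum carries a climate zone, a soil class and a
management state (land use, tillage, carbon-input level) at each inventory
date. The equilibrium stock under a management state is the product

    SOC = SOC_ref(climate, soil) · F_LU(land use, climate)
          · F_MG(tillage, climate) · F_I(input, climate)

and a management change moves the stock linearly to its new equilibrium over
the horizon `D` (default 20 years, the Tier 1 equilibration time), giving an
annual rate `(SOC_new − SOC_old) / D` in Mg C ha⁻¹ yr⁻¹. The scenario
changes exactly one thing: every convertible cropland stratum's 1997 tillage
is replaced by NT in 2017, holding land use, rotation and input level fixed.

**Inventory chaining.** Each inventory's end state is assumed fully
equilibrated by the next inventory date (the 1997 opening stock equals the
1982 inventory's closing stock). The NT-conversion rate therefore depends
only on the 1997 state and the NT end state; the 1982 state matters only for
sequence labelling and composition. The first inventory interval is 15 years
while `D = 20`; full equilibration over it is an explicit assumption of this
implementation, consistent with the zero rows for `…NTNT` sequences (land
already at the NT equilibrium gains nothing more).

**Eligibility.** A stratum is convertible iff its 1997 land use is cropland
and its 1997 tillage is CT or RT. Set-aside/CRP and perennial (hay, pasture)
land in 1997 is excluded with an explicit flag; already-NT land is
classified (`CTNTNT`, `RTNTNT`, `NCNTNT`) but contributes exactly zero.
The nine sequence codes partition all classifiable state triples; a 1982
NT cropland state is a classification error, since the tillage surveys
report no NT cropland at that date.

**Economics.** The unit cost of a stratum is its state's annual conservation
payment divided by its annual CO₂ rate (payment / `rate · 44/12`). Program
rules on payment duration and practice maintenance are documented but not
modelled — the payment is used purely as the cost of switching. Carbon↔CO₂
conversion uses 44/12 kept as an exact binary ratio; the conventional 3.67
appears nowhere in computation. The default dollar-year deflator is the
exact ratio 36.36/30 (restating the $30 geologic-storage cost from 2005 to
2014 dollars); restating $71 with this ratio gives $86.05, while published
restatements using an unrounded price index print $86.06 — the package does
not chase the cent. An optional reserve-pool fraction `f ∈ [0, 1)` (default
0; exchanges have used 0.20) discounts the creditable rate, which raises
every unit cost by exactly `1/(1−f)` and shrinks curve quantities by
`(1−f)`; the curve-conservation identity below is stated at `f = 0`.

**Cost curve.** Positive-rate strata are sorted by unit cost, ties broken by
stratum id so output is bit-identical across runs; zero- and negative-rate
strata go to a first-class exclusion list with reasons rather than being
priced at infinity. `quantity_below(price)` sums annual quantity strictly
below the price (boundary excluded), matching the "less than" convention of
threshold comparisons. Threshold summaries report per-sequence quantities,
shares of the below-threshold total, and shares of the scenario-wide annual
potential (which includes zero-rate land in its denominator). Default
thresholds are $36.36 and $86.06 / Mg CO₂, the low/high geologic
capture-and-storage cost estimates.

## Units

Internal canonical units are Mg C ha⁻¹ yr⁻¹, ha and years. Because
1 Tg = 10⁶ Mg and 1 Mha = 10⁶ ha, the identity
`annual total (Tg yr⁻¹) = rate (Mg ha⁻¹ yr⁻¹) × area (Mha)` is exact, and
conservation checks are asserted at 1e−9 relative.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| horizon `D` | 20 | yr | Tier 1 equilibration time |
| CO₂/C ratio | 44/12 exact | — | molar masses |
| deflator | 36.36/30 exact | — | 2005→2014 restatement of the $30 threshold |
| reserve fraction | 0 | — | no reversal insurance unless requested |
| thresholds | 36.36, 86.06 | $/Mg CO₂ | geologic-storage cost range (2014$) |
| factor uncertainty | LU 12, MG 10, I 15 | % | reported Tier 1 relative uncertainties (upper ends) |

Factor multipliers and reference stocks are configuration, not code. The
packaged `data/factors.csv` and `data/ref_stocks.csv` hold editable defaults
populated from the 2006 IPCC guideline tables (temperate RT/NT factors
1.02–1.08 / 1.10–1.15, cultivated land-use factors 0.69–0.80, reference
stocks 19–130 Mg C ha⁻¹); no factor value is treated as a test oracle.
Climate and soil enumerations follow the 2006 IPCC naming with an alias map
for common spellings ("cold temperate, moist", "HAC").

## Synthetic data generator

The generator emulates the structure of the unavailable survey inputs:

- **Sequences** are assigned per stratum multinomially with configurable
  area shares; defaults are the published national shares (CTCTNT 58.0 %,
  CTRTNT 23.2 %, CTNTNT 2.2 %, RTRTNT 0.9 %, RTNTNT 4.8 %, NCCTNT 6.9 %,
  NCRTNT 3.1 %, NCNTNT 0.9 %, RTCTNT 0 — printed as 0.0 % of area; a
  non-zero share can be configured, but the default keeps the shares summing
  to exactly 100).
- **Areas** are i.i.d. lognormal (σ = 1 by default, mimicking the
  heterogeneity of survey expansion weights) rescaled so the total is
  exactly the configured 124.7 Mha.
- **Rates are never written into strata.** The generator draws per-climate
  factors (F_NT ∈ [1.10, 1.17], the RT gap constrained to 40–60 % of the CT
  gap) and then solves, per climate, the reference-stock interval for which
  *every* (tillage, input-level) combination in the catalog yields a
  conversion rate inside the configured range (default 0.12–0.47 Mg C ha⁻¹
  yr⁻¹, the published span of region × sequence averages). Reference stocks
  are drawn from that interval, so rates emerge through the real Tier 1
  arithmetic and the containment is a theorem, not a clamp. An infeasible
  range (narrower than the factor spread allows) raises a generation error.
- **Payments** are uniform over the configured range (default
  $18.29–$125.73 ha⁻¹, the published national extremes) for 48 conterminous
  states; climate, soil, rotation, region and state are uniform over their
  catalogs.
- **Determinism.** One `numpy` generator seeded by the master seed drives
  all draws in a fixed stream order (factors by climate, reference stocks by
  climate × soil, payments by state, then per-stratum blocks); regenerating
  from the recorded `provenance.json` is byte-identical.

What the generator does **not** emulate: geographic realism (no spatial
correlation between climate, region and state), the joint distribution of
sequence × climate × rotation (treated as independent), and the actual
payment distribution (uniform rather than the real state schedule). Passing
tests therefore demonstrate the pipeline's correctness and calibration
recovery, not agreement with the historical national totals, whose
micro-data are unavailable.

`expected_aggregates` provides the recovery targets: the standard error of
an area-weighted share under multinomial assignment with lognormal areas is
`sqrt(p(1−p)·deff/n)` with design effect `deff = exp(σ²)`, so tolerances
scale as `1/√n`.

## Sensitivity sweep

Factor-level uncertainty is propagated by perturbing every factor entry
independently with a relative Gaussian error at its kind's percentage
(defaults above), re-running the SOC model and curve for each draw, and
reporting per-price min/2.5 %/median/97.5 %/max envelopes of
`quantity_below`. Draws perturb factors, not rates, because the reported
uncertainties are stated at the factor level. Perturbed multipliers are
floored at a tiny positive value to preserve the positivity invariant.

## Numerical conventions

- Rounding happens only in the reporting layer (`render_table`), one decimal
  for rates/totals/percentages and two for currency, half away from zero via
  `decimal`; an unrounded CSV always accompanies every rendered table.
- Curve ordering is (unit cost, stratum id); equal-cost output is
  deterministic and bit-identical across runs.
- Negative rates (impossible under the default reduced-disturbance factor
  ordering, possible with user-supplied tables) are computed, flagged and
  excluded from curves, never silently dropped.
- Empty inputs raise explicit errors rather than producing empty reports.

## Problem sizes

The test suite uses synthetic bundles of 25–5000 strata; the acceptance
script runs the full pipeline at 5000 strata and evaluates the worked-example
arithmetic on the nine published sequence rows. The whole suite completes in
a few seconds on one CPU.

## Known limitations

Single 0–30 cm pool and Tier 1 only (no measurement- or process-based
estimation, no N₂O/CH₄); instantaneous conversion at the 1997 state with no
adoption dynamics; no profit-based cost estimation, discounting/NPV or
transaction and monitoring costs; threshold comparisons are strict (`<`), so
a stratum priced exactly at a threshold is not counted below it.
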