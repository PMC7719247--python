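# soccurve

Marginal cost curves for increasing soil organic carbon (SOC) on cropland
through no-till adoption.

## The problem

Reducing tillage intensity raises the equilibrium SOC stock of cropland, so
converting conventionally tilled (CT) or reduced-till (RT) land to no-till
(NT) sequesters atmospheric CO₂ — but at a cost to the landowner. This
package combines the two sides of that trade:

- **Biophysics** — the IPCC Tier 1 inventory method. The equilibrium SOC
  stock of a managed soil (0–30 cm) is

  `SOC = SOC_ref(climate, soil) · F_LU · F_MG · F_I`

  where `SOC_ref` is the stock under native vegetation and `F_LU`, `F_MG`,
  `F_I` are land-use, tillage and input multipliers. After a management
  change the stock moves linearly to its new equilibrium over `D = 20`
  years, so the annual sequestration rate of converting a stratum to NT is
  `ΔSOC / D` (Mg C ha⁻¹ yr⁻¹), converted to a CO₂ basis with the molar-mass
  ratio 44/12.

- **Economics** — each state's conservation-program payment for no-till
  adoption (`$ ha⁻¹ yr⁻¹`) is taken as the minimum incentive a landowner
  requires, so the unit cost ("carbon value") of a land stratum is

  `C_value ($ / Mg CO₂) = payment / rate_CO₂`.

Sorting all strata by unit cost and accumulating their annual quantities
gives the marginal cost curve: how many Tg CO₂ yr⁻¹ can be bought below any
carbon price, e.g. below the $36.36–$86.06 / Mg CO₂ range estimated for
geologic carbon capture and storage (2014 dollars).

Strata are homogeneous land units (climate × soil × rotation × state ×
tillage history × area) tracked over three inventory dates (1982, 1997,
2017) and labelled with one of nine tillage sequences (CTCTNT, CTRTNT, …,
NCNTNT; NC = non-crop in 1982). Land already under NT in 1997, or not
cropland in 1997 (CRP / hay / pasture), contributes zero and is excluded
from the curve.

The survey micro-data behind the original analysis (land-use survey points,
tillage-survey adoption, state payment schedules) are not publicly
available at the required resolution, so the package includes a seeded
synthetic-data generator (`soccurve.synthetic_data`) that emulates their
statistical structure, and the default factor/reference-stock tables ship
as editable CSV fixtures populated from the 2006 IPCC guidelines.

## Worked example

```python
import soccurve as sc

bundle = sc.generate_bundle(sc.GeneratorConfig(n_strata=1000, seed=7))
results = sc.compute_rates(bundle.strata, bundle.factors, bundle.ref_stocks)
table1 = sc.aggregate_by_sequence(results)
curve = sc.build_curve(results, bundle.payments)
total = sum(r.annual_total_co2 for r in results)

print(sc.render_table(table1[["area_mha", "area_share_pct", "annual_tg_co2", "wavg_rate_c"]],
                      precision={"wavg_rate_c": 2}))
print(f"priced strata: {len(curve.points)}, excluded: {len(curve.excluded)}")
print(f"cheapest unit cost: ${curve.points[0].unit_cost:.2f} / Mg CO2")
print(f"quantity below $36.36: {sc.quantity_below(curve, 36.36):.1f} Tg CO2/yr")
print(f"share below $100.00: {100 * sc.quantity_below(curve, 100.0) / total:.1f} %")
```

prints

```
         area_mha area_share_pct annual_tg_co2 wavg_rate_c
sequence
CTCTNT       68.9           55.2          79.9        0.32
CTRTNT       30.9           24.8          20.6        0.18
CTNTNT        2.6            2.1           0.0        0.00
RTRTNT        0.6            0.5           0.4        0.18
RTNTNT        6.8            5.4           0.0        0.00
NCCTNT        7.9            6.3           9.5        0.33
NCRTNT        4.8            3.9           2.8        0.16
NCNTNT        2.2            1.8           0.0        0.00
TOTAL       124.7          100.0         113.3        0.25
priced strata: 931, excluded: 69
cheapest unit cost: $13.50 / Mg CO2
quantity below $36.36: 20.7 Tg CO2/yr
share below $100.00: 76.0 %
```

Reading the output: 1000 synthetic strata covering 124.7 Mha of 1997
cropland are classified into tillage sequences; the `…NTNT` rows are zero
because land already under no-till gains nothing from the scenario. The
113.3 Tg CO₂ yr⁻¹ total is the scenario's annual biophysical potential;
931 strata with positive rates are priced onto the curve, the 69 zero-rate
strata are listed in `curve.excluded`; 20.7 Tg CO₂ yr⁻¹ is available below
the low geologic-storage cost and 76 % of the potential below $100 / Mg CO₂.

The same run is available from a shell:

```bash
soccurve all --seed 7 --n-strata 1000 --out scratch/run7
```

which writes `rates.csv`, `curve.csv`, `summary.csv`, `table1.csv`,
`table2.csv` (region × sequence rates), rendered `.txt` tables and a
`run.log` with input digests. `soccurve simulate` writes just the synthetic
inputs; `soccurve report --config run.yaml` runs the pipeline on your own
CSVs (schemas documented in the module docstrings).

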