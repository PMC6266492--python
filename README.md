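# ecofoot

Ecological-footprint accounting and grey forecasting for multi-city regions.

`ecofoot` is for sustainability analysts who have regional yearbook data —
item-level biological production, energy consumption, land areas, a resident
population — and want the standard ecological-footprint balance sheet plus a
short-horizon forecast of where it is heading. It computes, per year:

- the **ecological footprint per capita** (demand side),
  `ef = Σ_j w_j · A_j`, where `A_j` is the per-capita biologically
  productive area of land type `j` (arable, forest, pasture, water,
  fossil-energy, built-up) and `w_j` the equivalence factor converting it to
  world-average-productivity area; item areas are production divided by the
  item's global average yield (biological items) or consumption divided by
  the global average energy footprint (energy items); `EF = N · ef`;
- the **ecological carrying capacity** (supply side),
  `EC = Σ_j w_j · y_j · A_j` with yield factors `y_j`, `ec = EC / N`, of
  which 12% is deducted as biodiversity conservation land, leaving the
  *available* capacity `0.88 · ec`;
- the **ecological deficit** `ED = ef − 0.88 · ec` (positive: demand exceeds
  supply);
- **GM(1,1) grey-model forecasts** of the per-capita series: the series is
  cumulated (AGO), the grey differential equation `dx⁽¹⁾/dt + a·x⁽¹⁾ = u` is
  fitted by least squares on its half-sum discretisation, and forecasts are
  restored by differencing the time response
  `x̂⁽¹⁾(t+1) = (x⁽⁰⁾(1) − u/a)·e^(−a·t) + u/a`. The model is designed for
  the 4–10-point annual series typical of regional accounts.

The package ships a complete worked dataset: the published five-year
(2013–2017) account of an eight-city urban agglomeration in the lower
Yangtze region, with item-level biological and energy accounts for 2017.

## Worked example

```
$ ecofoot reproduce
year  column                    computed  published  match
2013  ef_per_capita               1.5270     1.5270  ok
...
2017  ef_per_capita               1.2611     1.2611  ok
2017  ec_per_capita               0.3595     0.3595  ok
2017  available_ec_per_capita     0.3164     0.3164  ok
2017  deficit_per_capita          0.9447     0.9447  ok

forecasts (raw_ec):
 year  ef_forecast  ec_forecast  deficit_forecast
 2018       1.5371       0.3658            1.1713
 2019       1.4566       0.3587            1.0979
 2020       1.3803       0.3517            1.0287
 2021       1.3080       0.3448            0.9632
 2022       1.2395       0.3381            0.9015
```

In 2017 the region demanded 1.2611 hm² of world-average-productivity land
per resident while supplying 0.3164 hm² after the biodiversity deduction — a
per-capita deficit of 0.9447 hm², i.e. demand close to four times supply.
The grey fits (`a = 0.0538` for demand, `a = 0.0197` for supply, both
positive, so both series decay geometrically at rate `e^(−a)`) put the 2018
deficit at 1.1713 hm²/person, declining year by year through 2022.

The same stages are available piecewise (`ecofoot footprint`, `capacity`,
`balance`, `fit`, `forecast`, `simulate`) and as library functions:

```python
import ecofoot

fx = ecofoot.study_fixtures()
table = ecofoot.study_annual_table(fx)          # 2017 recomputed from items
report = ecofoot.run_balance_forecast(table, horizon=5, round_decimals=4)
print(report.ef_fit.a, report.ef_fit.asymptote)  # 0.05379 37.92
```

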