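# riveryield

Riverine organic-carbon load estimation and inter-station watershed yield
allocation.

Gauging stations on a river network observe daily streamflow continuously
but constituent concentrations (here particulate and dissolved organic
carbon, POC and DOC) only on sparse sampling days. `riveryield` turns those
sparse paired records into mean constituent loads per station, and then —
using the drainage topology connecting small catchment units — into a
spatially distributed map of *net* carbon yield: how much carbon each
inter-station watershed adds to, or removes from, the water column. The
net yield can be negative (burial, outgassing exceed terrestrial input),
which a simple load/area ratio can never show.

## Method

**Rating curves.** For each station and constituent, the instantaneous
load L = 86400·Q·C (gC day⁻¹) on sampled days is regressed on streamflow
and season with nine candidate log-linear models,

```
ln L = a0 + a1·lnQ [+ a2·lnQ² ] [+ sin/cos(2π·dtime)] [+ dtime, dtime²] + ε
```

where lnQ and dtime (decimal time) are centered with the decorrelating
center c = mean + Σd³/(2Σd²), which zeroes the covariance between a
covariate and its square. The minimum-AIC model (AIC counts the residual
variance as a parameter) predicts the load on every day of the flow
record, with the lognormal retransformation correction exp(s²/2); the
whole-record mean is the station's load. Stations with fewer than 12
paired observations are excluded (carried through with a reason code).

**Drainage network.** Catchment units carry one downstream link each;
after applying an explicit corrections table the links must form a forest.
A station's drainage area is the summed area of all units upstream of its
unit — except stations in headwater units, where the gauge-record reported
area is substituted, since the gauge controls only part of the unit.
Closed (endorheic) basins and everything draining into them are excluded.

**Yield allocation.** Stations are leveled (level 1 = no gauge
downstream), every unit is assigned to the nearest station down its flow
path, and each region's net yield is

```
Y = (F_down − Σ F_up) / (A_down − Σ A_up)    [kgC km⁻² yr⁻¹]
```

over the downstream station and its immediate upstream stations
(Y = F/A for a station with nothing gauged above it). Yields telescope:
summing Y·ΔA over the regions above a station reproduces its load exactly.

**Validation harnesses.** (1) regression of network-derived on reported
drainage areas against the 1:1 line; (2) for pairs of a sparsely sampled
upstream gauge (≤20 obs) under a densely sampled downstream gauge
(≥30 obs), the upstream load implied by pure area scaling,
F_down·(A_up/A_down), is correlated against the rating-curve estimate.

A synthetic-watershed generator (random drainage forests with lognormal
unit areas averaging ~104 km², seasonal lognormal flows, concentrations
drawn exactly from a chosen rating-curve model, and a ground-truth yield
field inducing mass-balanced station loads) exercises every stage with
known answers.

## Worked example

```python
from riveryield import (
    ObservationGeneratorSpec, SyntheticNetworkSpec,
    generate_network, place_stations, generate_true_yields, induce_station_loads,
    build_graph, station_drainage_area, assign_station_levels,
    compute_all_region_yields, simulate_observations, estimate_station_load,
)

# one gauged station: ten years of daily flow, 40 sampled days
spec = ObservationGeneratorSpec(model_id=4, coefficients=(8.0, 1.0, 0.3, 0.2),
                                sigma=0.3, n_samples=40, seed=11)
flow, samples = simulate_observations(spec)
rec = estimate_station_load(flow, samples, station_id="S0000", constituent="DOC")
print(f"selected model {rec.model_id}, R2 = {rec.r_square_pct:.1f}%")
print(f"mean daily load = {rec.mean_daily_load:,.0f} gC/day "
      f"-> annual load = {rec.annual_load:,.0f} kgC/yr")

# a small watershed: net yields between nested gauges
units = generate_network(SyntheticNetworkSpec(n_units=120, seed=3))
graph = build_graph(units)
stations = place_stations(units, 10, seed=3)
truth = generate_true_yields(units, seed=3)
loads = induce_station_loads(graph, stations, truth)
areas = {s.station_id: station_drainage_area(graph, s)[0] for _, s in stations.iterrows()}
levels = assign_station_levels(graph, stations)
regions = compute_all_region_yields(graph, stations, loads, areas, levels)
for sid, ry in sorted(regions.items())[:5]:
    print(f"{sid}: level {ry.level}, dA = {ry.incremental_area:7.1f} km2, "
          f"yield = {ry.yield_value:8.1f} kgC/km2/yr [{ry.status}]")
```

prints

```
selected model 4, R2 = 92.0%
mean daily load = 6,595 gC/day -> annual load = 2,409 kgC/yr
S0000: level 1, dA =  1524.4 km2, yield =   4957.5 kgC/km2/yr [ok]
S0001: level 1, dA =  1402.8 km2, yield =   5672.6 kgC/km2/yr [ok]
S0002: level 2, dA =   263.7 km2, yield =   5782.9 kgC/km2/yr [ok]
S0003: level 1, dA =   639.1 km2, yield =   5362.5 kgC/km2/yr [ok]
S0004: level 1, dA =  1297.8 km2, yield =   6269.3 kgC/km2/yr [ok]
```

AIC identified the generating seasonal model (4) with 92% of ln-load
variance explained; the regional yields scatter around the true field
mean of 5,000 kgC km⁻² yr⁻¹, each one the exact incremental-area-weighted
truth for its region because the loads here are noise-free.

The same workflow runs from the shell on CSV files:

```bash
riveryield --seed 1 --out-dir outputs run-all   # simulate -> fit -> yields -> validate
```

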