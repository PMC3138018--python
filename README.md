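# pmbme

Two-stage mapping of monthly fine particulate matter (PM2.5) over a city,
for exposure assessment when PM2.5 monitoring is sparse but PM10 monitoring
and landuse data are rich.

Many networks measured PM10 for decades before adding PM2.5 channels, so
long-term PM2.5 exposure fields must be reconstructed. This package
combines two complementary sources of structure:

1. **Ratio land-use regression (LUR).** The fine-to-coarse ratio
   `r_{s,t} = PM2.5 / PM10` is driven by the local emission environment and
   varies more in space than in time, so it is regressed on the areas of
   landuse classes (road, forest, industry, park, …) within ring buffers
   of 0–50 … 500–1000 m around each monitor, with stepwise selection and
   variance-inflation screening. Multiplying the predicted ratio by PM10
   gives an *uncertain trend* `m = r̂·Y` for PM2.5, with interval bounds
   `[(r̂−SD)·Y, (r̂+SD)·Y]`.

2. **Bayesian Maximum Entropy (BME) space-time estimation.** PM2.5
   residuals about the trend carry the dependence structure

   `c(h,τ) = c0·e^(−3h/a_r1)·e^(−3τ/a_t1) + c1·e^(−3h/a_r2)·e^(−3τ/a_t2)`

   (a nested pair of exponential structures: local transport with ranges of
   order 11 km / 3 months and regional transport of order 50 km / 50
   months). BME blends exact residuals at PM2.5 stations (*hard* data) with
   uniform-interval residuals implied by the LUR uncertainty elsewhere
   (*soft* data) into a posterior density at every map point. With a
   Gaussian general knowledge base the machinery reduces to closed-form
   conditioning plus rectangle integrals; simple kriging is the exact
   hard-data-only special case and serves as the baseline comparator.

The package ships a synthetic-city generator reproducing the targeted
study design (18 dual-pollutant + 8 PM10-only stations, 36 months, a
landuse-driven ratio surface), estimator classes in the scikit-learn
idiom (`RatioLUR`, `NestedCovarianceWLS`, `SimpleKriging`,
`BMEInterpolator`), a pipeline with leave-one-station-out
cross-validation of three methods (`kriging`, `lur`, `lur_bme`), and a
thin CLI (`pmbme`). See `docs/methods.md` for the model details.

## Worked example

```python
import numpy as np
from pmbme import (ScenarioConfig, generate_scenario, cross_validate,
                   empirical_covariance, fit_nested_exponential)

scen = generate_scenario(ScenarioConfig(seed=1))
cfg = scen.analysis_config()

# nested space-time covariance of the PM2.5 observations
emp = empirical_covariance(scen.observations, scen.stations, pollutant="pm25")
cov = fit_nested_exponential(emp, random_state=1)
print(f"sills ({cov.c0:.2f}, {cov.c1:.2f}) (ug/m3)^2, "
      f"ranges ({cov.ar1:.1f} km, {cov.at1:.1f} mo) local")

# leave-one-station-out comparison of the three estimation methods
for method in ("kriging", "lur", "lur_bme"):
    stats = cross_validate(method, scen.observations, scen.stations,
                           scen.landuse, cfg)
    s = stats.summary
    print(f"{method:8s} MSE {s['mse']:7.2f}  MAE {s['mae']:5.2f}  "
          f"mean error {s['mean_error']:+.2f}")
```

Output on this seed:

```
sills (77.76, 106.23) (ug/m3)^2, ranges (0.2 km, 2.2 mo) local
kriging  MSE  194.49  MAE 10.40  mean error +0.00
lur      MSE  120.59  MAE  8.38  mean error +0.07
lur_bme  MSE  119.51  MAE  8.29  mean error -0.29
```

The fitted sills here describe the raw PM2.5 observations, not trend
residuals, hence their magnitude: station-to-station ratio differences
look like a short-range structure (here nugget-like, 0.2 km) persisting in
time, on top of a large smooth component. The MSE ranking is the expected
one: the ratio-trend method already beats plain kriging of the sparse
PM2.5 network, and assimilating the trend's interval uncertainty through
BME improves it further; over ten replicate cities the combination beats
kriging on every seed (median MSE 65.4 vs 133.7).

From the shell the same run is:

```sh
pmbme simulate --seed 1 --out scenario
pmbme crossval --method lur_bme --obs scenario/observations.csv \
      --stations scenario/stations.csv --landuse scenario/landuse.geojson \
      --out cv_lur_bme.json
```

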