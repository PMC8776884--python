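# fleetres

Fishing-fleet resilience analysis from AIS-derived fishing effort.

`fleetres` treats a fishing **fleet** — the set of vessels that use the same
gear — as if it were a fish stock. The fleet's total monthly fishing hours
A_t play the role of stock abundance, and everything that removes fishing
hours (seasonal bans, vessel decommissioning, market shocks, pandemic
lockdowns) plays the role of fishing pressure on that "stock". Fitting the
Schaefer surplus-production dynamic

```
A_{t+1} = A_t + r·A_t·(1 − A_t/kq) − Cq_t
```

to a fleet's effort series yields interpretable management traits:

* **r** — the fleet's intrinsic monthly growth rate: how fast it rebuilds
  fishing hours after a loss (its resilience);
* **kq** — the maximum monthly fishing hours the fleet's resources (target
  stocks and market) can sustain (carrying capacity × catchability; the
  catchability q is implicit and never estimated separately);
* **MSR = r·kq/4** — the maximum sustainable reduction of fishing hours,
  the MSY analogue of the Schaefer model;
* **Cmsr_t = Cq_t / MSR** — the monthly relative stress series: months with
  Cmsr > 1 are over-stressed, < 1 under-stressed.

Because the recurrence inverts exactly for the implied stress Cq_t given
(r, kq), the fit is a viable-pair Monte-Carlo: draw many (r, kq) pairs from
a log-uniform prior box and keep those whose implied stress is everywhere
non-negative with A_t never exceeding kq; medians over the viable cloud are
the point estimates, the central 95% the uncertainty.

Around this core the package provides the full pipeline a fleet analyst
needs, aimed at Adriatic-style mixed fisheries (bottom otter trawl OTB,
pelagic pair trawl PTM, beam trawl TBB, purse seine PS, OTHER):

* **AIS preprocessing** (`fleetres.ais`) — ping ingestion, trip
  segmentation, speed-band fishing flags, fishing-hour accounting;
* **gear classification** (`fleetres.classify`) — speed-profile features,
  k-means smoothing and a behavioural rule cascade (pairing → beam-trawl
  speeds → otter-trawl speeds → purse-seine loitering), validated against a
  licence registry with Cohen's kappa;
* **effort mapping** (`fleetres.gridding`) — gridded fishing hours on a
  regular lat-lon lattice, log-normal low/medium/high cell classes, period
  comparison, per-gear effort barycentres and their extents;
* **ETP overlap** (`fleetres.etp`) — species-richness grids from range
  polygons, high-effort × high-richness impact cells, effort-at-risk series;
* **synthetic data** (`fleetres.synthetic`) — generators for effort series
  with Schaefer structure, gear-realistic AIS tracks and clustered species
  grids, so the whole pipeline runs without proprietary inputs.

## Worked example

Fit the fleet model to a synthetic purse-seine effort series generated under
the default study conditions (71 months from January 2015, seasonal stress,
March–May 2020 lockdown shock, no observation noise):

```python
import dataclasses
from fleetres import FleetResilienceModel, PriorConfig
from fleetres.synthetic import ADRIATIC_FLEETS, simulate_effort_series

params = dataclasses.replace(ADRIATIC_FLEETS["PS"], noise_cv=0.0)
series = simulate_effort_series(params)          # EffortSeries, 71 months
res = FleetResilienceModel(series, prior=PriorConfig(seed=1)).fit()
print(res.summary())
```

```
Fleet resilience fit (Schaefer viable-pair Monte-Carlo)
========================================================
fleet: PS    months: 71 (2015-01..2020-11)
prior: r in (0.05, 2.0) /month, kq in (11704, 46816) h, log-uniform
samples: 100000   viable: 41357
--------------------------------------------------------
trait                           estimate    95% interval
r (month^-1)                       0.935    [0.43, 1.92]
kq (hours/month)                   24261  [12270, 45374]
MSR = r*kq/4 (hours/month)          5672
--------------------------------------------------------
over-stressed months (Cmsr > 1): 29 of 70
```

The generator's truth for this fleet is r = 1.04 month⁻¹ and kq = 20,818
hours: 41,357 of 100,000 sampled pairs are compatible with the series, and
their medians recover the truth to about −10% (r) and +17% (kq) — within
the uncertainty such one-sided viability filtering can achieve. The stress
table (`res.stress`) labels each month:

```
 year  month          Cq     Cmsr state
 2020      9 4164.940520 0.734288 UNDER
 2020     10 5133.080087 0.904973 UNDER
 2020     11 5814.132454 1.025044  OVER
```

The same analysis from the shell, plus the full synthetic pipeline:

```
fleetres assess-fleet --series series.csv --fleet PS --seed 1 --out out/
fleetres demo --seed 1 --out demo-out/        # AIS → gears → maps → ETP → traits
```

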