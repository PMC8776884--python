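# Methods

## The fleet-as-stock model

The core assumption is that a fleet's monthly fishing effort behaves like
the abundance of a harvested population. Total fishing hours A_t (hours per
month, strictly positive) follow the discrete Schaefer surplus-production
recurrence

    A_{t+1} = A_t + r·A_t·(1 − A_t/kq) − Cq_t

with r the intrinsic monthly growth rate (month⁻¹), kq the carrying
capacity of the fleet's resources expressed in fishing hours (carrying
capacity × catchability; q is never estimated separately — it cancels in
every reported quantity), and Cq_t the hours removed between months t and
t+1 by external stress factors. Given (r, kq) the recurrence inverts
exactly:

    Cq_t = A_t + r·A_t·(1 − A_t/kq) − A_{t+1}

so each candidate parameter pair implies a unique stress series. The model
is deterministic (no process error) and the inversion is algebraic; all
inference happens through the admissibility of the implied stress.

### Viable-pair Monte-Carlo

`n_samples` pairs (r, kq) are drawn log-uniformly from a prior box and a
pair is **viable** iff

1. every implied Cq_t ≥ 0 (stress can remove hours, never inject them), and
2. A_t ≤ kq for every month (effort cannot exceed carrying capacity).

Point estimates are medians of the viable cloud, uncertainty the central
95% interval; both are distribution-free. From the medians follow
MSR = r·kq/4 (the Schaefer MSY, here the maximum sustainable monthly
reduction of fishing hours) and the relative stress series
Cmsr_t = Cq_t/MSR with month states OVER (> 1), UNDER (< 1) and
SUSTAINABLE (= 1 within 1e-9). Cq_t is labelled with month t+1, the month
in which the loss of hours is observed.

Defaults, with rationale:

| parameter    | default               | why |
|--------------|-----------------------|-----|
| r prior      | (0.05, 2.0) month⁻¹   | wide neutral box containing all plausible monthly recovery speeds for commercial fleets |
| kq prior     | (max A, 4·max A) h    | kq below the observed maximum is infeasible (condition 2); a factor 4 leaves room without diluting the sample |
| sampling     | log-uniform           | scale-free over a box spanning more than an order of magnitude |
| n_samples    | 100,000               | viable counts in the tens of thousands; medians stable to well under 1% across seeds |
| estimate     | median, 2.5–97.5 pct  | robust, percentile-based reporting convention of viable-sample methods |
| depletion window | off               | an optional filter lo ≤ A_end/kq ≤ hi exists (`PriorConfig.final_depletion`) but is not part of the default viability rule |

The viability constraints bound the parameters from one side only (any
larger r, and any larger kq, keeps a viable pair viable). Medians therefore
depend on the prior box, and the method should be read as "which parameter
region is compatible with the series", not as a likelihood optimum. The
recovery bands the test suite asserts (r within ±45%, kq within ±20% of the
generator's truth, mirroring the relative widths of the reported confidence
intervals) reflect this one-sidedness.

Numerics: viability is evaluated vectorized in 50,000-pair chunks (peak
memory ≈ chunk × months doubles). The inversion round-trip is exact
step-by-step to 1e-9 relative; over a full 71-month trajectory, float
rounding is amplified by the product of the logistic map's derivatives, so
trajectory-level 1e-9 agreement is only guaranteed at the generator's own
parameters (same arithmetic path), and the property tests check the
step-wise form for arbitrary viable pairs.

## Synthetic effort series

The generator emulates a fleet under seasonal regulation with an optional
lockdown shock. Stress removes a fraction of current effort each month:

    Cq_t = f(month)·A_t,
    f(month) = base·(1 − a_s·cos(2π(month − 8)/12)) [+ shock in shock months]

* **base stress** defaults to r/2, which holds the fleet at the
  sustainably-stressed equilibrium A* = kq/2 with Cmsr ≈ 1 — the regime a
  well-regulated fleet oscillates around, and the regime in which the
  (max A, 4·max A) prior is informative (max A ≈ kq/2 puts the prior's
  geometric centre near the true kq).
* **seasonal amplitude** a_s defaults to 0.15. Under the equilibrium
  schedule the seasonal peak of effort is max A ≈ (1 + a_s)·kq/2, so the
  median of the kq prior sits near (1 + a_s)·kq: the amplitude directly
  sets the systematic bias of the kq estimate. 0.15 keeps that bias inside
  the ±20% recovery band while leaving enough month-to-month variation to
  constrain r. The sinusoid's minimum falls in August; the phase only
  determines in which calendar months the extremes fall.
* **lockdown shock**: in each shock month an extra `shock_magnitude`
  (default 0.37) of current effort is removed — applied to the stress, not
  to A_t, so the Schaefer structure is preserved. The reference conditions
  use March–May 2020.
* **observation noise** is multiplicative lognormal with median 1 and CV
  `noise_cv` (default 0.05; hours are positive and right-skewed). The true
  noise level of monthly effort totals is unknown; 0.05 is a pipeline
  assumption, and the recovery analyses use noise_cv = 0.
* The reference fleet conditions (`ADRIATIC_FLEETS`) use the reported trait
  estimates of the four Adriatic fleets as simulation truths: PS r = 1.04,
  kq = 20,818; PTM r = 0.96, kq = 4,526; TBB r = 0.57, kq = 18,150;
  OTB r = 0.56, kq = 117,033; 71 months from January 2015; a0 = kq/2.

The generator raises on any schedule that drives A_t ≤ 0 ("effort
collapse") rather than silently clipping.

## Synthetic AIS tracks

Vessels alternate port dwell, steaming legs and fishing legs; pings are
emitted every 5 minutes (configurable) with the integrated speed reported
as sog, so displacement-derived speeds match the reported ones. Gear
behaviour: otter trawlers tow at ~3.2 kn, beam trawlers ~5.5 kn, pair
trawlers ~3.5 kn with the partner vessel a rigid ~150 m translate of the
leader (same speeds, well inside the 300 m pairing distance), purse seiners
alternate ~0.2 kn setting/soaking with ~1 kn hauling, OTHER vessels transit
at ~8 kn. Leg durations are exponential/uniform draws fixed in the module;
port dwell is at least 5 h and silent (no pings), so the 4 h trip-gap
threshold always separates trips. Real transponders often keep transmitting
at berth — the pipeline's segmentation does not depend on this
simplification, only the generator does. Tracks live in an abstract
Adriatic-sized box with flat-earth kinematics; no coastline, bathymetry or
port geometry is modelled, so spatial results from synthetic data
demonstrate mechanics, not realistic footprints.

## AIS preprocessing

* Trip segmentation cuts at gaps > 4 h; fishing-hour accumulation caps
  individual ping gaps at 1 h so dropouts do not inflate hours. Both values
  are configurable; at the 5-minute cadence they are inactive.
* Fishing flags use the reported sog, not recomputed displacement speed
  (a validation utility recomputes it). Default bands (knots): OTB
  [2.0, 4.5), TBB [4.0, 7.0), PTM [2.0, 5.0), PS [0.0, 1.5), OTHER
  [0.0, 15.0). These are configurable defaults chosen from towing-practice
  ranges, not measured constants.
* PS flags additionally require the ping to be > 1 km from both trip
  endpoints (port buffer), since near-zero speed is otherwise
  indistinguishable from dwell.

## Gear classification

Per-trip features: a normalized 30-bin speed histogram over [0, 15] kn,
the loitering fraction (sog < 0.5 kn away from the endpoints) and the
paired fraction (pings at 2–5 kn with another vessel within 300 m at ±2.5
min). Trips are smoothed by 5-means clustering (features replaced by their
cluster centroid) before the rule cascade; clustering regularises noisy
single-trip histograms but carries no gear semantics itself. Rules, in
order: paired fraction > 0.3 → PTM; dominant speed mode (bins ≥ 1 kn) in
the TBB band → TBB (checked before OTB because the bands may overlap and
beam trawls tow faster); in the OTB band → OTB; loitering > 0.3 with a
near-zero overall mode (< 1.5 kn) → PS; else OTHER. Vessel label = majority
over its trips, ties → OTHER. Agreement with a licence registry is scored
with Cohen's kappa over the five classes; both-sides-constant-and-equal
returns 1 by convention.

## Effort grids, classes, barycentres

Cells are half-open [lon, lon+res) × [lat, lat+res) on a lattice anchored
at integer degrees (typical resolutions 0.1° and 0.5°). Each fishing
interval's hours go entirely to the cell of its first ping — at 5-minute
cadence the placement error is at most one cell and gridding conserves
total hours exactly. Cell coordinates are snapped with a 1e-9-cell epsilon
so points arithmetically on an edge land in the upper cell.

Positive cells are classified assuming a log-normal distribution of hours:
with μ and σ the mean and sample SD of log10(hours) over the positive cells
of a reference grid (default: the grid itself, optionally a fixed reference
period for cross-year comparability), HIGH iff log10 h ≥ μ + σ, LOW iff
log10 h < μ − σ, MEDIUM otherwise; σ = 0 makes everything MEDIUM. The log
base is irrelevant to the classes; 10 gives readable thresholds. A
tertile-based alternative (`method="quantile"`) is provided; the one-sigma
rule is the default. The same classifier is reused verbatim for
species-richness counts (restricted to cells with ≥ 1 species).

Barycentres are hours-weighted means of active cell centres, reported per
gear and month, with bounding-box extents summarising seasonal movement
ranges.

## ETP overlap

Species ranges are intersected with the lattice as presence/absence — any
overlap counts, including a shared edge or corner (conservative for
impact), and each species counts once per cell. Impact cells are strictly
HIGH effort ∧ HIGH richness; MEDIUM combinations are reported in the
summary but not flagged. The effort-at-risk series sums each month's hours
over the impact cells per gear. The synthetic species generator gives every
species the hotspot disc plus an independent 15% scatter of background
cells, and derives its counts from its own polygons with the same
intersection rule, so re-deriving the grid from the generated ranges is an
identity.

## Problem sizes

The shipped analyses use 71-month series, 100,000 sampler draws, 20
synthetic vessels at 5-minute cadence over 3 days, and 0.1° grids over an
Adriatic-sized box — sizes at which the full demo pipeline, the test suite
and the acceptance script each complete in seconds to a few minutes on one
CPU while keeping viable-pair counts in the tens of thousands.

## Known limitations

* The viability filter constrains (r, kq) from below only; estimates are
  prior-dependent and systematically above the feasibility boundary. With
  depletion priors unavailable, the generator's study conditions are chosen
  so the median is informative; on arbitrary real series the medians should
  be read together with their 95% intervals.
* No process error: all deviation from the deterministic recurrence is
  attributed to stress. Series with strong observation noise will leak
  noise into Cq_t.
* Gear rules assume single-gear vessels; gear switching within a trip or
  season yields majority labels, not mixtures.
* Hours-to-first-ping-cell gridding slightly favours the approach side of a
  tow at coarse resolutions.
* Synthetic tracks ignore coastlines and real port geometry; kappa measured
  on them validates the pipeline's internal consistency, not performance on
  real AIS data.
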