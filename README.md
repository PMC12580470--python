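# huntshift

Camera-trap analysis of how hunting and recreation displace a mammal
community in time: from raw trigger streams to independence-filtered events,
relative abundance and trail-use indices with bootstrap uncertainty,
solar-time activity curves across a disturbance grid, and a beta-binomial
regression of nocturnality on disturbance covariates.

The package is written for wildlife ecologists analyzing paired trail /
off-trail camera-trap designs in areas where lethal (hunting) and non-lethal
(hiking, biking) disturbance co-occur — typically protected areas with a
hunting zone along the border. Everything runs end-to-end on a built-in
synthetic study generator with known ground truth, so every stage is
testable without field data.

## What it computes

**Independent events.** A new event starts when a trigger's gap to the
immediately preceding trigger of the same camera × class is at least the
class threshold: 8 s for recreational activity (groups passing in quick
succession), 5 min for wildlife.

**Relative abundance index (RAI).** Events per 100 trapping days pooled over
a stratum's cameras; trapping days exclude outage/obstruction days. Trail
use relative to forest use is summarized by the trail index

```
trail index = ln( (RAI_trail + 1) / (RAI_forest + 1) )
```

positive when a species is recorded relatively more on trails. 95% CIs come
from resampling camera *locations* with replacement (B = 1000); a paired
location contributes both its trail and forest camera to each replicate, so
contrasts (forest vs trail, high vs low hunting effort) are differenced
replicate-by-replicate and called significant when the CI excludes zero.

**Hunting effort strata.** Months are classed by their share of the year's
successful hunting events: low < 5%, medium 5–10%, high > 10%. The two
high-effort hunting seasons (late autumn–winter of both study years) pool
into one stratum.

**Activity curves.** Clock times are mapped to solar radians (sunrise → π/2,
sunset → 3π/2, linearly between date-specific sun events) and each species'
events are split into a 24-subset grid — effort (3) × placement (2) ×
recreation intensity at the paired trail camera (median split, 2) ×
hunting-zone membership (2). Subsets with < 10 events are dropped. Each kept
subset gets a von Mises kernel density on the circle, with a plug-in
bandwidth and pointwise percentile envelopes from 1000 resamples.

**Nocturnality model.** Events are split at nautical twilight (sun altitude
−12°): night runs from evening dusk onset to morning dawn end. Night counts
per camera × effort are modelled as

```
n_night ~ BetaBinomial(n_total, mu·phi, (1 − mu)·phi)
logit(mu) = X beta
```

with the full three-way interaction of effort and placement with each
z-scored continuous covariate (distance to the hunting-zone border,
recreation RAI, visibility), fitted by maximum likelihood (optionally
ridge-penalized MAP, plus a Metropolis sampler for comparison). `mu` is the
nocturnality index; 0.5 means equal day/night activity.

## Worked example

```python
from huntshift import synthetic, report, events

config = synthetic.SimConfig(n_location_pairs=20, seed=42)
study = synthetic.simulate_study(config)
paths = synthetic.write_study(study, "quickstart")

cfg = report.RunConfig(
    detections=paths["detections"], deployments=paths["deployments"],
    hunting_calendar=paths["hunting"], outdir="quickstart/report",
    bootstrap_reps=1000, seed=1,
)
inputs = report.load_inputs(cfg)
ev = report.independent_events(cfg, inputs["detections"], inputs["calendar"])
td = events.compute_trap_days(inputs["deployments"], inputs["calendar"])
rai_tbl, diff_tbl = report.abundance_tables(
    cfg, ev["wildlife"], td, inputs["deployments"], inputs["calendar"])
```

For the synthetic red fox (a trail-favoring generator truth) under high
hunting effort this prints:

```
red fox, high hunting effort:
  RAI trail  = 4.83  [4.09, 5.59]
  RAI forest = 0.68  [0.43, 0.93]
  trail index = 1.25  [1.06, 1.45]
  forest - trail RAI = -4.16  [-4.97, -3.38]  significant=True
```

i.e. about 4.8 independent fox events per 100 trail trap-days against 0.7 in
the forest; the positive trail index with a CI above zero says the species
is recorded significantly more on trails.

The same pipeline is packaged as numbered drivers — `analysis/01_simulate.py`
through `analysis/05_nocturnality.py` — which generate the full 61-pair
study and write every table under `results/`, and as a CLI:

```
huntshift simulate --outdir results/synthetic --seed 7
huntshift all --detections results/synthetic/detections.csv \
    --deployments results/synthetic/deployments.csv \
    --hunting-calendar results/synthetic/hunting_calendar.csv \
    --outdir results/run
```

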