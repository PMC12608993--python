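# camoverlap

Spatiotemporal predator–prey overlap analysis for camera-trap surveys.

Camera traps record which species triggered which camera at what time.  From
those triggers, ecologists ask whether a predator and its potential prey are
active at the same *times of day*, use the same *places*, and how both
answers change along gradients of human disturbance, altitude and season.
`camoverlap` implements that whole workflow as a reusable, tested Python
pipeline:

1. **Independent detections.** Triggers of the same species at the same
   station within a quiet period (30 min by default) are collapsed to one
   detection, the unit of all counts.  Sampling effort is measured in
   trap-days, truncated at the last photo when a camera fails.
2. **Solar time.** Clock times are re-anchored so each day's sunrise maps to
   π/2 and sunset to 3π/2 (2π = 24 h), removing seasonal day-length changes
   from diel comparisons.
3. **Diel activity and temporal overlap.** Activity densities are estimated
   by von Mises kernel density estimation on the circle.  Pairwise temporal
   overlap is the coefficient of overlapping

   Δ = ∫ min(f̂(t), ĝ(t)) dt ∈ [0, 1],

   estimated by Δ̂₁ (grid integral, samples < 75) or Δ̂₄ (point-evaluation
   ratio estimator, samples ≥ 75), with 95% smoothed-bootstrap confidence
   intervals and a Watson–Wheeler two-sample test of distributional
   difference.
4. **Spatial overlap.** Per-station relative abundance (RAI = detections per
   100 trap-days) feeds Pianka's niche-overlap index

   O = Σᵢ pᵢqᵢ / √(Σᵢ pᵢ² · Σᵢ qᵢ²) ∈ [0, 1],

   with a paired site-bootstrap CI.
5. **Spatiotemporal overlap.** The product Δ × O, read as the probability of
   the predator encountering that prey in both time and space, reported per
   stratum: human-presence, distance-to-settlement, distance-to-road and
   altitude classes (quartile or explicit breaks) and warm (May–October) vs
   cold season.

Because real surveys are rarely shareable, the package ships a synthetic
survey generator (`camoverlap.synthetic`) with von Mises mixture activity,
log-linear covariate-dependent Poisson detection rates, and analytic oracles
(`true_delta`, `true_pianka`) so every estimator can be tested against known
truth.

## Worked example

Simulate a 60-station survey and run the full stratified analysis:

```bash
camoverlap simulate --seed 7 --out-dir survey --n-sites 60
# wrote 4764 detections at 60 sites to survey

camoverlap validate --detections survey/detections.csv \
    --sites survey/sites.csv --deployments survey/deployments.csv
# detections=4764 sites=60 deployments=60 rejects=0

cat > config.yaml <<'YAML'
bootstrap_reps: 200
predators: [civet]
prey: [nocturnal_rat, pallas_squirrel, bamboo_partridge]
YAML

camoverlap pipeline --detections survey/detections.csv \
    --sites survey/sites.csv --deployments survey/deployments.csv \
    --config config.yaml --out-dir results --seed 7
# wrote 45 result rows to results/results.csv
```

The results table (excerpt, rounded) contains one row per stratification
scheme × stratum × predator–prey pair:

```
        scheme  stratum             prey estimator  delta  delta_ci_low  delta_ci_high  ww_p  pianka  st_overlap
       overall      all    nocturnal_rat    Delta4  0.614         0.577          0.714 0.000   0.792       0.486
       overall      all  pallas_squirrel    Delta4  0.231         0.178          0.343 0.000   0.569       0.132
       overall      all bamboo_partridge    Delta4  0.171         0.132          0.266 0.000   0.620       0.106
human_presence     high    nocturnal_rat    Delta1  0.718         0.532          0.845 0.520   0.877       0.630
human_presence     high  pallas_squirrel    Delta1  0.245         0.139          0.392 0.000   0.655       0.161
```

Reading the first row: the nocturnal predator and the nocturnal rodents share
61% of their diel activity curve (CI 0.58–0.71), their activity patterns
still differ significantly (Watson–Wheeler p < 0.001), they co-occur
spatially with Pianka O = 0.79, and the combined spatiotemporal overlap is
0.49 — far higher than for either diurnal prey (0.13 and 0.11), as expected
for a predator hunting by night.  In the high human-presence stratum the
sample falls below 75 detections, so the pipeline switches to the Δ̂₁
estimator automatically; there the civet–rat comparison is no longer
significant (p = 0.52).

The same machinery is available as a library:

```python
import numpy as np
from camoverlap import ActivitySample, estimate_overlap

rng = np.random.default_rng(1)
a = ActivitySample("predator", rng.vonmises(np.pi, 2, 300) % (2 * np.pi))
b = ActivitySample("prey", rng.vonmises(0.0, 2, 300) % (2 * np.pi))
res = estimate_overlap(a, b, reps=1000, seed=1)
print(res.estimator, round(res.delta, 3), (res.ci_low, res.ci_high))
```

## Layout

| module | contents |
| --- | --- |
| `camoverlap.data_model` | detection/site/deployment records, independence filter, trap-days, RAI, CSV I/O |
| `camoverlap.solartime` | NOAA sunrise/sunset, anchored solar-time transform and its inverse |
| `camoverlap.activity` | circular KDE, Δ̂₁/Δ̂₄, smoothed bootstrap, Watson–Wheeler test |
| `camoverlap.spatial` | Pianka's index and site bootstrap |
| `camoverlap.strata` | quartile/explicit three-class gradients, warm/cold season |
| `camoverlap.interaction` | stratified pipeline and the Δ × O product |
| `camoverlap.synthetic` | survey generator, species presets, analytic oracles |
| `camoverlap.cli` | `camoverlap` command: validate / simulate / filter / activity / spatial / pipeline |

See `docs/methods.md` for the statistical details and design choices.
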