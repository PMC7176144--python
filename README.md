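# riversurvey

Distance-sampling density and abundance estimation for riverine dolphin
surveys, built around the mixed protocol used for Amazonian river dolphins
(*Inia* spp.) in large dammed rivers: cross-channel **line transects** with
a fitted detection function, shore-parallel **strip transects** with fixed
band-correction probabilities, a double-platform **g(0)** trackline
correction, and habitat × geographic-stratum abundance aggregation. A
synthetic survey generator with known truth makes every estimator testable
end to end.

It is a library for quantitative ecologists; a thin CLI (`riversurvey`)
wraps the pipeline for shell use.

## The estimators

Line-transect density per habitat *i* × stratum *j*:

    D_ij = n_ij · E(s)_ij · f(0) / (2 · L_ij · g(0))

with f(0) = 1/ESW from a half-normal or hazard-rate detection function
(covariates on the scale, AICc selection). Strip-transect density uses
shore-band counts weighted by fixed probabilities P1 = 0.960 (within 50 m
of the trackline) and P2 = 0.630 (beyond):

    D_ij = E(s)_ij · [n₀₋₅₀/P2 + n₅₀₋₁₀₀/P1 + n₁₀₀₋₁₅₀/P1 + n₁₅₀₋₂₀₀/P2] / (W · L_ij · g(0))

The trackline probability comes from the two-platform mark-recapture rule
g(0) = 1 − (n₀₁/n₁)². Abundance is N_ij = D_ij · A_ij, totals sum over
cells with CV(N_t) = Σ SE(N_ij) / Σ N_ij and log-normal intervals.
See `docs/methods.md` for assumptions and variance details.

## Worked example

```python
import riversurvey as rs

scenario = rs.demo_scenario(seed=5, effort_scale=2.0)   # dammed-river scenario
transects, sightings, truth = rs.simulate_survey(scenario)

result = rs.estimate_abundance(
    transects, sightings, scenario.areas, rs.AnalysisConfig(seed=5),
    candidates=("hr", "hr+pt", "hn", "hn+pt"),
)
print(result.best_model, round(result.g0.g0, 3))
table = result.tables["geographic_post"]
print(table.to_frame().to_string(index=False))
print(round(table.total_n), round(scenario.true_abundance()))
```

prints (abridged):

```
hn 0.776
      habitat    stratum   Es   n      L   Er    D      N   CV      A
    reservoir reservoir2 1.29 111  176.0 0.63 3.81 1302.0 0.16  342.0
river_channel   upstream 1.41  17  147.0 0.12 0.76  176.0 0.29  230.0
 river_margin   upstream 1.55  20  250.0 0.08 1.05   95.0 0.25   90.0
        TOTAL             NaN 157 1008.0 0.16 1.22 1721.0 0.21 1413.0
1721 1742
```

At this survey size AICc picks the parsimonious half-normal key (with
richer data the hazard-rate + platform model wins — see
`examples/02_fit_detection.py`), the estimated g(0) ≈ 0.78 means roughly
22% of groups on the line are missed by both platforms, and the stratified
total of 1721 individuals recovers the true simulated abundance of 1742. The `examples/`
scripts walk through each stage: simulation, detection fitting, g(0), strip
correction, stratified totals, and rebuilding the published 2014 Tocantins
River survey panels from their printed density × area arithmetic.

From the shell:

```bash
riversurvey run --out scratch/demo --seed 5
riversurvey estimate --effort effort.csv --sightings sightings.csv \
    --areas areas.csv --stratify both --out results/
```

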