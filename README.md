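# metkin — metastatic growth-kinetics analysis from serial CT volumetry

`metkin` is a Python toolkit for analysing the growth kinetics of individual
metastases measured on serial CT scans, built around the question of whether
kinetics — and especially the *heterogeneity* of kinetics across a patient's
metastases — predicts survival in advanced melanoma treated with BRAF
inhibitors.  It is aimed at biostatisticians and quantitative oncologists
working with per-lesion measurement tables (not images).

It provides, as composable library modules with a thin CLI:

* **Volumetry & kinetics** — ellipsoid volumes from three diameters,
  `V = (π/6)·d1·d2·d3`, and per-window indices: exponential growth rate
  `aExp = (ln V2 − ln V1)/Δt`, linear slope `aLin = (V2 − V1)/Δt`, relative
  volume change `RVC = (V2 − V1)/V1`, each computed on total burden and per
  lesion, with SD/range spread as heterogeneity measures.
* **Lethal-burden risk score** — the spontaneous course is modelled as
  `V(t) = V_BL·e^{aExp·t}` with death when `V(t)` reaches a critical burden
  `V_lethal`; the score `LB = aExp_global/(ln V_lethal − ln V_BL)` is the
  inverse predicted time to that crossing, and `V_lethal` is calibrated on
  an untreated reference cohort by grid search.
* **RECIST-1.1 proxy** — theoretical target selection (largest volumes, ≤5
  total, ≤2 per organ), progression calling (20%/5 mm diameter rule, new
  lesions, non-target volume doubling) and mixed-vs-uniform response labels.
* **Survival inference** — left-truncated Cox regression (Efron ties),
  likelihood-ratio model selection, martingale-residual diagnostics,
  covariate screening with correlation de-duplication, and multistate
  models (brain-metastasis and RECIST-progression structures) fitted as
  stratified Cox on counting-process data with transition-specific
  covariates.
* **Relative-risk survival tree** — LeBlanc–Crowley full-likelihood
  recursive partitioning (Poisson deviance on hazard-transformed follow-up,
  delayed entry supported) with seeded cross-validation pruning.
* **Synthetic cohorts** — a generative model of multi-lesion exponential
  growth with lesion-specific treatment effects, resistance, a lethal
  burden threshold, scan schedules, detection limits and censoring, with
  ground truth retained for parameter-recovery testing.

## Worked example

Simulate a 40-patient treated cohort and run every stage:

```python
import metkin as mk

cfg = mk.RunConfig(
    mode="braf", outdir="demo", seed=1,
    simulation=mk.SimulationConfig(n_patients=40, seed=11),
)
artifacts = mk.run_pipeline(cfg)
print(open(artifacts["report"]).read())
```

The report (abridged) reads:

```
# Kinetics analysis report (braf mode)

Patients with anchored timelines: 38
First-assessment PD: 9/38

## Cox screen
     covariate  log_transformed      coef       HR  HR_lower95  HR_upper95     p_lr
  rvc_range_bl             True  0.749901  2.116791    1.432770    3.127371 0.000020
            lb            False 13.031030      ...         ...         ... 0.000042
mixed_response            False  1.031372  2.804911    1.279501    6.148903 0.008136
  rvc_range_ir            False  0.087676  1.091635    0.971604    1.226493 0.181850

## Relative-risk tree
rvc_range_bl <= 1.134? RR=1.000 (n=38, events=28)
  * RR=0.185 (n=8, events=1)
  rvc_range_ir <= 1.786? RR=1.460 (n=30, events=27)
    ...
    * RR=3.201 (n=8, events=8)

Post-discontinuation global_rate: {'increased': 6, 'decreased': 4, 'stable': 1}
Post-discontinuation range_rate: {'increased': 8, 'decreased': 3}
```

Reading it: the range of per-lesion RVC before treatment (`rvc_range_bl`,
log-transformed automatically because it spans orders of magnitude) doubles
the death hazard per log-unit (HR 2.1, p = 2e-5), and the risk score `lb`
is strongly prognostic — in this synthetic cohort death is driven exactly by
burden crossing, so its effect is much stronger than could be seen
clinically.  The tree first separates an indolent low-heterogeneity group
(RR 0.19), then splits the rest on response heterogeneity at first
assessment, isolating a high-risk leaf (RR 3.2) — kinetics first, response
heterogeneity second.  After discontinuation, growth rates are not
systematically faster than before treatment, but their spread widens
(8 of 11 evaluable patients).

The same stages run from the shell:

```bash
metkin simulate --seed 11 --out demo_cohort
metkin kinetics --measurements demo_cohort/measurements.csv \
                --metadata demo_cohort/metadata.csv --out kinetics.csv
metkin run --config run.yaml
```

For an untreated reference cohort, `mode="historical"` runs the
pre-treatment window only and calibrates `V_lethal` over a geometric grid,
writing the model and the full criterion trace
(`lethal_burden.json`, `calibration_trace.csv`).

Real cohorts are read with `metkin.read_cohort(measurements_csv,
metadata_csv, dialect)`; a YAML `Dialect` maps arbitrary input column names
onto the canonical long-format schema (see `metkin/io.py`) and converts
day-based times.

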