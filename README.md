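# motornorms

Spatiotemporal motor-capacity analysis for markerless RGB-Depth camera
recordings: feature extraction from 25-landmark 3D skeleton time series,
normative tables, covariate-adjusted confound models, and z-score reports
for individual subjects.

## Who this is for

Clinical movement-analysis labs and researchers using consumer depth-camera
systems (Kinect-v2-class sensors at ~30 Hz, 1.5–4.5 m range) to assess
*motor capacity* — what a person can do in short standardized tests — in
conditions such as multiple sclerosis or Parkinson's disease. The package
implements the full analysis chain behind a normative database of 43
spatiotemporal parameters over six tasks:

| task | protocol | parameters |
|------|----------|------------|
| SCSW | short comfortable speed walk | gait speed, step length/width/duration, cadence, arm swing amplitude and symmetry |
| SMSW | short maximum speed walk | gait speed |
| SLW  | short line walk (tandem gait) | progression speed and variability, trunk roll sway, cadence, arm movement |
| SIP  | stepping in place (40 s) | knee amplitude, step/stance duration, cadence, knee symmetry, arrhythmicity |
| SAS  | standing up and sitting down | transition times, anterior-posterior chest deflection |
| POCO | postural control (20 s eyes open + 20 s closed) | pitch/roll/3D sway range and speed, six Romberg ratios |

## The model at the core

Individual values x are normalized against healthy-adult norms (n = 133,
ages 20–60) in two ways:

    z_raw = (x − x̄) / s

with x̄, s the normative sample mean and SD, and — for parameters whose
confound association generalizes — the residual z-score

    ε = x − (β₀ + β_age·age + β_sex·sex + β_height·height + β_weight·weight)
    z_res = ε / s_ε

where the β's come from an OLS fit of `parameter ~ age + sex + height +
weight + study` on the normative cohort (sex coded female 0 / male 1, study
effect-coded and never used for prediction) and s_ε is the residual SD.
A parameter earns a z_res model only if the mean held-out coefficient of
determination Rtest² = 1 − SSres/SStot over a repeated (100×) five-fold
cross-validation exceeds 0.1; in the packaged norms only SCSW step length
and step width pass this gate.

Because the underlying recordings are not public, the package ships (a) the
published normative statistics and coefficients as a scoring resource and
(b) a synthetic skeleton-motion generator with known ground truths that
exercises every extraction algorithm end to end.

## Worked example

```python
from motornorms import Subject, load_reference_resource, score_subject

norms = load_reference_resource()
patient = Subject(subject_id="patient-01", age=53, sex="male",
                  height=183, weight=73)
profile = score_subject({"scsw_step_length": 54.86, "scsw_step_width": 7.65},
                        patient, norms)
for key, z in profile.entries.items():
    print(key, round(z.z_raw, 2), None if z.z_res is None else round(z.z_res, 2))
```

prints

```
scsw_step_length -1.88 -3.05
scsw_step_width -0.93 -1.62
```

Step length sits 1.88 SD below the healthy mean; adjusting for this
subject's covariates (a tall man should take longer steps) moves the
deficit further out. `render_report(profile, "report.png")` draws the
lab-report chart with guides at z = 0, ±1, ±2.

More in `examples/`: synthetic-walk extraction with ground-truth recovery
(`extract_from_synthetic_walk.py`), building norms from a cohort with the
cross-validation gate (`build_norms_from_cohort.py`), and the seeded
end-to-end pipeline (`full_pipeline.py`). A thin CLI wraps the same stages:
`motornorms simulate|extract|qc|normative|confounds|score|run --help`.

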