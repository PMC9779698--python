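"""Score an individual's gait parameters against the packaged norms.

Reproduces the worked example of the normative database: a 53-year-old man
(183 cm, 73 kg) with multiple sclerosis walked with a step length of
54.86 cm and a step width of 7.65 cm. Raw z-scores place him relative to
the healthy group mean; the residual z-score for step width additionally
adjusts for age, sex, height and weight through the packaged regression
model.
"""

from motornorms import Subject, load_reference_resource, score_subject

norms = load_reference_resource()
patient = Subject(subject_id="patient-01", age=53, sex="male",
                  height=183, weight=73)
features = {"scsw_step_length": 54.86, "scsw_step_width": 7.65}

profile = score_subject(features, patient, norms)
for key, z in profile.entries.items():
    line = f"{key:22s} value {z.value:7.2f}   z_raw {z.z_raw:+.2f}"
    if z.z_res is not None:
        line += f"   z_res {z.z_res:+.2f} (preferred)"
    print(line)

print()
print("z_raw below -1 means more than one SD below the healthy mean;")
print("the covariate-adjusted z_res is the preferred score where a")
print("generalizable confound model exists (step length and step width).")
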