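"""Generate a synthetic comfortable-speed walk and extract its parameters.

The generator plants known ground truths (1.2 m/s, 110 steps/min, 10 cm
step width, 26 degree arm swing); the extractor recovers them from the
25-landmark skeleton stream after tilt correction, resampling and
filtering — the recovery accuracy shown here is the package's central
self-check.
"""

from motornorms import WalkTruth, extract_scsw, gen_walk_recording, preprocess

truth = WalkTruth(speed=1.2, cadence=110, step_width=0.10,
                  arm_amplitude_left=26.0, arm_amplitude_right=26.0,
                  noise_sd=0.003, seed=42)
recording = gen_walk_recording(truth, protocol="comfortable")
features = extract_scsw(preprocess(recording))

print(f"{'parameter':28s} {'extracted':>10s} {'truth':>10s}")
rows = [
    ("gait speed [m/s]", "scsw_gait_speed", truth.speed),
    ("step length [cm]", "scsw_step_length", 100 * 60 * truth.speed / truth.cadence),
    ("step width [cm]", "scsw_step_width", 100 * truth.step_width),
    ("step duration [s]", "scsw_step_duration", 60 / truth.cadence),
    ("gait cadence [steps/min]", "scsw_gait_cadence", truth.cadence),
    ("arm amplitude [deg]", "scsw_arm_angular_amplitude", 26.0),
    ("arm symmetry angle [n.u.]", "scsw_arm_symmetry_angle", 0.0),
]
for label, key, expected in rows:
    print(f"{label:28s} {features.value(key):10.3f} {expected:10.3f}")
print("\nExtracted values track the planted truths; residual deviations come")
print("from the 3 mm landmark noise and the 30 Hz frame grid.")
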