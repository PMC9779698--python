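"""Generator construction checks: the synthetic recordings must embody the
ground truths they claim, verified by independent oracles on the raw
trajectories (not via the feature extractors)."""

import math

import numpy as np
import pytest

from motornorms import (CohortSpec, PlantedEffect, PocoSegment, PocoTruth,
                        SasTruth, SipTruth, Subject, TandemTruth, WalkTruth,
                        gen_cohort, gen_poco_recording, gen_sas_recording,
                        gen_sip_recording, gen_tandem_recording,
                        gen_walk_recording)


def test_same_seed_is_bit_identical():
    a = gen_walk_recording(WalkTruth(seed=7, noise_sd=0.004))
    b = gen_walk_recording(WalkTruth(seed=7, noise_sd=0.004))
    assert np.array_equal(a.pos, b.pos) and np.array_equal(a.t, b.t)
    c = gen_walk_recording(WalkTruth(seed=8, noise_sd=0.004))
    assert not np.array_equal(a.pos, c.pos)


def test_walk_pelvis_steady_speed():
    truth = WalkTruth(speed=1.2, cadence=110, seed=0)
    rec = gen_walk_recording(truth)
    z = rec.joint("spine_base")[:, 2]
    # steady phase: after the two ramp steps, before the end
    t_ramp = 2 * 60.0 / truth.cadence
    m = (rec.t > t_ramp) & (z > 1.6)
    tt, zz = rec.t[m], z[m]
    speed = (zz[0] - zz[-1]) / (tt[-1] - tt[0])
    assert speed == pytest.approx(1.2, abs=0.01)


def test_walk_ankle_crossing_rate_matches_cadence():
    # event-count oracle: zero crossings of the signed left-minus-right
    # ankle depth difference occur once per step
    truth = WalkTruth(speed=1.2, cadence=110, seed=0)
    rec = gen_walk_recording(truth)
    d = rec.joint("ankle_left")[:, 2] - rec.joint("ankle_right")[:, 2]
    t_ramp = 2 * 60.0 / truth.cadence
    m = rec.t > t_ramp
    tt, dd = rec.t[m], d[m]
    sign = np.sign(dd)
    cross_times = tt[1:][sign[1:] != sign[:-1]]
    assert cross_times.size >= 3
    rate = 1.0 / np.mean(np.diff(cross_times))
    assert rate == pytest.approx(110 / 60, rel=0.05)


def test_walk_rejects_bad_parameters():
    with pytest.raises(ValueError):
        WalkTruth(speed=0.0)
    with pytest.raises(ValueError):
        gen_walk_recording(WalkTruth(seed=0), protocol="sprint")


def test_tandem_zero_roll_keeps_trunk_over_pelvis():
    rec = gen_tandem_recording(TandemTruth(roll_amplitude=0.0, seed=0))
    lateral = rec.joint("spine_shoulder")[:, 0] - rec.joint("spine_base")[:, 0]
    assert np.max(np.abs(lateral)) < 1e-12


def test_tandem_constant_progression_speed():
    rec = gen_tandem_recording(TandemTruth(speed=0.35, speed_cov=0.0, seed=0))
    z = rec.joint("spine_base")[:, 2]
    assert (z[0] - z[-1]) / (rec.t[-1] - rec.t[0]) == pytest.approx(0.35, rel=0.01)


def test_tandem_ankle_oscillation_period():
    # pooled left/right ankle-relative-to-hip peaks alternate every 60/cadence s
    truth = TandemTruth(cadence=72, seed=0)
    rec = gen_tandem_recording(truth)
    times = []
    for side in ("left", "right"):
        rel = rec.joint(f"hip_{side}")[:, 2] - rec.joint(f"ankle_{side}")[:, 2]
        from scipy.signal import find_peaks

        idx, _ = find_peaks(rel, prominence=0.1)
        times.extend(rec.t[idx])
    times = np.sort(times)
    assert np.mean(np.diff(times)) == pytest.approx(60.0 / 72, rel=0.02)


def test_sip_frame_count_and_symmetric_truth():
    rec = gen_sip_recording(SipTruth(duration=40.0, seed=0))
    assert rec.n_frames == pytest.approx(1200, abs=2)
    truth = rec.meta["truth"]
    assert truth["knee_amplitude_left"] == truth["knee_amplitude_right"]


@pytest.mark.parametrize("seed", range(5))
def test_sip_stride_jitter_hits_target_cov(seed):
    # 40 s at cadence 100 gives ~33 strides/side: the sample CoV of the
    # constructed stride times stays within [4, 8]% for a planted 6%
    rec = gen_sip_recording(SipTruth(stride_cov=0.06, seed=seed))
    for side in ("left", "right"):
        strides = np.diff(rec.meta["truth"][f"peak_times_{side}"])
        cov = strides.std(ddof=1) / strides.mean()
        assert 0.04 <= cov <= 0.08


def test_sas_threshold_truth_matches_numeric_oracle():
    # brute-force oracle: evaluate the sin^2 velocity profile on a fine
    # grid and measure the 10%-of-peak inter-threshold interval
    truth = SasTruth(up_duration=1.5, seed=0)
    tt = np.linspace(0.0, 1.5, 200001)
    v = np.sin(np.pi * tt / 1.5) ** 2
    above = tt[v >= 0.1 * v.max()]
    numeric = above[-1] - above[0]
    assert truth.detected_duration(1.5) == pytest.approx(numeric, abs=1e-4)
    assert truth.detected_duration(1.5) == pytest.approx(1.19, abs=0.01)


def test_sas_ap_deflection_constructed_range():
    truth = SasTruth(ap_deflection_up=0.37, seed=0)
    rec = gen_sas_recording(truth)
    m = (rec.t >= truth.lead_in) & (rec.t <= truth.lead_in + truth.up_duration)
    z = rec.joint("spine_shoulder")[m, 2]
    assert z.max() - z.min() == pytest.approx(0.37, abs=0.005)


def test_poco_sinusoid_closed_forms_on_raw_geometry():
    # oracle on the generated pelvis geometry: recover the pitch angle and
    # check range = 2A and mean |angular velocity| = 4 f A
    seg = PocoSegment(pitch_amplitude=0.5, pitch_freq=0.25,
                      roll_amplitude=0.0, roll_freq=0.2)
    rec = gen_poco_recording(PocoTruth(open_segment=seg, closed_segment=seg,
                                       seed=0))
    pelvis = rec.joint("spine_base")
    ankle_mid = 0.5 * (rec.joint("ankle_left") + rec.joint("ankle_right"))
    s = pelvis - ankle_mid
    pitch = np.degrees(np.arctan2(s[:, 2], s[:, 1]))
    assert pitch.max() - pitch.min() == pytest.approx(1.0, rel=0.01)
    dt = 1.0 / rec.nominal_rate
    speed = np.mean(np.abs(np.diff(pitch))) / dt
    assert speed == pytest.approx(4 * 0.25 * 0.5, rel=0.02)


def test_poco_identical_segments_give_unit_romberg_truth():
    seg = PocoSegment()
    rec = gen_poco_recording(PocoTruth(open_segment=seg, closed_segment=seg,
                                       seed=0))
    t = rec.meta["truth"]
    for k in t["open"]:
        assert t["closed"][k] / t["open"][k] == pytest.approx(1.0)


def test_cohort_covariates_match_target_distribution():
    spec = CohortSpec(seed=11)
    subjects, truths = gen_cohort(spec)
    assert len(subjects) == 133
    ages = np.array([s.age for s in subjects])
    assert abs(ages.mean() - 36.83) < 3.0
    assert ages.min() >= 20 and ages.max() <= 60
    heights = np.array([s.height for s in subjects])
    assert abs(heights.mean() - 172.9) < 4.0
    frac_female = np.mean([s.sex == "female" for s in subjects])
    assert 0.4 < frac_female < 0.7
    assert truths.shape == (133, 43)
    assert np.isfinite(truths.to_numpy()).all()


def test_cohort_is_deterministic_under_seed():
    a = gen_cohort(CohortSpec(seed=3))
    b = gen_cohort(CohortSpec(seed=3))
    assert [s.subject_id for s in a[0]] == [s.subject_id for s in b[0]]
    assert np.array_equal(a[1].to_numpy(), b[1].to_numpy())
    assert all(sa.age == sb.age and sa.height == sb.height
               for sa, sb in zip(a[0], b[0]))


def test_cohort_planted_effect_enters_truths():
    eff = PlantedEffect(beta0=6.164, beta_age=0.038, beta_sex=1.301,
                        beta_height=-0.020, beta_weight=0.076,
                        residual_sd=0.01)
    spec = CohortSpec(planted_effects={"scsw_step_width": eff}, seed=5)
    subjects, truths = gen_cohort(spec)
    pred = np.array([eff.predict(s) for s in subjects])
    resid = truths["scsw_step_width"].to_numpy() - pred
    assert np.abs(resid).max() < 0.05  # only the tiny residual noise remains
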