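"""Feature extraction: generator-oracle recovery for all six tasks,
closed-form scalar utilities, and geometric invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motornorms import (FeatureConfig, PocoSegment, PocoTruth, SasTruth,
                        SipTruth, SkeletonRecording, TandemTruth, WalkTruth,
                        coefficient_of_variation, detect_walk_steps,
                        extract_features, extract_poco, extract_sas,
                        extract_scsw, extract_sip, extract_slw, extract_smsw,
                        gen_poco_recording, gen_sas_recording,
                        gen_sip_recording, gen_tandem_recording,
                        gen_walk_recording, preprocess, romberg_ratio,
                        symmetry_angle)


# ---------------------------------------------------------------------------
# scalar utilities (closed forms)
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("left,right,expected", [
    (1.0, 1.0, 0.0),
    (2.0, 1.0, abs(45 - math.degrees(math.atan2(2, 1))) / 90),  # 0.2048
    (30.0, 20.0, abs(45 - math.degrees(math.atan(1.5))) / 90),  # ~0.126
    (0.20, 0.10, abs(45 - math.degrees(math.atan(2.0))) / 90),  # ~0.205
    (1.0, 0.0, 0.5),
    (0.0, 1.0, 0.5),
])
def test_symmetry_angle_closed_forms(left, right, expected):
    assert symmetry_angle(left, right) == pytest.approx(expected, abs=1e-9)
    assert symmetry_angle(2.0, 1.0) == pytest.approx(0.2048, abs=5e-4)


def test_symmetry_angle_undefined_for_double_zero():
    with pytest.raises(ValueError):
        symmetry_angle(0.0, 0.0)


@given(st.floats(0.001, 1e3), st.floats(0.001, 1e3))
@settings(max_examples=50, deadline=None)
def test_symmetry_angle_bounded_and_symmetric(a, b):
    s = symmetry_angle(a, b)
    assert 0.0 <= s <= 0.5
    assert s == pytest.approx(symmetry_angle(b, a), abs=1e-12)
    if a == b:
        assert s == 0.0


def test_romberg_ratio():
    assert romberg_ratio(0.30, 0.20) == pytest.approx(1.5)
    assert romberg_ratio(0.47, 0.47) == 1.0
    with pytest.raises(ValueError):
        romberg_ratio(0.47, 0.0)


def test_coefficient_of_variation_matches_reported_convention():
    # a two-point sample with mean 1.16 and sample SD 0.17, the published
    # gait-speed row: CoV = 0.17/1.16 = 0.1466, printed as 0.15
    half = 0.17 / math.sqrt(2)
    sample = [1.16 - half, 1.16 + half]
    cov = coefficient_of_variation(sample)
    assert cov == pytest.approx(0.17 / 1.16, abs=1e-12)
    assert round(cov, 2) == 0.15


@given(st.lists(st.floats(0.1, 10.0), min_size=2, max_size=30),
       st.floats(0.1, 100.0))
@settings(max_examples=50, deadline=None)
def test_coefficient_of_variation_scale_invariant(values, c):
    v = np.asarray(values)
    if v.mean() > 1e-6:
        assert coefficient_of_variation(c * v) == pytest.approx(
            coefficient_of_variation(v), rel=1e-9)


def test_cov_degenerate_cases():
    assert coefficient_of_variation([3.0, 3.0, 3.0]) == 0.0
    with pytest.raises(ValueError):
        coefficient_of_variation([1.0])
    with pytest.raises(ValueError):
        coefficient_of_variation([-1.0, 1.0])


# ---------------------------------------------------------------------------
# step detection
# ---------------------------------------------------------------------------


def test_stationary_ankles_give_no_events(sip_prep):
    # stepping-in-place has no ankle progression along a walk axis, but a
    # proper degenerate check needs a walk-task recording with still feet
    rec = gen_walk_recording(WalkTruth(seed=0))
    pos = rec.pos.copy()
    from motornorms.joints import JOINT_INDEX

    for j in ("ankle_left", "ankle_right"):
        pos[:, JOINT_INDEX[j], :] = pos[0, JOINT_INDEX[j], :]
    frozen = rec.copy_with(pos=pos)
    assert detect_walk_steps(preprocess(frozen)) == []


def test_constructed_in_band_placements_are_all_detected():
    truth = WalkTruth(speed=0.5, cadence=120, seed=0)
    rec = gen_walk_recording(truth)
    assert rec.meta["truth"]["n_in_band_placements"] == 8
    events = detect_walk_steps(preprocess(rec))
    assert len(events) == 8
    assert all(a.side != b.side for a, b in zip(events, events[1:]))


@pytest.mark.parametrize("seed", range(10))
def test_step_detection_robust_to_landmark_noise(seed):
    truth = WalkTruth(speed=1.0, cadence=105, noise_sd=0.005, seed=seed)
    rec = gen_walk_recording(truth)
    clean = gen_walk_recording(WalkTruth(speed=1.0, cadence=105, seed=seed))
    n_expected = len(detect_walk_steps(preprocess(clean)))
    n_noisy = len(detect_walk_steps(preprocess(rec)))
    assert n_noisy == n_expected


def test_too_few_steps_marks_parameters_absent():
    # a very short walk: pelvis barely crosses the band start
    truth = WalkTruth(speed=1.2, cadence=110, seed=0, z_start=4.7, z_end=3.9)
    rec = gen_walk_recording(truth)
    fv = extract_scsw(preprocess(rec))
    assert not fv["scsw_step_length"].present
    assert fv["scsw_step_length"].reason == "insufficient steps"


# ---------------------------------------------------------------------------
# generator-oracle recovery (noise-free)
# ---------------------------------------------------------------------------


def test_scsw_recovery(scsw_prep, scsw_rec):
    truth = scsw_rec.meta["truth"]
    fv = extract_scsw(scsw_prep)
    assert fv.value("scsw_gait_speed") == pytest.approx(truth["speed"], rel=0.03)
    assert fv.value("scsw_step_length") == pytest.approx(
        truth["step_length_cm"], rel=0.05)
    assert fv.value("scsw_step_width") == pytest.approx(
        truth["step_width_cm"], rel=0.05)
    assert fv.value("scsw_gait_cadence") == pytest.approx(
        truth["cadence"], abs=2.0)
    assert fv.value("scsw_step_duration") == pytest.approx(
        truth["step_duration"], rel=0.05)
    assert fv.value("scsw_arm_angular_amplitude") == pytest.approx(26.0, rel=0.05)
    assert fv.value("scsw_arm_symmetry_angle") == pytest.approx(0.0, abs=0.01)


def test_scsw_asymmetric_arms():
    truth = WalkTruth(arm_amplitude_left=30.0, arm_amplitude_right=20.0, seed=2)
    fv = extract_scsw(preprocess(gen_walk_recording(truth)))
    expected = abs(45 - math.degrees(math.atan(1.5))) / 90  # ~0.1257
    assert fv.value("scsw_arm_symmetry_angle") == pytest.approx(expected, abs=0.02)


def test_smsw_speed_only_and_agrees_with_scsw_estimator():
    rec = gen_walk_recording(WalkTruth(speed=1.66, cadence=130, seed=2),
                             protocol="maximum")
    prep = preprocess(rec)
    fv = extract_smsw(prep)
    assert set(fv) == {"smsw_gait_speed"}
    assert fv.value("smsw_gait_speed") == pytest.approx(1.66, rel=0.03)
    # shared estimator: the comfortable-walk extractor sees the same speed
    prep_c = prep.copy_with(task="SCSW")
    assert extract_scsw(prep_c).value("scsw_gait_speed") == pytest.approx(
        fv.value("smsw_gait_speed"), rel=1e-6)


def test_smsw_absent_when_never_in_band():
    rec = gen_walk_recording(WalkTruth(speed=1.0, cadence=110, seed=0,
                                       z_start=4.8, z_end=4.3),
                             protocol="maximum")
    fv = extract_smsw(preprocess(rec))
    assert not fv["smsw_gait_speed"].present
    assert fv["smsw_gait_speed"].reason


def test_slw_recovery(slw_rec):
    fv = extract_slw(preprocess(slw_rec))
    truth = slw_rec.meta["truth"]
    assert fv.value("slw_progression_speed") == pytest.approx(0.35, rel=0.03)
    assert fv.value("slw_progression_variability") == pytest.approx(0.0, abs=0.02)
    assert fv.value("slw_roll_sway_variability") == pytest.approx(
        truth["roll_variability"], rel=0.05)
    assert fv.value("slw_roll_sway_speed") == pytest.approx(
        truth["roll_speed"], rel=0.05)
    assert fv.value("slw_line_walk_cadence") == pytest.approx(72.0, abs=2.0)


def test_slw_speed_modulation_recovers_cov():
    rec = gen_tandem_recording(TandemTruth(speed=0.35, speed_cov=0.2, seed=3))
    fv = extract_slw(preprocess(rec))
    assert fv.value("slw_progression_variability") == pytest.approx(0.2, abs=0.03)


def test_slw_rigid_arms_give_zero_arm_movement():
    rec = gen_tandem_recording(TandemTruth(arm_amplitude=0.0, seed=0))
    fv = extract_slw(preprocess(rec))
    assert fv.value("slw_arm_variability") == pytest.approx(0.0, abs=0.01)
    assert fv.value("slw_arm_speed") == pytest.approx(0.0, abs=0.05)


def test_slw_arm_oscillation_matches_folded_sinusoid_oracle():
    # the arm angle against the mean direction is |A sin|; its SD has the
    # closed form A*sqrt(1/2 - (2/pi)^2)
    amp = 8.0
    rec = gen_tandem_recording(TandemTruth(arm_amplitude=amp, arm_freq=0.6,
                                           seed=1))
    fv = extract_slw(preprocess(rec))
    expected_sd = amp * math.sqrt(0.5 - (2 / math.pi) ** 2)
    assert fv.value("slw_arm_variability") == pytest.approx(expected_sd, rel=0.10)
    assert fv.value("slw_arm_speed") == pytest.approx(4 * 0.6 * amp, rel=0.10)


def test_sip_recovery(sip_prep, sip_rec):
    truth = sip_rec.meta["truth"]
    fv = extract_sip(sip_prep)
    assert fv.value("sip_knee_amplitude") == pytest.approx(0.18, rel=0.05)
    assert fv.value("sip_stepping_cadence") == pytest.approx(100.0, abs=2.0)
    assert fv.value("sip_knee_symmetry_angle") == pytest.approx(0.0, abs=0.01)
    assert fv.value("sip_arrhythmicity") < 1.0
    assert fv.value("sip_step_duration") == pytest.approx(
        truth["step_duration"], rel=0.05)
    assert fv.value("sip_stance_duration") == pytest.approx(
        truth["stance_duration"], rel=0.10)


@pytest.mark.parametrize("seed", range(5))
def test_sip_arrhythmicity_recovers_planted_jitter(seed):
    rec = gen_sip_recording(SipTruth(stride_cov=0.06, seed=seed))
    fv = extract_sip(preprocess(rec))
    assert 4.0 <= fv.value("sip_arrhythmicity") <= 8.0


def test_sip_asymmetric_amplitudes():
    rec = gen_sip_recording(SipTruth(knee_amplitude_left=0.20,
                                     knee_amplitude_right=0.10, seed=1))
    fv = extract_sip(preprocess(rec))
    expected = abs(45 - math.degrees(math.atan(2.0))) / 90
    assert fv.value("sip_knee_symmetry_angle") == pytest.approx(expected, abs=0.02)


def test_sas_recovery(sas_rec):
    truth = sas_rec.meta["truth"]
    fv = extract_sas(preprocess(sas_rec))
    two_frames = 2.0 / sas_rec.nominal_rate
    assert fv.value("sas_transition_time_up") == pytest.approx(
        truth["detected_up_duration"], abs=two_frames)
    assert fv.value("sas_transition_time_down") == pytest.approx(
        truth["detected_down_duration"], abs=two_frames)
    assert fv.value("sas_ap_deflection_up") == pytest.approx(0.37, abs=0.01)
    assert fv.value("sas_ap_deflection_down") == pytest.approx(0.40, abs=0.01)


def test_sas_motionless_recording_absent():
    rec = gen_sas_recording(SasTruth(seed=0))
    pos = np.tile(rec.pos[0], (rec.n_frames, 1, 1))
    frozen = rec.copy_with(pos=pos)
    fv = extract_sas(preprocess(frozen))
    assert all(not fv[k].present for k in fv)
    assert all(fv[k].reason for k in fv)


def test_poco_recovery(poco_rec):
    fv = extract_poco(preprocess(poco_rec))
    truth = poco_rec.meta["truth"]
    for label in ("open", "closed"):
        for meas, key in (("pitch_range", f"poco_pitch_range_{label}"),
                          ("pitch_speed", f"poco_pitch_speed_{label}"),
                          ("roll_range", f"poco_roll_range_{label}"),
                          ("roll_speed", f"poco_roll_speed_{label}")):
            assert fv.value(key) == pytest.approx(truth[label][meas], rel=0.02), key
    # closed amplitudes are 1.5x open: range-based Romberg ratios ~ 1.5
    assert fv.value("poco_rr_pitch_range") == pytest.approx(1.5, rel=0.02)
    assert fv.value("poco_rr_roll_range") == pytest.approx(1.5, rel=0.02)


def test_poco_identical_segments_unit_romberg():
    seg = PocoSegment(pitch_amplitude=0.5, pitch_freq=0.25,
                      roll_amplitude=0.4, roll_freq=0.2)
    rec = gen_poco_recording(PocoTruth(open_segment=seg, closed_segment=seg,
                                       seed=0))
    fv = extract_poco(preprocess(rec))
    for key in ("poco_rr_pitch_range", "poco_rr_roll_range",
                "poco_rr_pitch_speed", "poco_rr_roll_speed",
                "poco_rr_3d_range", "poco_rr_3d_speed"):
        assert fv.value(key) == pytest.approx(1.0, abs=0.02), key


def test_poco_zero_open_sway_gives_tiny_ranges():
    zero = PocoSegment(pitch_amplitude=0.0, roll_amplitude=0.0)
    rec = gen_poco_recording(PocoTruth(open_segment=zero,
                                       closed_segment=PocoSegment(), seed=0))
    fv = extract_poco(preprocess(rec))
    # filter leakage at the segment boundary keeps this from exact zero
    assert fv.value("poco_pitch_range_open") == pytest.approx(0.0, abs=0.01)
    assert fv.value("poco_pitch_speed_open") == pytest.approx(0.0, abs=0.01)


def test_poco_static_subject_gives_absent_ratios():
    zero = PocoSegment(pitch_amplitude=0.0, roll_amplitude=0.0)
    rec = gen_poco_recording(PocoTruth(open_segment=zero, closed_segment=zero,
                                       seed=0))
    fv = extract_poco(preprocess(rec))
    assert fv.value("poco_pitch_range_open") <= 1e-9
    assert not fv["poco_rr_pitch_range"].present
    assert fv["poco_rr_pitch_range"].reason == "degenerate denominator"


# ---------------------------------------------------------------------------
# invariances
# ---------------------------------------------------------------------------


def _translate(rec: SkeletonRecording, offset) -> SkeletonRecording:
    return rec.copy_with(pos=rec.pos + np.asarray(offset))


def _rotate_about_vertical(rec: SkeletonRecording, deg: float) -> SkeletonRecording:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    rot = np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
    return rec.copy_with(pos=rec.pos @ rot.T)


def _present_values(fv):
    return {k: v.value for k, v in fv.items() if v.present}


@pytest.mark.parametrize("task_fixture", ["sip", "poco"])
def test_translation_invariance_stationary_tasks(task_fixture, sip_rec, poco_rec):
    rec = {"sip": sip_rec, "poco": poco_rec}[task_fixture]
    base = _present_values(extract_features(preprocess(rec)))
    moved = _present_values(extract_features(preprocess(
        _translate(rec, [0.7, 0.0, -0.4]))))
    assert set(moved) == set(base)
    for k in base:
        assert moved[k] == pytest.approx(base[k], rel=1e-4, abs=1e-6), k


def test_translation_invariance_walk_vertical(scsw_rec):
    # the walk measurement band is anchored to the sensor distance, so only
    # translations that preserve horizontal distances leave step geometry
    # untouched; vertical offsets must change nothing
    base = _present_values(extract_scsw(preprocess(scsw_rec)))
    moved = _present_values(extract_scsw(preprocess(
        _translate(scsw_rec, [0.0, 0.35, 0.0]))))
    assert set(moved) == set(base)
    for k in base:
        assert moved[k] == pytest.approx(base[k], rel=1e-4, abs=1e-6), k


@pytest.mark.parametrize("fixture_name", ["sip", "sas", "poco"])
def test_rotation_about_vertical_invariance(fixture_name, sip_rec, sas_rec,
                                            poco_rec):
    rec = {"sip": sip_rec, "sas": sas_rec, "poco": poco_rec}[fixture_name]
    base = _present_values(extract_features(preprocess(rec)))
    rotated = _present_values(extract_features(preprocess(
        _rotate_about_vertical(rec, 25.0))))
    assert set(rotated) == set(base)
    for k in base:
        assert rotated[k] == pytest.approx(base[k], rel=1e-3, abs=1e-5), k


def test_walk_parameters_rederived_along_rotated_walk_axis(scsw_rec):
    base = _present_values(extract_scsw(preprocess(scsw_rec)))
    rotated = _present_values(extract_scsw(preprocess(
        _rotate_about_vertical(scsw_rec, 30.0))))
    for k in base:
        assert rotated[k] == pytest.approx(base[k], rel=1e-3), k


def test_poco_time_reversal_invariance(poco_rec):
    prep = preprocess(poco_rec)
    fv = extract_poco(prep)
    rev = prep.copy_with(
        t=prep.t[-1] - prep.t[::-1], pos=prep.pos[::-1].copy(),
        valid=prep.valid[::-1].copy(),
    )
    # reversal swaps the segments; a half-frame epsilon keeps the boundary
    # frame assigned to the same segment in both directions
    dt = 1.0 / prep.nominal_rate
    fv_r = extract_poco(
        rev,
        segment_boundary=prep.t[-1] - prep.meta["segment_boundary"] + 0.5 * dt)
    swap = {"open": "closed", "closed": "open"}
    for label in ("open", "closed"):
        for stem in ("pitch_range", "roll_range", "pitch_speed", "roll_speed"):
            a, b = stem.rsplit("_", 1)
            key = f"poco_{a}_{b}_{label}"
            key_swapped = f"poco_{a}_{b}_{swap[label]}"
            assert fv_r.value(key_swapped) == pytest.approx(
                fv.value(key), rel=1e-3), key


def test_units_and_ranges_are_physical(scsw_prep, sip_prep, poco_rec):
    for fv in (extract_scsw(scsw_prep), extract_sip(sip_prep),
               extract_poco(preprocess(poco_rec))):
        for k, v in fv.items():
            if not v.present:
                continue
            if "symmetry" in k:
                assert 0.0 <= v.value <= 0.5
            elif "rr_" in k:
                assert v.value > 0
            elif any(s in k for s in ("speed", "range", "duration", "cadence",
                                      "amplitude", "length", "width")):
                assert v.value >= 0
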