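"""Synthetic skeleton-motion generator for the six motor tasks.

Generates recordings with *known* ground-truth spatiotemporal parameters, the
central oracle for the feature-extraction algorithms, plus whole cohorts with
realistic covariate distributions and optionally planted linear confound
effects. The kinematic models are deliberately minimal — rigid trunk,
sinusoidal limb oscillations, smooth-step transitions — because the target is
exercising extraction and event detection, not biomechanical realism.

All generators are pure functions of (truth, seed) and reproduce bit-exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .joints import JOINT_INDEX, N_JOINTS
from .types import SkeletonRecording, Subject, Task

# default standing-pose joint offsets relative to the pelvic center, meters,
# (lateral, vertical, depth) with the subject facing the sensor (+x = their
# left, depth measured away from the sensor)
_POSE: dict[str, tuple[float, float, float]] = {
    "spine_base": (0.0, 0.0, 0.0),
    "spine_mid": (0.0, 0.22, 0.0),
    "spine_shoulder": (0.0, 0.45, 0.0),
    "neck": (0.0, 0.52, 0.0),
    "head": (0.0, 0.65, 0.0),
    "shoulder_left": (0.18, 0.43, 0.0),
    "elbow_left": (0.20, 0.12, 0.0),
    "wrist_left": (0.21, -0.15, 0.0),
    "hand_left": (0.21, -0.22, 0.0),
    "hand_tip_left": (0.21, -0.28, 0.0),
    "thumb_left": (0.18, -0.22, 0.0),
    "shoulder_right": (-0.18, 0.43, 0.0),
    "elbow_right": (-0.20, 0.12, 0.0),
    "wrist_right": (-0.21, -0.15, 0.0),
    "hand_right": (-0.21, -0.22, 0.0),
    "hand_tip_right": (-0.21, -0.28, 0.0),
    "thumb_right": (-0.18, -0.22, 0.0),
    "hip_left": (0.09, -0.05, 0.0),
    "hip_right": (-0.09, -0.05, 0.0),
    "knee_left": (0.10, -0.50, 0.0),
    "knee_right": (-0.10, -0.50, 0.0),
    "ankle_left": (0.11, -0.90, 0.0),
    "ankle_right": (-0.11, -0.90, 0.0),
    "foot_left": (0.11, -0.95, -0.10),
    "foot_right": (-0.11, -0.95, -0.10),
}

PELVIS_HEIGHT = 1.0  # m, default standing pelvic-center height


def _base_body(n: int, pelvis: np.ndarray) -> np.ndarray:
    """(n, 25, 3) body with every joint at its standing offset from pelvis."""
    pos = np.empty((n, N_JOINTS, 3))
    for name, off in _POSE.items():
        pos[:, JOINT_INDEX[name], :] = pelvis + np.asarray(off)
    return pos


def _finish(
    t: np.ndarray,
    pos: np.ndarray,
    task: Task,
    truth_meta: dict,
    noise_sd: float,
    frame_drop_rate: float,
    rng: np.random.Generator,
    rate: float,
    sensor_pitch: float = 0.0,
    repetition_index: int = 1,
) -> SkeletonRecording:
    """Apply sensor pitch, landmark noise and frame drops; build the recording."""
    if sensor_pitch != 0.0:
        # the camera is tilted by `sensor_pitch`; recorded coordinates are the
        # world coordinates rotated into the camera frame (inverse of the
        # preprocessing tilt correction)
        a = np.deg2rad(sensor_pitch)
        c, s = np.cos(a), np.sin(a)
        rot = np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])
        pos = pos @ rot.T
    if noise_sd > 0:
        pos = pos + rng.normal(0.0, noise_sd, size=pos.shape)
    keep = np.ones(len(t), dtype=bool)
    if frame_drop_rate > 0:
        keep[1:-1] = rng.random(len(t) - 2) >= frame_drop_rate
    t, pos = t[keep], pos[keep]
    valid = np.ones((len(t), N_JOINTS), dtype=bool)
    return SkeletonRecording(
        t=t,
        pos=pos,
        valid=valid,
        task=task,
        nominal_rate=rate,
        repetition_index=repetition_index,
        sensor_pitch=sensor_pitch,
        meta={"truth": truth_meta},
    )


def _smoothstep(u: np.ndarray) -> np.ndarray:
    """Monotone 0->1 profile with zero end velocities (sin^2 velocity shape)."""
    return u - np.sin(2 * np.pi * u) / (2 * np.pi)


# ---------------------------------------------------------------------------
# walks (SCSW / SMSW)
# ---------------------------------------------------------------------------


@dataclass
class WalkTruth:
    """Ground truth for the short comfortable / maximum speed walks.

    speed : steady-state gait speed, m/s
    cadence : steps/min; step length follows as 60*speed/cadence m
    step_width : lateral ankle separation, m
    arm_amplitude_* : per-cycle angular excursion (max - min) of the wrist
        elevation angle at the manubrium, degrees, per side
    """

    speed: float = 1.2
    cadence: float = 110.0
    step_width: float = 0.10
    arm_amplitude_left: float = 26.0
    arm_amplitude_right: float = 26.0
    noise_sd: float = 0.0
    frame_drop_rate: float = 0.0
    seed: int = 0
    rate: float = 30.0
    z_start: float = 4.7
    z_end: float = 1.4
    sensor_pitch: float = 0.0

    def __post_init__(self) -> None:
        if self.speed <= 0 or self.cadence <= 0:
            raise ValueError("speed and cadence must be positive")
        if self.z_start <= self.z_end:
            raise ValueError("walk must progress toward the sensor")


def gen_walk_recording(truth: WalkTruth, protocol: str = "comfortable") -> SkeletonRecording:
    """Simulate a straight walk toward the sensor with a static start.

    The pelvis accelerates linearly over the first two steps (the subject
    starts standing just outside the sensor range) and then translates at the
    truth speed. Foot placements are spaced one step length apart on the
    ground; each swing follows a smooth-step profile lasting half a stride.
    Wrists oscillate sagittally about the manubrium at half the cadence.
    """
    if protocol not in ("comfortable", "maximum"):
        raise ValueError(f"unknown walk protocol {protocol!r}")
    rng = np.random.default_rng(truth.seed)
    v, cad, rate = truth.speed, truth.cadence, truth.rate
    T = 60.0 / cad                 # step period, s
    L = v * T                      # step length, m
    t_ramp = 2.0 * T               # speed ramps 0 -> v over the first two steps
    total = truth.z_start - truth.z_end

    def progress(tt: np.ndarray) -> np.ndarray:
        ramp = v * tt**2 / (2 * t_ramp)
        steady = v * (tt - t_ramp / 2)
        return np.where(tt < t_ramp, ramp, steady)

    def time_at(x: float) -> float:
        # inverse of `progress`
        if x < v * t_ramp / 2:
            return math.sqrt(2 * t_ramp * x / v)
        return x / v + t_ramp / 2

    t_end = time_at(total) + 0.3
    dt = 1.0 / rate
    t = np.arange(0.0, t_end, dt)
    xp = progress(t)

    # foot placement schedule: step k lands at ground progress k*L on the
    # steady-state beat (k - 0.5)*L/v + t_ramp/2; during the two ramp steps
    # the feet lead the (still accelerating) pelvis slightly, which keeps
    # every inter-placement interval exactly one step period
    n_steps = int(math.floor(total / L)) + 1
    placements = []  # (k, time, ground position, side)
    for k in range(1, n_steps + 1):
        tk = (k - 0.5) * L / v + t_ramp / 2
        if tk >= t_end:
            break
        side = "left" if k % 2 == 1 else "right"
        placements.append((k, tk, k * L, side))

    def ankle_progress(side: str) -> np.ndarray:
        own = [(tk, g) for (k, tk, g, s) in placements if s == side]
        a = np.zeros_like(t)
        if not own:
            return a
        # every swing lasts one step period (half the stride), symmetric
        # about the opposite foot's placement, and ends with zero velocity
        t0, g0 = own[0]
        sw = min(T, t0)
        u = np.clip((t - (t0 - sw)) / sw, 0.0, 1.0)
        a = g0 * _smoothstep(u)
        for (ta, ga), (tb, gb) in zip(own[:-1], own[1:]):
            sw = min(T, (tb - ta) / 2)
            u = np.clip((t - (tb - sw)) / sw, 0.0, 1.0)
            a = np.where(t > ta, ga + (gb - ga) * _smoothstep(u), a)
        return a

    aL = ankle_progress("left")
    aR = ankle_progress("right")

    pelvis = np.column_stack(
        [np.zeros_like(t), np.full_like(t, PELVIS_HEIGHT), truth.z_start - xp]
    )
    pos = _base_body(len(t), pelvis)
    w = truth.step_width / 2
    for side, a, sgn in (("left", aL, 1.0), ("right", aR, -1.0)):
        j = JOINT_INDEX[f"ankle_{side}"]
        pos[:, j, 0] = sgn * w
        pos[:, j, 1] = 0.10
        pos[:, j, 2] = truth.z_start - a
        jf = JOINT_INDEX[f"foot_{side}"]
        pos[:, jf, 0] = sgn * w
        pos[:, jf, 1] = 0.05
        pos[:, jf, 2] = truth.z_start - a - 0.10
        # knees midway between hip and ankle
        jh, jk = JOINT_INDEX[f"hip_{side}"], JOINT_INDEX[f"knee_{side}"]
        pos[:, jk, :] = 0.5 * (pos[:, jh, :] + pos[:, j, :])

    # arms: wrist elevation angle about the manubrium, anti-phase sinusoids
    # at cadence/2; the truth amplitude is the per-cycle max-min excursion
    f_arm = cad / 120.0
    r_arm = 0.55
    manub = pos[:, JOINT_INDEX["spine_shoulder"], :]
    for side, amp, phase, sgn in (
        ("left", truth.arm_amplitude_left, 0.0, 1.0),
        ("right", truth.arm_amplitude_right, np.pi, -1.0),
    ):
        theta = np.deg2rad(amp / 2) * np.sin(2 * np.pi * f_arm * t + phase)
        jw = JOINT_INDEX[f"wrist_{side}"]
        pos[:, jw, 0] = sgn * 0.21
        pos[:, jw, 1] = manub[:, 1] - r_arm * np.cos(theta)
        # forward (toward the sensor) is -z for a subject facing the sensor
        pos[:, jw, 2] = manub[:, 2] - r_arm * np.sin(theta)
        for jn in (f"hand_{side}", f"hand_tip_{side}", f"thumb_{side}"):
            pos[:, JOINT_INDEX[jn], :] = pos[:, jw, :] + np.array([0.0, -0.06, 0.0])
        je, js = JOINT_INDEX[f"elbow_{side}"], JOINT_INDEX[f"shoulder_{side}"]
        pos[:, je, :] = 0.5 * (pos[:, js, :] + pos[:, jw, :])

    in_band = [
        (k, tk)
        for (k, tk, g, s) in placements
        if 2.0 <= truth.z_start - progress(np.array([tk]))[0] <= 4.0
    ]
    truth_meta = {
        "speed": v,
        "cadence": cad,
        "step_length_cm": L * 100,
        "step_width_cm": truth.step_width * 100,
        "step_duration": T,
        "arm_amplitude_left": truth.arm_amplitude_left,
        "arm_amplitude_right": truth.arm_amplitude_right,
        "placement_times": [tk for (_, tk, _, _) in placements],
        "placement_sides": [s for (_, _, _, s) in placements],
        "n_in_band_placements": len(in_band),
    }
    task = Task.SCSW if protocol == "comfortable" else Task.SMSW
    return _finish(
        t, pos, task, truth_meta, truth.noise_sd, truth.frame_drop_rate, rng,
        rate, truth.sensor_pitch,
    )


# ---------------------------------------------------------------------------
# tandem gait (SLW)
# ---------------------------------------------------------------------------


@dataclass
class TandemTruth:
    """Ground truth for the short line walk (heel-to-toe tandem gait).

    speed : mean progression speed, m/s
    speed_cov : coefficient of variation of the frame-wise progression speed
        (imposed as a sinusoidal speed modulation)
    roll_amplitude / roll_freq : trunk roll sinusoid, deg peak / Hz
    cadence : steps/min, driving anti-phase ankle-relative-to-hip AP peaks
    arm_amplitude / arm_freq : sagittal upper-arm oscillation, deg peak / Hz
    """

    speed: float = 0.35
    speed_cov: float = 0.0
    speed_mod_freq: float = 0.4
    roll_amplitude: float = 2.5
    roll_freq: float = 0.6  # trunk roll locked to the stride rate (cadence/120)
    cadence: float = 72.0
    step_excursion: float = 0.25
    arm_amplitude: float = 8.0
    arm_freq: float = 0.6
    noise_sd: float = 0.0
    frame_drop_rate: float = 0.0
    seed: int = 0
    rate: float = 30.0
    z_start: float = 4.6
    z_end: float = 1.5
    sensor_pitch: float = 0.0

    def __post_init__(self) -> None:
        if self.speed <= 0:
            raise ValueError("progression speed must be positive")


def gen_tandem_recording(truth: TandemTruth) -> SkeletonRecording:
    """Simulate tandem gait: single-file foot placements, trunk roll sway."""
    rng = np.random.default_rng(truth.seed)
    rate, v0 = truth.rate, truth.speed
    dur = (truth.z_start - truth.z_end) / v0
    t = np.arange(0.0, dur, 1.0 / rate)
    dt = 1.0 / rate

    # progression with sinusoidal speed modulation of the requested CoV
    vmod = v0 * (1.0 + truth.speed_cov * math.sqrt(2.0)
                 * np.sin(2 * np.pi * truth.speed_mod_freq * t))
    xp = np.concatenate([[0.0], np.cumsum(0.5 * (vmod[1:] + vmod[:-1]) * dt)])

    pelvis = np.column_stack(
        [np.zeros_like(t), np.full_like(t, PELVIS_HEIGHT), truth.z_start - xp]
    )
    pos = _base_body(len(t), pelvis)

    # trunk roll: rotate the upper body about the AP axis through the pelvis
    phi = np.deg2rad(truth.roll_amplitude) * np.sin(2 * np.pi * truth.roll_freq * t)
    upper = [
        "spine_mid", "spine_shoulder", "neck", "head",
        "shoulder_left", "shoulder_right",
    ]
    c, s = np.cos(phi), np.sin(phi)
    for name in upper:
        off = np.asarray(_POSE[name])
        pos[:, JOINT_INDEX[name], 0] = pelvis[:, 0] + c * off[0] + s * off[1]
        pos[:, JOINT_INDEX[name], 1] = pelvis[:, 1] - s * off[0] + c * off[1]

    # single-file feet: ankles on the line, AP oscillation relative to hips
    f_side = truth.cadence / 120.0  # per-side peak rate, Hz
    for side, phase in (("left", 0.0), ("right", np.pi)):
        rel = truth.step_excursion * np.sin(2 * np.pi * f_side * t + phase)
        jh, ja = JOINT_INDEX[f"hip_{side}"], JOINT_INDEX[f"ankle_{side}"]
        pos[:, jh, 0] = pelvis[:, 0] + _POSE[f"hip_{side}"][0]
        pos[:, ja, 0] = 0.0
        pos[:, ja, 1] = 0.10
        pos[:, ja, 2] = pos[:, jh, 2] - rel
        jf = JOINT_INDEX[f"foot_{side}"]
        pos[:, jf, :] = pos[:, ja, :] + np.array([0.0, -0.05, -0.10])
        jk = JOINT_INDEX[f"knee_{side}"]
        pos[:, jk, :] = 0.5 * (pos[:, jh, :] + pos[:, ja, :])

    # arms: upper-arm sagittal oscillation about the shoulder
    alpha = np.deg2rad(truth.arm_amplitude) * np.sin(2 * np.pi * truth.arm_freq * t)
    r_ua = 0.31
    for side, sgn in (("left", 1.0), ("right", -1.0)):
        js, je = JOINT_INDEX[f"shoulder_{side}"], JOINT_INDEX[f"elbow_{side}"]
        pos[:, je, 0] = pos[:, js, 0]
        pos[:, je, 1] = pos[:, js, 1] - r_ua * np.cos(alpha)
        pos[:, je, 2] = pos[:, js, 2] - r_ua * np.sin(alpha)
        jw = JOINT_INDEX[f"wrist_{side}"]
        pos[:, jw, :] = pos[:, je, :] + np.array([sgn * 0.01, -0.27, 0.0])

    truth_meta = {
        "speed": v0,
        "speed_cov": truth.speed_cov,
        "roll_amplitude": truth.roll_amplitude,
        "roll_freq": truth.roll_freq,
        "roll_variability": truth.roll_amplitude / math.sqrt(2.0),
        "roll_speed": 4.0 * truth.roll_freq * truth.roll_amplitude,
        "cadence": truth.cadence,
        "arm_amplitude": truth.arm_amplitude,
        "arm_freq": truth.arm_freq,
    }
    return _finish(
        t, pos, Task.SLW, truth_meta, truth.noise_sd, truth.frame_drop_rate,
        rng, rate, truth.sensor_pitch,
    )


# ---------------------------------------------------------------------------
# stepping in place (SIP)
# ---------------------------------------------------------------------------

# fraction of a swing hump spent below 20% of the peak amplitude:
# sin^2(pi*u) < 0.2 on u in (0, asin(sqrt(0.2))/pi) and symmetric tail
_SIP_BELOW20_FRAC = 2.0 * math.asin(math.sqrt(0.2)) / math.pi


@dataclass
class SipTruth:
    """Ground truth for stepping in place.

    knee_amplitude_* : peak AP knee excursion per side, m
    cadence : steps/min (each knee lift is one step)
    stride_cov : multiplicative log-normal jitter of per-side stride times,
        as a fraction (0.06 = 6% arrhythmicity)
    """

    knee_amplitude_left: float = 0.18
    knee_amplitude_right: float = 0.18
    cadence: float = 100.0
    stride_cov: float = 0.0
    duration: float = 40.0
    swing_fraction: float = 0.5
    noise_sd: float = 0.0
    frame_drop_rate: float = 0.0
    seed: int = 0
    rate: float = 30.0
    stand_z: float = 2.5
    sensor_pitch: float = 0.0

    def __post_init__(self) -> None:
        if self.cadence <= 0:
            raise ValueError("cadence must be positive")
        if self.knee_amplitude_left < 0 or self.knee_amplitude_right < 0:
            raise ValueError("knee amplitudes must be non-negative")


def _jittered_strides(rng, t_stride, cov, t_start, t_end):
    """Stride start times with multiplicative log-normal period jitter."""
    if cov > 0:
        sigma = math.sqrt(math.log(1.0 + cov**2))
        mu = -sigma**2 / 2  # unit-mean log-normal
    starts, tt = [], t_start
    while tt < t_end:
        starts.append(tt)
        step = t_stride if cov <= 0 else t_stride * rng.lognormal(mu, sigma)
        tt += step
    return starts


def gen_sip_recording(truth: SipTruth) -> SkeletonRecording:
    """Simulate stepping in place: alternating AP knee humps, static pelvis."""
    rng = np.random.default_rng(truth.seed)
    rate = truth.rate
    t = np.arange(0.0, truth.duration, 1.0 / rate)
    t_stride = 120.0 / truth.cadence   # per-side stride period
    t_swing = truth.swing_fraction * t_stride  # constant swing duration

    pelvis = np.column_stack(
        [np.zeros_like(t), np.full_like(t, PELVIS_HEIGHT), np.full_like(t, truth.stand_z)]
    )
    pos = _base_body(len(t), pelvis)

    amp = {"left": truth.knee_amplitude_left, "right": truth.knee_amplitude_right}
    peak_times: dict[str, list[float]] = {}
    for side, offset in (("left", 0.0), ("right", t_stride / 2.0)):
        starts = _jittered_strides(rng, t_stride, truth.stride_cov, offset,
                                   truth.duration - t_swing)
        exc = np.zeros_like(t)
        for st in starts:
            u = (t - st) / t_swing
            m = (u >= 0) & (u <= 1)
            exc[m] += amp[side] * np.sin(np.pi * u[m]) ** 2
        jk = JOINT_INDEX[f"knee_{side}"]
        base = pos[:, jk, :].copy()
        pos[:, jk, 2] = base[:, 2] - exc            # forward = toward the sensor
        pos[:, jk, 1] = base[:, 1] + 0.4 * exc      # knee also lifts
        ja = JOINT_INDEX[f"ankle_{side}"]
        pos[:, ja, 2] = pos[:, ja, 2] - 0.6 * exc
        pos[:, ja, 1] = pos[:, ja, 1] + 0.5 * exc
        peak_times[side] = [st + t_swing / 2 for st in starts]

    stance_truth = t_stride - (1.0 - _SIP_BELOW20_FRAC) * t_swing
    truth_meta = {
        "knee_amplitude_left": truth.knee_amplitude_left,
        "knee_amplitude_right": truth.knee_amplitude_right,
        "cadence": truth.cadence,
        "stride_cov": truth.stride_cov,
        "stance_duration": stance_truth,
        "step_duration": t_stride / 2.0,
        "peak_times_left": peak_times["left"],
        "peak_times_right": peak_times["right"],
    }
    return _finish(
        t, pos, Task.SIP, truth_meta, truth.noise_sd, truth.frame_drop_rate,
        rng, rate, truth.sensor_pitch,
    )


# ---------------------------------------------------------------------------
# standing up and sitting down (SAS)
# ---------------------------------------------------------------------------


@dataclass
class SasTruth:
    """Ground truth for the sit-to-stand-to-sit task.

    up_duration / down_duration : nominal bound-to-bound durations of the
        smooth-step transitions, s. The velocity profile is sin^2, so the
        duration a 10%-of-peak threshold detector reports is
        ``D * (1 - 2*asin(sqrt(0.1))/pi)`` — recorded in the truth metadata.
    ap_deflection_* : max-min AP excursion of the manubrium within each
        transition, m
    """

    up_duration: float = 1.9
    down_duration: float = 2.1
    ap_deflection_up: float = 0.37
    ap_deflection_down: float = 0.40
    rise_height: float = 0.45
    lead_in: float = 2.0
    stand_hold: float = 3.0
    tail: float = 2.0
    threshold_fraction: float = 0.1
    noise_sd: float = 0.0
    frame_drop_rate: float = 0.0
    seed: int = 0
    rate: float = 30.0
    stand_z: float = 2.5
    sensor_pitch: float = 0.0

    def __post_init__(self) -> None:
        if self.up_duration <= 0 or self.down_duration <= 0:
            raise ValueError("transition durations must be positive")

    def detected_duration(self, nominal: float) -> float:
        """Inter-threshold duration a |v| > frac*peak detector sees."""
        f = self.threshold_fraction
        return nominal * (1.0 - 2.0 * math.asin(math.sqrt(f)) / math.pi)


def gen_sas_recording(truth: SasTruth) -> SkeletonRecording:
    """Simulate standing up and sitting down on an auditory cue."""
    rng = np.random.default_rng(truth.seed)
    rate = truth.rate
    total = truth.lead_in + truth.up_duration + truth.stand_hold \
        + truth.down_duration + truth.tail
    t = np.arange(0.0, total, 1.0 / rate)

    y_sit = PELVIS_HEIGHT - truth.rise_height  # pelvic center seated
    up0 = truth.lead_in
    down0 = truth.lead_in + truth.up_duration + truth.stand_hold

    y = np.full_like(t, y_sit)
    zoff = np.zeros_like(t)  # manubrium AP offset (forward = -z)
    # stand up
    u = np.clip((t - up0) / truth.up_duration, 0.0, 1.0)
    y = y + truth.rise_height * _smoothstep(u)
    m = (t >= up0) & (t <= up0 + truth.up_duration)
    zoff[m] -= (truth.ap_deflection_up / 2.0) * np.sin(2 * np.pi * u[m])
    # sit down
    u = np.clip((t - down0) / truth.down_duration, 0.0, 1.0)
    y = y - truth.rise_height * _smoothstep(u)
    m = (t >= down0) & (t <= down0 + truth.down_duration)
    zoff[m] -= (truth.ap_deflection_down / 2.0) * np.sin(2 * np.pi * u[m])

    pelvis = np.column_stack([np.zeros_like(t), y, np.full_like(t, truth.stand_z)])
    pos = _base_body(len(t), pelvis)
    jm = JOINT_INDEX["spine_shoulder"]
    pos[:, jm, 2] += zoff
    for name in ("neck", "head", "spine_mid"):
        pos[:, JOINT_INDEX[name], 2] += zoff
    # feet stay planted
    for name in ("ankle_left", "ankle_right", "foot_left", "foot_right"):
        j = JOINT_INDEX[name]
        pos[:, j, 1] = _POSE[name][1] + PELVIS_HEIGHT
        pos[:, j, 2] = truth.stand_z + _POSE[name][2]

    truth_meta = {
        "up_duration": truth.up_duration,
        "down_duration": truth.down_duration,
        "detected_up_duration": truth.detected_duration(truth.up_duration),
        "detected_down_duration": truth.detected_duration(truth.down_duration),
        "ap_deflection_up": truth.ap_deflection_up,
        "ap_deflection_down": truth.ap_deflection_down,
    }
    return _finish(
        t, pos, Task.SAS, truth_meta, truth.noise_sd, truth.frame_drop_rate,
        rng, rate, truth.sensor_pitch,
    )


# ---------------------------------------------------------------------------
# postural control (POCO)
# ---------------------------------------------------------------------------


@dataclass
class PocoSegment:
    """Sway ground truth for one eyes-open or eyes-closed segment.

    In ``sinusoid`` mode pitch/roll are pure sinusoids (closed forms:
    angular range = 2A, mean angular speed = 4*f*A). In ``noise`` mode they
    are Gaussian random walks low-passed to ``noise_cutoff`` with the target
    RMS amplitude.
    """

    pitch_amplitude: float = 0.5   # deg (peak for sinusoid, RMS for noise)
    pitch_freq: float = 0.25       # Hz
    roll_amplitude: float = 0.5
    roll_freq: float = 0.2
    mode: str = "sinusoid"         # "sinusoid" | "noise"
    noise_cutoff: float = 1.0      # Hz, for noise mode


@dataclass
class PocoTruth:
    """Ground truth for the postural-control task (eyes open, then closed)."""

    open_segment: PocoSegment = field(default_factory=PocoSegment)
    closed_segment: PocoSegment = field(
        default_factory=lambda: PocoSegment(pitch_amplitude=0.75, roll_amplitude=0.75)
    )
    segment_duration: float = 20.0
    noise_sd: float = 0.0
    frame_drop_rate: float = 0.0
    seed: int = 0
    rate: float = 30.0
    stand_z: float = 2.5
    sensor_pitch: float = 0.0


def _sway_series(seg: PocoSegment, t: np.ndarray, rng: np.random.Generator):
    """(pitch_deg, roll_deg) time series for one segment."""
    out = []
    for amp, freq, phase in (
        (seg.pitch_amplitude, seg.pitch_freq, 0.0),
        (seg.roll_amplitude, seg.roll_freq, np.pi / 3),
    ):
        if seg.mode == "sinusoid":
            out.append(amp * np.sin(2 * np.pi * freq * t + phase))
        elif seg.mode == "noise":
            from scipy.signal import butter, filtfilt

            raw = rng.normal(0.0, 1.0, size=len(t))
            dt = t[1] - t[0]
            b, a = butter(2, seg.noise_cutoff * 2 * dt)
            sm = filtfilt(b, a, raw)
            rms = np.sqrt(np.mean(sm**2))
            out.append(amp * sm / rms if rms > 0 else sm)
        else:
            raise ValueError(f"unknown sway mode {seg.mode!r}")
    return out[0], out[1]


def gen_poco_recording(truth: PocoTruth) -> SkeletonRecording:
    """Simulate quiet stance sway about the fixed mean-ankle point."""
    rng = np.random.default_rng(truth.seed)
    rate, dur = truth.rate, truth.segment_duration
    t = np.arange(0.0, 2 * dur, 1.0 / rate)
    open_mask = t < dur

    pitch = np.empty_like(t)
    roll = np.empty_like(t)
    for seg, mask in ((truth.open_segment, open_mask),
                      (truth.closed_segment, ~open_mask)):
        p, r = _sway_series(seg, t[mask] - t[mask][0], rng)
        pitch[mask], roll[mask] = p, r

    # pelvis sways about the fixed mean-ankle point: the sway vector's
    # horizontal components are h*tan(angle) so atan2 recovery is exact
    h = 0.90
    ankle_mid = np.array([0.0, 0.10, truth.stand_z])
    pelvis = np.column_stack([
        ankle_mid[0] + h * np.tan(np.deg2rad(roll)),
        np.full_like(t, ankle_mid[1] + h),
        ankle_mid[2] + h * np.tan(np.deg2rad(pitch)),
    ])
    pos = _base_body(len(t), pelvis)
    for side, sgn in (("left", 1.0), ("right", -1.0)):
        ja = JOINT_INDEX[f"ankle_{side}"]
        pos[:, ja, :] = ankle_mid + np.array([sgn * 0.05, 0.0, 0.0])
        jf = JOINT_INDEX[f"foot_{side}"]
        pos[:, jf, :] = pos[:, ja, :] + np.array([0.0, -0.05, -0.10])
        jk = JOINT_INDEX[f"knee_{side}"]
        pos[:, jk, :] = 0.5 * (pos[:, JOINT_INDEX[f"hip_{side}"], :] + pos[:, ja, :])

    def closed_forms(seg: PocoSegment) -> dict:
        if seg.mode != "sinusoid":
            return {}
        return {
            "pitch_range": 2 * seg.pitch_amplitude,
            "pitch_speed": 4 * seg.pitch_freq * seg.pitch_amplitude,
            "roll_range": 2 * seg.roll_amplitude,
            "roll_speed": 4 * seg.roll_freq * seg.roll_amplitude,
        }

    truth_meta = {
        "segment_boundary": dur,
        "open": closed_forms(truth.open_segment),
        "closed": closed_forms(truth.closed_segment),
    }
    rec = _finish(
        t, pos, Task.POCO, truth_meta, truth.noise_sd, truth.frame_drop_rate,
        rng, rate, truth.sensor_pitch,
    )
    rec.meta["segment_boundary"] = dur
    return rec


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass
class PlantedEffect:
    """A linear confound effect planted on one parameter."""

    beta0: float
    beta_age: float
    beta_sex: float
    beta_height: float
    beta_weight: float
    residual_sd: float

    def __post_init__(self) -> None:
        if self.residual_sd <= 0:
            raise ValueError("residual SD must be positive")

    def predict(self, subject: Subject) -> float:
        return (
            self.beta0
            + self.beta_age * subject.age
            + self.beta_sex * subject.sex_code
            + self.beta_height * subject.height
            + self.beta_weight * subject.weight
        )


@dataclass
class CohortSpec:
    """Covariate distributions and planted effects for a synthetic cohort.

    Defaults emulate a healthy-adult normative cohort of 133 participants
    pooled from three studies, ages 20-60 (mean ~36.8, SD ~10.4), 56% female,
    with sex-conditional height/weight distributions whose mixture matches
    the cohort-level means and SDs (height 172.9 +- 9.3 cm, weight
    71.8 +- 13.9 kg).
    """

    studies: dict[str, int] = field(
        default_factory=lambda: {"studyA": 41, "studyB": 57, "studyC": 35}
    )
    female_fraction: float = 0.56
    age_mean: float = 36.83
    age_sd: float = 10.44
    age_range: tuple[float, float] = (20.0, 60.0)
    height_by_sex: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"female": (167.0, 7.0), "male": (180.0, 7.0)}
    )
    weight_by_sex: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"female": (64.0, 11.0), "male": (81.0, 11.0)}
    )
    height_range: tuple[float, float] = (153.0, 194.0)
    weight_range: tuple[float, float] = (46.0, 115.0)
    planted_effects: dict[str, PlantedEffect] = field(default_factory=dict)
    # parameter -> (mean, sd) for i.i.d. draws; None = use packaged norms
    base_distributions: dict[str, tuple[float, float]] | None = None
    parameters: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.studies.values()):
            raise ValueError("study sizes must be >= 1")

    @property
    def n(self) -> int:
        return sum(self.studies.values())


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Draw from a normal truncated to [lo, hi] by rejection."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=size)
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(ok), size - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
    return out


def gen_cohort(spec: CohortSpec):
    """Draw a cohort of subjects and their per-parameter ground truths.

    Returns ``(subjects, truths)`` where ``truths`` is a pandas DataFrame
    (one row per subject, one column per parameter). Planted-effect
    parameters follow ``linear predictor + N(0, residual_sd)``; all others
    are drawn i.i.d. around their normative mean/SD.
    """
    import pandas as pd

    from .parameters import ALL_KEYS
    from .scoring import load_reference_resource

    rng = np.random.default_rng(spec.seed)
    subjects: list[Subject] = []
    i = 0
    for study, n in sorted(spec.studies.items()):
        sexes = np.where(rng.random(n) < spec.female_fraction, "female", "male")
        ages = _truncated_normal(rng, spec.age_mean, spec.age_sd,
                                 *spec.age_range, n)
        for k in range(n):
            sex = str(sexes[k])
            hm, hs = spec.height_by_sex[sex]
            wm, ws = spec.weight_by_sex[sex]
            height = float(_truncated_normal(rng, hm, hs, *spec.height_range, 1)[0])
            weight = float(_truncated_normal(rng, wm, ws, *spec.weight_range, 1)[0])
            subjects.append(Subject(
                subject_id=f"S{i:04d}", age=float(ages[k]), sex=sex,
                height=height, weight=weight, study=study,
            ))
            i += 1

    keys = spec.parameters if spec.parameters is not None else ALL_KEYS
    base = spec.base_distributions
    if base is None:
        res = load_reference_resource()
        base = {k: (res.entries[k].mean, res.entries[k].sd)
                for k in keys if k in res.entries}

    truths = pd.DataFrame(index=[s.subject_id for s in subjects],
                          columns=list(keys), dtype=float)
    for key in keys:
        if key in spec.planted_effects:
            eff = spec.planted_effects[key]
            mu = np.array([eff.predict(s) for s in subjects])
            truths[key] = mu + rng.normal(0.0, eff.residual_sd, size=len(subjects))
        elif key in base:
            m, sd = base[key]
            truths[key] = rng.normal(m, sd, size=len(subjects))
        else:
            raise KeyError(f"no distribution known for parameter {key!r}")
    return subjects, truths


def _arm_sides_from(mean_amp: float, symmetry_angle: float) -> tuple[float, float]:
    """Invert (mean amplitude, symmetry angle) into per-side amplitudes."""
    rho = math.tan(math.radians(45.0 + 90.0 * symmetry_angle))
    left = 2 * mean_amp * rho / (1 + rho)
    right = 2 * mean_amp / (1 + rho)
    return left, right


def render_subject_recordings(
    subject: Subject,
    truths: "dict | object",
    seed: int = 0,
    tasks: tuple[Task, ...] = tuple(Task),
    repetitions: int = 1,
) -> list[SkeletonRecording]:
    """Materialize skeleton recordings whose extraction recovers a subject's
    parameter truths (for the parameters with closed-form inverses).

    ``truths`` maps parameter keys to values, e.g. one row of the cohort
    truth frame.
    """
    g = truths.get if hasattr(truths, "get") else lambda k, d=None: getattr(truths, k, d)
    recs: list[SkeletonRecording] = []
    detect_frac = 1.0 - 2.0 * math.asin(math.sqrt(0.1)) / math.pi
    for rep in range(1, repetitions + 1):
        rep_seed = int(np.random.SeedSequence([seed, rep]).generate_state(1)[0] % (2**31))
        if Task.SCSW in tasks:
            speed = float(g("scsw_gait_speed", 1.2))
            step_len_cm = float(g("scsw_step_length", 100 * 60 * speed / 110.0))
            cad = 60.0 * speed / (step_len_cm / 100.0)
            al, ar = _arm_sides_from(
                float(g("scsw_arm_angular_amplitude", 26.0)),
                min(float(g("scsw_arm_symmetry_angle", 0.0)), 0.45),
            )
            recs.append(gen_walk_recording(WalkTruth(
                speed=speed, cadence=cad,
                step_width=max(float(g("scsw_step_width", 10.0)), 2.0) / 100.0,
                arm_amplitude_left=al, arm_amplitude_right=ar,
                seed=rep_seed,
            ), protocol="comfortable"))
            recs[-1].repetition_index = rep
        if Task.SMSW in tasks:
            rec = gen_walk_recording(WalkTruth(
                speed=float(g("smsw_gait_speed", 1.66)), cadence=130.0,
                seed=rep_seed + 1,
            ), protocol="maximum")
            rec.repetition_index = rep
            recs.append(rec)
        if Task.SLW in tasks:
            roll_var = float(g("slw_roll_sway_variability", 1.8))
            roll_amp = roll_var * math.sqrt(2.0)
            roll_speed = float(g("slw_roll_sway_speed", 5.6))
            rec = gen_tandem_recording(TandemTruth(
                speed=float(g("slw_progression_speed", 0.35)),
                speed_cov=min(float(g("slw_progression_variability", 0.2)), 0.6),
                roll_amplitude=roll_amp,
                roll_freq=roll_speed / (4.0 * roll_amp) if roll_amp > 0 else 0.5,
                cadence=float(g("slw_line_walk_cadence", 72.0)),
                seed=rep_seed + 2,
            ))
            rec.repetition_index = rep
            recs.append(rec)
        if Task.SIP in tasks:
            kl, kr = _arm_sides_from(
                float(g("sip_knee_amplitude", 0.18)),
                min(float(g("sip_knee_symmetry_angle", 0.0)), 0.45),
            )
            rec = gen_sip_recording(SipTruth(
                knee_amplitude_left=kl, knee_amplitude_right=kr,
                cadence=float(g("sip_stepping_cadence", 100.0)),
                stride_cov=max(float(g("sip_arrhythmicity", 5.0)), 0.5) / 100.0,
                seed=rep_seed + 3,
            ))
            rec.repetition_index = rep
            recs.append(rec)
        if Task.SAS in tasks:
            rec = gen_sas_recording(SasTruth(
                up_duration=float(g("sas_transition_time_up", 1.5)) / detect_frac,
                down_duration=float(g("sas_transition_time_down", 1.66)) / detect_frac,
                ap_deflection_up=float(g("sas_ap_deflection_up", 0.37)),
                ap_deflection_down=float(g("sas_ap_deflection_down", 0.40)),
                seed=rep_seed + 4,
            ))
            rec.repetition_index = rep
            recs.append(rec)
        if Task.POCO in tasks:
            def seg(prefix: str) -> PocoSegment:
                pr = max(float(g(f"poco_pitch_range_{prefix}", 1.0)), 0.05)
                rr = max(float(g(f"poco_roll_range_{prefix}", 1.0)), 0.05)
                ps = max(float(g(f"poco_pitch_speed_{prefix}", 0.15)), 0.01)
                rs = max(float(g(f"poco_roll_speed_{prefix}", 0.15)), 0.01)
                return PocoSegment(
                    pitch_amplitude=pr / 2, pitch_freq=ps / (2 * pr),
                    roll_amplitude=rr / 2, roll_freq=rs / (2 * rr),
                )
            rec = gen_poco_recording(PocoTruth(
                open_segment=seg("open"), closed_segment=seg("closed"),
                seed=rep_seed + 5,
            ))
            rec.repetition_index = rep
            recs.append(rec)
    for rec in recs:
        rec.subject = subject
    return recs
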