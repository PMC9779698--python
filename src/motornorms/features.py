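"""Extraction of the 43 spatiotemporal parameters from skeleton recordings.

Each task has a dedicated extractor operating on a *preprocessed* recording
(see :mod:`motornorms.skeleton_io`). Parameters that cannot be computed —
too few detected steps, a degenerate denominator — are returned absent with
a coded reason rather than raising.

Directions are derived from the data, not from the raw camera axes: walk
tasks measure along the principal horizontal direction of pelvis travel,
stationary tasks (SIP, SAS, POCO) along the horizontal line from the subject
to the sensor. All parameters are therefore invariant to translating the
scene or rotating it about the vertical axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .joints import LATERAL, VERTICAL, DEPTH  # noqa: F401  (axis documentation)
from .parameters import parameters_for
from .types import FeatureVector, SkeletonRecording, Task

REASON_INSUFFICIENT_STEPS = "insufficient steps"
REASON_OUT_OF_BAND = "pelvis never inside measurement band"
REASON_NO_TRANSITION = "no transition detected"
REASON_DEGENERATE = "degenerate denominator"
REASON_SHORT_SEGMENT = "segment too short"


@dataclass
class FeatureConfig:
    """Thresholds of the extraction algorithms (all configurable).

    band : pelvis-to-sensor distance window (m) within which walk
        parameters are measured; excludes the static-start acceleration and
        near-field tracking loss inside the 1.5-4.5 m operating range.
    step_prominence : minimum prominence (m) of the signed left-minus-right
        ankle excursion for a foot placement to count.
    sip_prominence : minimum prominence (m) of AP knee excursion peaks.
    sip_stance_fraction : knee excursion below this fraction of the side
        amplitude counts as stance.
    sas_threshold_fraction : transition bounds at this fraction of the
        episode's peak vertical speed.
    sas_min_peak_speed : absolute floor (m/s) for a vertical-speed episode
        to count as a transition.
    slw_angle_cutoff_hz / sas_velocity_cutoff_hz / poco_angle_cutoff_hz :
        zero-phase low-pass cutoffs applied to the derived angle/velocity
        series before differentiation or thresholding. Trunk sway and
        sit-to-stand transitions carry no voluntary content above ~1-2 Hz,
        and rate/extreme-value estimates amplify residual landmark noise, so
        these series are smoothed harder than the raw trajectories.
    """

    band: tuple[float, float] = (2.0, 4.0)
    step_prominence: float = 0.15
    min_step_events: int = 3
    slw_peak_prominence: float = 0.10
    slw_angle_cutoff_hz: float = 1.2
    sip_prominence: float = 0.05
    sip_stance_fraction: float = 0.20
    sip_baseline_percentile: float = 5.0
    sas_threshold_fraction: float = 0.10
    sas_min_peak_speed: float = 0.10
    sas_velocity_cutoff_hz: float = 1.5
    poco_min_segment: float = 15.0
    poco_angle_cutoff_hz: float = 1.0
    # open-eyes measures at or below this are degenerate Romberg denominators
    poco_degenerate_floor: float = 1e-9


@dataclass
class StepEvent:
    """One detected foot placement during a walk."""

    t: float
    side: str                 # which foot was just placed (leading foot)
    s_left: float             # ankle positions along the walk axis, m
    s_right: float
    lateral_left: float       # ankle positions across the walk axis, m
    lateral_right: float

    @property
    def step_length(self) -> float:
        return abs(self.s_left - self.s_right)

    @property
    def step_width(self) -> float:
        return abs(self.lateral_left - self.lateral_right)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def _pelvis(rec: SkeletonRecording) -> np.ndarray:
    return rec.joint("spine_base")


def _walk_axes(rec: SkeletonRecording) -> tuple[np.ndarray, np.ndarray]:
    """(walk direction, lateral direction), horizontal unit vectors.

    The walk axis is the net horizontal pelvis displacement; the lateral
    axis is its 90-degree rotation in the horizontal plane.
    """
    p = _pelvis(rec)
    d = p[-1] - p[0]
    d[1] = 0.0
    norm = np.linalg.norm(d)
    if norm < 1e-9:
        raise ValueError("pelvis shows no net horizontal displacement")
    u = d / norm
    w = np.array([-u[2], 0.0, u[0]])  # horizontal 90-degree rotation
    return u, w


def _facing_axes(rec: SkeletonRecording) -> tuple[np.ndarray, np.ndarray]:
    """(anterior direction, lateral direction) for a stationary subject.

    Anterior = horizontal unit vector perpendicular to the mean shoulder
    line, pointing the way the subject faces. Deriving the axes from the
    body (rather than the camera) makes the stationary-task parameters
    invariant to translating the scene or rotating it about vertical.
    """
    ell = (rec.joint("shoulder_left") - rec.joint("shoulder_right")).mean(axis=0)
    ell[1] = 0.0
    norm = np.linalg.norm(ell)
    if norm < 1e-9:
        raise ValueError("degenerate shoulder line; cannot derive facing direction")
    ell /= norm
    f = np.cross(np.array([0.0, 1.0, 0.0]), ell)  # anterior = up x left
    w = ell
    return f, w


def _band_mask(rec: SkeletonRecording, cfg: FeatureConfig) -> np.ndarray:
    """Frames where the pelvis-to-sensor horizontal distance is in band."""
    p = _pelvis(rec)
    r = np.hypot(p[:, 0], p[:, 2])
    return (r >= cfg.band[0]) & (r <= cfg.band[1])


def _lowpass(x: np.ndarray, rate: float, cutoff: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass along axis 0 (no-op above Nyquist)."""
    from scipy.signal import butter, filtfilt

    nyq = rate / 2.0
    if cutoff <= 0 or cutoff >= nyq:
        return x
    b, a = butter(order, cutoff / nyq)
    # pad a few filter time constants so edge transients die out symmetrically
    padlen = min(int(3 * rate / cutoff), x.shape[0] - 1)
    return filtfilt(b, a, x, axis=0, padlen=padlen)


def _mean_abs_rate(x: np.ndarray, dt: float) -> float:
    """Mean |frame difference| / dt."""
    return float(np.mean(np.abs(np.diff(x)))) / dt


def _central_rate(x: np.ndarray, dt: float) -> np.ndarray:
    """Central-difference derivative."""
    return np.gradient(x, dt)


def _find_peaks_clean(x: np.ndarray, prominence: float, min_sep_frames: int = 1):
    """Peak indices with prominence and minimum separation.

    Plateaus break ties at their first sample.
    """
    idx, props = find_peaks(x, prominence=prominence,
                            distance=max(min_sep_frames, 1), plateau_size=1)
    left = props.get("left_edges")
    if left is not None:
        idx = left  # first sample of a plateau
    return np.asarray(idx, dtype=int)


def _refine_peak_time(x: np.ndarray, t: np.ndarray, i: int) -> float:
    """Sub-frame peak time by parabolic interpolation around sample ``i``.

    Event times quantized to the frame grid bias short-span cadence and
    interval estimates by up to half a frame; a three-point parabola
    recovers the extremum to a small fraction of a frame.
    """
    if i <= 0 or i >= len(x) - 1:
        return float(t[i])
    denom = x[i - 1] - 2.0 * x[i] + x[i + 1]
    if abs(denom) < 1e-12:
        return float(t[i])
    delta = 0.5 * (x[i - 1] - x[i + 1]) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    return float(t[i] + delta * (t[min(i + 1, len(t) - 1)] - t[i]))


# ---------------------------------------------------------------------------
# scalar utilities
# ---------------------------------------------------------------------------


def symmetry_angle(left: float, right: float) -> float:
    """Absolute symmetry angle between left and right amplitudes.

    ``|45 deg - atan2(left, right)| / 90 deg``, a dimensionless fraction in
    [0, 0.5]: 0 for perfect symmetry, 0.5 for one-sided movement.
    """
    if left < 0 or right < 0:
        raise ValueError("amplitudes must be non-negative")
    if left == 0 and right == 0:
        raise ValueError("symmetry angle undefined for two zero amplitudes")
    return abs(45.0 - np.degrees(np.arctan2(left, right))) / 90.0


def romberg_ratio(closed: float, open_: float) -> float:
    """Eyes-closed measure divided by the eyes-open measure."""
    if open_ <= 0:
        raise ValueError("Romberg ratio undefined for non-positive open-eyes value")
    return closed / open_


def coefficient_of_variation(values) -> float:
    """Sample SD (denominator n-1) divided by the mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    m = v.mean()
    if m == 0:
        raise ValueError("coefficient of variation undefined for zero mean")
    return float(v.std(ddof=1) / m)


# ---------------------------------------------------------------------------
# step detection (walks)
# ---------------------------------------------------------------------------


def detect_walk_steps(
    rec: SkeletonRecording, cfg: FeatureConfig | None = None,
    restrict_to_band: bool = True,
) -> list[StepEvent]:
    """Detect foot placements in a walk recording.

    A placement is a local extremum of the signed left-minus-right ankle
    position along the walk axis, restricted to frames where the pelvis is
    inside the measurement band and with prominence at least
    ``cfg.step_prominence``. At a maximum the left foot leads (a left
    placement); at a minimum the right foot leads. Event times are refined
    to sub-frame precision by parabolic interpolation.
    """
    cfg = cfg or FeatureConfig()
    u, w = _walk_axes(rec)
    al = rec.joint("ankle_left")
    ar = rec.joint("ankle_right")
    sl, sr = al @ u, ar @ u
    d = sl - sr
    band = _band_mask(rec, cfg)

    # minimum separation: a quarter of the dominant inter-extremum period
    raw = np.sort(np.concatenate([
        _find_peaks_clean(d, cfg.step_prominence),
        _find_peaks_clean(-d, cfg.step_prominence),
    ]))
    if raw.size >= 2:
        med = float(np.median(np.diff(raw)))
        sep = max(int(round(0.25 * med)), 1)
        raw = np.sort(np.concatenate([
            _find_peaks_clean(d, cfg.step_prominence, sep),
            _find_peaks_clean(-d, cfg.step_prominence, sep),
        ]))

    ll, lr = al @ w, ar @ w
    events: list[StepEvent] = []
    for i in raw:
        if restrict_to_band and not band[i]:
            continue
        side = "left" if d[i] > 0 else "right"
        sig = d if side == "left" else -d
        events.append(StepEvent(
            t=_refine_peak_time(sig, rec.t, i), side=side,
            s_left=float(sl[i]), s_right=float(sr[i]),
            lateral_left=float(ll[i]), lateral_right=float(lr[i]),
        ))
    # enforce alternating sides: of consecutive same-side events keep the
    # one with the larger foot separation
    cleaned: list[StepEvent] = []
    for ev in events:
        if cleaned and cleaned[-1].side == ev.side:
            if ev.step_length > cleaned[-1].step_length:
                cleaned[-1] = ev
        else:
            cleaned.append(ev)
    return cleaned


def _gait_speed(rec: SkeletonRecording, cfg: FeatureConfig) -> float | None:
    """Least-squares slope of pelvis travel along the walk axis, in band."""
    try:
        u, _ = _walk_axes(rec)
    except ValueError:
        return None
    band = _band_mask(rec, cfg)
    if band.sum() < 5:
        return None
    s = _pelvis(rec) @ u
    coeff = np.polyfit(rec.t[band], s[band], 1)
    return float(abs(coeff[0]))


# ---------------------------------------------------------------------------
# per-task extractors
# ---------------------------------------------------------------------------


def _arm_swing_amplitudes(
    rec: SkeletonRecording, events: list[StepEvent], u: np.ndarray
) -> dict[str, float]:
    """Mean per-gait-cycle (max - min) wrist elevation angle, per side, deg.

    The elevation angle is measured at the manubrium from the downward
    vertical toward the anterior walk direction. Gait cycles are delimited
    by consecutive same-side step events.
    """
    manub = rec.joint("spine_shoulder")
    # cycle boundaries: consecutive left-placement events
    lefts = [ev.t for ev in events if ev.side == "left"]
    out: dict[str, float] = {}
    for side in ("left", "right"):
        wrist = rec.joint(f"wrist_{side}")
        rel = wrist - manub
        # anterior = direction of travel
        theta = np.degrees(np.arctan2(rel @ u, -rel[:, 1]))
        amps = []
        for t0, t1 in zip(lefts[:-1], lefts[1:]):
            m = (rec.t >= t0) & (rec.t <= t1)
            if m.sum() >= 3:
                amps.append(float(theta[m].max() - theta[m].min()))
        if amps:
            out[side] = float(np.mean(amps))
    return out


def extract_scsw(
    rec: SkeletonRecording, cfg: FeatureConfig | None = None
) -> FeatureVector:
    """The seven comfortable-speed-walk parameters."""
    cfg = cfg or FeatureConfig()
    fv = FeatureVector()
    speed = _gait_speed(rec, cfg)
    if speed is None:
        fv.set("scsw_gait_speed", None, REASON_OUT_OF_BAND)
    else:
        fv.set("scsw_gait_speed", speed)

    try:
        events = detect_walk_steps(rec, cfg)
        u, _ = _walk_axes(rec)
    except ValueError:
        events, u = [], None
    if len(events) < cfg.min_step_events:
        for key in ("scsw_step_length", "scsw_step_width", "scsw_step_duration",
                    "scsw_gait_cadence", "scsw_arm_angular_amplitude",
                    "scsw_arm_symmetry_angle"):
            fv.set(key, None, REASON_INSUFFICIENT_STEPS)
        return fv

    times = np.array([ev.t for ev in events])
    fv.set("scsw_step_length", 100.0 * float(np.mean([ev.step_length for ev in events])))
    fv.set("scsw_step_width", 100.0 * float(np.mean([ev.step_width for ev in events])))
    fv.set("scsw_step_duration", float(np.mean(np.diff(times))))
    fv.set("scsw_gait_cadence", 60.0 * (len(events) - 1) / float(times[-1] - times[0]))

    # gait cycles for arm swing may extend beyond the measurement band:
    # the band guards step geometry, not the arm oscillation itself
    all_events = detect_walk_steps(rec, cfg, restrict_to_band=False)
    amps = _arm_swing_amplitudes(rec, all_events, u)
    if len(amps) == 2:
        fv.set("scsw_arm_angular_amplitude", 0.5 * (amps["left"] + amps["right"]))
        try:
            fv.set("scsw_arm_symmetry_angle", symmetry_angle(amps["left"], amps["right"]))
        except ValueError:
            fv.set("scsw_arm_symmetry_angle", None, REASON_DEGENERATE)
    else:
        fv.set("scsw_arm_angular_amplitude", None, REASON_INSUFFICIENT_STEPS)
        fv.set("scsw_arm_symmetry_angle", None, REASON_INSUFFICIENT_STEPS)
    return fv


def extract_smsw(
    rec: SkeletonRecording, cfg: FeatureConfig | None = None
) -> FeatureVector:
    """Maximum-speed walk: gait speed only (other parameters lack robustness
    in the few gait cycles the sensor range allows)."""
    cfg = cfg or FeatureConfig()
    fv = FeatureVector()
    speed = _gait_speed(rec, cfg)
    fv.set("smsw_gait_speed", speed, None if speed is not None else REASON_OUT_OF_BAND)
    return fv


def extract_slw(
    rec: SkeletonRecording, cfg: FeatureConfig | None = None
) -> FeatureVector:
    """The seven tandem-gait parameters."""
    cfg = cfg or FeatureConfig()
    fv = FeatureVector()
    dt = 1.0 / rec.nominal_rate
    try:
        u, w = _walk_axes(rec)
    except ValueError:
        for p in parameters_for(Task.SLW):
            fv.set(p.key, None, REASON_OUT_OF_BAND)
        return fv
    band = _band_mask(rec, cfg)
    if band.sum() < 5:
        for p in parameters_for(Task.SLW):
            fv.set(p.key, None, REASON_OUT_OF_BAND)
        return fv

    # frame-wise progression speed (pelvis series smoothed before
    # differencing; differentiation amplifies residual landmark noise)
    s = _lowpass(_pelvis(rec) @ u, rec.nominal_rate, cfg.slw_angle_cutoff_hz)
    v = _central_rate(s, dt)[band]
    fv.set("slw_progression_speed", float(np.mean(v)))
    try:
        fv.set("slw_progression_variability", abs(coefficient_of_variation(v)))
    except ValueError:
        fv.set("slw_progression_variability", None, REASON_DEGENERATE)

    # trunk roll: spine-shoulder relative to spine-base, lateral over
    # vertical; the relative vector is smoothed before the angle is taken
    # (smoothing the folded/unsigned angle series would distort it)
    rel = _lowpass(rec.joint("spine_shoulder") - rec.joint("spine_base"),
                   rec.nominal_rate, cfg.slw_angle_cutoff_hz)
    phi = np.degrees(np.arctan2(rel @ w, rel[:, 1]))
    fv.set("slw_roll_sway_variability", float(np.std(phi[band], ddof=1)))
    fv.set("slw_roll_sway_speed", _mean_abs_rate(phi[band], dt))

    # line walk cadence: pooled peaks of ankle-minus-hip displacement along
    # the walk axis
    peak_times = []
    for side in ("left", "right"):
        rel_ap = (rec.joint(f"ankle_{side}") - rec.joint(f"hip_{side}")) @ u
        idx = _find_peaks_clean(rel_ap, cfg.slw_peak_prominence)
        peak_times.extend(_refine_peak_time(rel_ap, rec.t, i)
                          for i in idx if band[i])
    peak_times = np.sort(np.array(peak_times))
    if peak_times.size >= 3:
        span = float(peak_times[-1] - peak_times[0])
        fv.set("slw_line_walk_cadence", 60.0 * (peak_times.size - 1) / span)
    else:
        fv.set("slw_line_walk_cadence", None, REASON_INSUFFICIENT_STEPS)

    # arm movement angle: upper-arm direction vs. its time-mean, per side
    varis, speeds = [], []
    for side in ("left", "right"):
        vec = _lowpass(rec.joint(f"elbow_{side}") - rec.joint(f"shoulder_{side}"),
                       rec.nominal_rate, cfg.slw_angle_cutoff_hz)
        unit = vec / np.linalg.norm(vec, axis=1, keepdims=True)
        mean_dir = unit[band].mean(axis=0)
        mean_dir /= np.linalg.norm(mean_dir)
        psi = np.degrees(np.arccos(np.clip(unit @ mean_dir, -1.0, 1.0)))
        varis.append(float(np.std(psi[band], ddof=1)))
        speeds.append(_mean_abs_rate(psi[band], dt))
    fv.set("slw_arm_variability", float(np.mean(varis)))
    fv.set("slw_arm_speed", float(np.mean(speeds)))
    return fv


def extract_sip(
    rec: SkeletonRecording, cfg: FeatureConfig | None = None
) -> FeatureVector:
    """The six stepping-in-place parameters."""
    cfg = cfg or FeatureConfig()
    fv = FeatureVector()
    dt = 1.0 / rec.nominal_rate
    f, _ = _facing_axes(rec)

    side_amp: dict[str, float] = {}
    side_peak_times: dict[str, np.ndarray] = {}
    side_stance: dict[str, float] = {}
    for side in ("left", "right"):
        exc = rec.joint(f"knee_{side}") @ f  # anterior knee excursion
        exc = exc - np.percentile(exc, cfg.sip_baseline_percentile)
        idx = _find_peaks_clean(exc, cfg.sip_prominence)
        if idx.size >= 2:
            med = float(np.median(np.diff(idx)))
            idx = _find_peaks_clean(exc, cfg.sip_prominence,
                                    max(int(round(0.25 * med)), 1))
        if idx.size < 3:
            continue
        amp = float(np.mean(exc[idx]))
        side_amp[side] = amp
        side_peak_times[side] = np.array(
            [_refine_peak_time(exc, rec.t, i) for i in idx])
        # stance: per cycle (peak to peak), dwell below the stance fraction
        thresh = cfg.sip_stance_fraction * amp
        dwells = []
        for i0, i1 in zip(idx[:-1], idx[1:]):
            dwells.append(float(np.sum(exc[i0:i1] < thresh)) * dt)
        side_stance[side] = float(np.mean(dwells))

    if len(side_amp) < 2:
        for p in parameters_for(Task.SIP):
            fv.set(p.key, None, REASON_INSUFFICIENT_STEPS)
        return fv

    fv.set("sip_knee_amplitude", 0.5 * (side_amp["left"] + side_amp["right"]))
    try:
        fv.set("sip_knee_symmetry_angle",
               symmetry_angle(side_amp["left"], side_amp["right"]))
    except ValueError:
        fv.set("sip_knee_symmetry_angle", None, REASON_DEGENERATE)
    fv.set("sip_stance_duration",
           0.5 * (side_stance["left"] + side_stance["right"]))

    pooled = np.sort(np.concatenate([side_peak_times["left"],
                                     side_peak_times["right"]]))
    fv.set("sip_step_duration", float(np.mean(np.diff(pooled))))
    span = float(pooled[-1] - pooled[0])
    fv.set("sip_stepping_cadence", 60.0 * (pooled.size - 1) / span)

    covs = []
    for side in ("left", "right"):
        strides = np.diff(side_peak_times[side])
        if strides.size >= 2 and strides.mean() > 0:
            covs.append(coefficient_of_variation(strides))
    if covs:
        fv.set("sip_arrhythmicity", 100.0 * float(np.mean(covs)))
    else:
        fv.set("sip_arrhythmicity", None, REASON_INSUFFICIENT_STEPS)
    return fv


def _transition_bounds(v: np.ndarray, cfg: FeatureConfig) -> tuple[int, int] | None:
    """Bounds of the maximal positive-velocity episode of ``v``.

    The episode is the contiguous v > 0 region around the global maximum;
    its bounds are where v last/first crosses ``cfg.sas_threshold_fraction``
    of the episode peak.
    """
    i_peak = int(np.argmax(v))
    vpeak = v[i_peak]
    if vpeak < cfg.sas_min_peak_speed:
        return None
    thresh = cfg.sas_threshold_fraction * vpeak
    lo = i_peak
    while lo > 0 and v[lo - 1] >= thresh:
        lo -= 1
    hi = i_peak
    while hi < len(v) - 1 and v[hi + 1] >= thresh:
        hi += 1
    return lo, hi


def extract_sas(
    rec: SkeletonRecording, cfg: FeatureConfig | None = None
) -> FeatureVector:
    """The four sit-to-stand / stand-to-sit parameters."""
    cfg = cfg or FeatureConfig()
    fv = FeatureVector()
    dt = 1.0 / rec.nominal_rate
    f, _ = _facing_axes(rec)
    manub = rec.joint("spine_shoulder")
    smooth_y = _lowpass(manub[:, 1], rec.nominal_rate, cfg.sas_velocity_cutoff_hz)
    v = _central_rate(smooth_y, dt)
    ap = _lowpass(manub @ f, rec.nominal_rate, cfg.sas_velocity_cutoff_hz)

    for direction, vel, keys in (
        ("up", v, ("sas_transition_time_up", "sas_ap_deflection_up")),
        ("down", -v, ("sas_transition_time_down", "sas_ap_deflection_down")),
    ):
        bounds = _transition_bounds(vel, cfg)
        if bounds is None:
            fv.set(keys[0], None, REASON_NO_TRANSITION)
            fv.set(keys[1], None, REASON_NO_TRANSITION)
            continue
        lo, hi = bounds
        fv.set(keys[0], float(rec.t[hi] - rec.t[lo]))
        seg = ap[lo:hi + 1]
        fv.set(keys[1], float(seg.max() - seg.min()))
    return fv


def extract_poco(
    rec: SkeletonRecording,
    segment_boundary: float | None = None,
    cfg: FeatureConfig | None = None,
) -> FeatureVector:
    """The 18 postural-control parameters (two segments + Romberg ratios).

    ``segment_boundary`` defaults to ``rec.meta["segment_boundary"]``
    (seconds); the first segment is eyes open, the second eyes closed.
    """
    cfg = cfg or FeatureConfig()
    fv = FeatureVector()
    if segment_boundary is None:
        segment_boundary = rec.meta.get("segment_boundary")
    if segment_boundary is None:
        raise ValueError("POCO extraction needs a segment boundary (protocol metadata)")
    dt = 1.0 / rec.nominal_rate
    f, w = _facing_axes(rec)
    pelvis = _pelvis(rec)
    ankle_mid = 0.5 * (rec.joint("ankle_left") + rec.joint("ankle_right"))

    seg_values: dict[str, dict[str, float]] = {}
    for label, mask in (
        ("open", rec.t < segment_boundary),
        ("closed", rec.t >= segment_boundary),
    ):
        if mask.sum() * dt < cfg.poco_min_segment:
            seg_values[label] = {}
            continue
        a = ankle_mid[mask].mean(axis=0)  # fixed per-segment reference point
        s = _lowpass(pelvis[mask] - a, rec.nominal_rate, cfg.poco_angle_cutoff_hz)
        anterior = s @ f
        lateral = s @ w
        vertical = s[:, 1]
        pitch = np.degrees(np.arctan2(anterior, vertical))
        roll = np.degrees(np.arctan2(lateral, vertical))
        unit = s / np.linalg.norm(s, axis=1, keepdims=True)
        mean_dir = unit.mean(axis=0)
        mean_dir /= np.linalg.norm(mean_dir)
        incl = np.degrees(np.arccos(np.clip(unit @ mean_dir, -1.0, 1.0)))
        step = np.degrees(np.arccos(np.clip(
            np.sum(unit[1:] * unit[:-1], axis=1), -1.0, 1.0)))
        seg_values[label] = {
            "pitch_range": float(pitch.max() - pitch.min()),
            "roll_range": float(roll.max() - roll.min()),
            "3d_range": float(incl.max() - incl.min()),
            "pitch_speed": _mean_abs_rate(pitch, dt),
            "roll_speed": _mean_abs_rate(roll, dt),
            "3d_speed": float(np.mean(step)) / dt,
        }

    for label in ("open", "closed"):
        for meas in ("pitch_range", "roll_range", "3d_range",
                     "pitch_speed", "roll_speed", "3d_speed"):
            key = f"poco_{meas.replace('_range', '')}_range_{label}" \
                if meas.endswith("range") else \
                f"poco_{meas.replace('_speed', '')}_speed_{label}"
            val = seg_values[label].get(meas)
            fv.set(key, val, None if val is not None else REASON_SHORT_SEGMENT)

    for meas in ("pitch_range", "roll_range", "3d_range",
                 "pitch_speed", "roll_speed", "3d_speed"):
        stem = meas.replace("_range", "").replace("_speed", "")
        kind = "range" if meas.endswith("range") else "speed"
        key = f"poco_rr_{stem}_{kind}"
        op = seg_values["open"].get(meas)
        cl = seg_values["closed"].get(meas)
        if op is None or cl is None:
            fv.set(key, None, REASON_SHORT_SEGMENT)
        elif op <= cfg.poco_degenerate_floor:
            fv.set(key, None, REASON_DEGENERATE)
        else:
            fv.set(key, romberg_ratio(cl, op))
    return fv


_EXTRACTORS = {
    Task.SCSW: extract_scsw,
    Task.SMSW: extract_smsw,
    Task.SLW: extract_slw,
    Task.SIP: extract_sip,
    Task.SAS: extract_sas,
    Task.POCO: extract_poco,
}


def extract_features(
    rec: SkeletonRecording, cfg: FeatureConfig | None = None
) -> FeatureVector:
    """Dispatch to the task-specific extractor of a preprocessed recording."""
    return _EXTRACTORS[rec.task](rec, cfg=cfg)
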