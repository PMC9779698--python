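"""Reading, writing and preprocessing of skeleton recordings.

The interchange format is a CSV file with one row per frame and columns
``t, <joint>_x, <joint>_y, <joint>_z, ...`` for the 25 canonical joints in
fixed order (seconds / meters, ``NaN`` for missing coordinates), plus a JSON
sidecar with the task and subject metadata. Preprocessing levels the sensor
tilt, bridges short tracking gaps, resamples to a uniform rate and applies a
zero-phase low-pass filter — the standard conditioning steps before
spatiotemporal parameter extraction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .joints import JOINTS, N_JOINTS
from .types import SkeletonRecording, Subject, Task


class RecordingFormatError(ValueError):
    """Raised when a recording file violates the interchange format."""


def _columns() -> list[str]:
    cols = ["t"]
    for j in JOINTS:
        cols += [f"{j}_x", f"{j}_y", f"{j}_z"]
    return cols


def sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(".json")


def write_recording(recording: SkeletonRecording, path: str | Path) -> Path:
    """Serialize a recording to CSV + JSON sidecar, losslessly.

    Floats are written with 17 significant digits so the CSV round-trips
    bit-exactly.
    """
    path = Path(path)
    n = recording.n_frames
    data = np.empty((n, 1 + 3 * N_JOINTS))
    data[:, 0] = recording.t
    data[:, 1:] = recording.pos.reshape(n, -1)
    df = pd.DataFrame(data, columns=_columns())
    df.to_csv(path, index=False, float_format="%.17g", na_rep="NaN")

    side = {
        "task": recording.task.value,
        "nominal_rate": recording.nominal_rate,
        "repetition_index": recording.repetition_index,
        "sensor_pitch": recording.sensor_pitch,
        "meta": recording.meta,
    }
    if recording.subject is not None:
        s = recording.subject
        side["subject"] = {
            "id": s.subject_id,
            "age": s.age,
            "sex": s.sex,
            "height_cm": s.height,
            "weight_kg": s.weight,
            "study": s.study,
        }
    with open(sidecar_path(path), "w") as fh:
        json.dump(side, fh, indent=1)
    return path


def read_recording(path: str | Path, sidecar: str | Path | None = None) -> SkeletonRecording:
    """Read a recording CSV and its metadata sidecar.

    Missing coordinates (NaN cells) are flagged invalid. Malformed headers,
    non-monotonic timestamps and unknown task codes raise
    :class:`RecordingFormatError` with a descriptive message.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = Path(sidecar) if sidecar is not None else sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"metadata sidecar not found: {sidecar}")

    df = pd.read_csv(path, float_precision="round_trip")
    expected = _columns()
    if list(df.columns) != expected:
        raise RecordingFormatError(
            f"malformed header in {path.name}: expected columns "
            f"{expected[:4]}... for the 25 canonical joints"
        )
    t = df["t"].to_numpy(dtype=float)
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        raise RecordingFormatError(
            f"non-monotonic timestamps in {path.name} at data row {bad[0] + 2}"
        )
    pos = df.iloc[:, 1:].to_numpy(dtype=float).reshape(len(df), N_JOINTS, 3)
    valid = np.all(np.isfinite(pos), axis=2)

    with open(sidecar) as fh:
        side = json.load(fh)
    try:
        task = Task(side["task"])
    except (KeyError, ValueError):
        raise RecordingFormatError(
            f"unknown task code {side.get('task')!r} in {sidecar.name}; "
            f"expected one of {[tk.value for tk in Task]}"
        ) from None
    subject = None
    if "subject" in side:
        sj = side["subject"]
        subject = Subject(
            subject_id=str(sj["id"]),
            age=float(sj["age"]),
            sex=str(sj["sex"]),
            height=float(sj["height_cm"]),
            weight=float(sj["weight_kg"]),
            study=str(sj.get("study", "default")),
        )
    return SkeletonRecording(
        t=t,
        pos=pos,
        valid=valid,
        task=task,
        nominal_rate=float(side.get("nominal_rate", 30.0)),
        repetition_index=int(side.get("repetition_index", 1)),
        sensor_pitch=float(side.get("sensor_pitch", 0.0)),
        subject=subject,
        meta=dict(side.get("meta", {})),
    )


@dataclass
class PreprocessConfig:
    """Settings for the preprocessing chain.

    max_gap : float
        Longest tracking gap (s) bridged by linear interpolation; longer
        gaps flag the recording for QC discard.
    cutoff_hz : float
        Low-pass cutoff of the zero-phase Butterworth filter. 6 Hz keeps
        all voluntary-movement content of gait and transitions; sway tasks
        may configure a lower cutoff.
    filter_order : int
        Butterworth order (applied forward-backward, so the effective
        attenuation is doubled).
    """

    max_gap: float = 0.5
    cutoff_hz: float = 6.0
    filter_order: int = 4
    tilt_correct: bool = True
    resample: bool = True
    lowpass: bool = True


def _rotation_about_lateral(angle_deg: float) -> np.ndarray:
    """Right-handed rotation matrix about the lateral (+x) axis."""
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _fill_gaps(t: np.ndarray, pos: np.ndarray, valid: np.ndarray, max_gap: float):
    """Linearly interpolate NaN gaps per joint/coordinate.

    Gaps no longer than ``max_gap`` seconds become valid; longer internal
    gaps are still filled (so filtering stays well-defined) but are reported
    so QC can discard the recording. Leading/trailing gaps are held at the
    nearest valid sample and stay invalid.
    """
    pos = pos.copy()
    valid_out = valid.copy()
    flagged: list[str] = []
    for j in range(pos.shape[1]):
        ok = valid[:, j]
        if ok.all():
            continue
        if not ok.any():
            flagged.append(JOINTS[j])
            continue
        idx_ok = np.flatnonzero(ok)
        for axis in range(3):
            pos[:, j, axis] = np.interp(t, t[idx_ok], pos[idx_ok, j, axis])
        # classify each internal gap by its duration
        gap_start = None
        for i in range(len(t)):
            if not ok[i] and gap_start is None:
                gap_start = i
            elif ok[i] and gap_start is not None:
                if gap_start > 0:  # internal gap
                    dur = t[i] - t[gap_start - 1]
                    if dur <= max_gap:
                        valid_out[gap_start:i, j] = True
                    else:
                        flagged.append(JOINTS[j])
                gap_start = None
        if gap_start is not None and gap_start > 0:
            # trailing gap: held, stays invalid
            pass
    return pos, valid_out, sorted(set(flagged))


def preprocess(
    recording: SkeletonRecording, config: PreprocessConfig | None = None
) -> SkeletonRecording:
    """Tilt-correct, gap-fill, resample and low-pass filter a recording.

    Steps (each toggleable via :class:`PreprocessConfig`):

    1. rotate all coordinates by ``-sensor_pitch`` about the lateral axis,
       so the vertical axis is gravity-aligned;
    2. bridge tracking gaps up to ``max_gap`` seconds by linear
       interpolation (longer gaps set ``meta["qc_gap_exceeded"]`` — the
       recording is flagged for QC discard, not silently fixed);
    3. resample to the uniform nominal rate by linear interpolation;
    4. apply a zero-phase Butterworth low-pass.
    """
    cfg = config or PreprocessConfig()
    t = recording.t - recording.t[0]
    pos = recording.pos
    valid = recording.valid

    if cfg.tilt_correct and recording.sensor_pitch != 0.0:
        rot = _rotation_about_lateral(-recording.sensor_pitch)
        pos = pos @ rot.T
        sensor_pitch = 0.0
    else:
        pos = pos.copy()
        sensor_pitch = recording.sensor_pitch

    pos, valid, flagged = _fill_gaps(t, pos, valid, cfg.max_gap)
    meta = dict(recording.meta)
    if flagged:
        meta["qc_gap_exceeded"] = flagged

    if cfg.resample:
        dt = 1.0 / recording.nominal_rate
        n_out = int(np.floor(t[-1] / dt)) + 1
        t_out = np.arange(n_out) * dt
        pos_out = np.empty((n_out, N_JOINTS, 3))
        flat = pos.reshape(len(t), -1)
        for k in range(flat.shape[1]):
            pos_out.reshape(n_out, -1)[:, k] = np.interp(t_out, t, flat[:, k])
        # a resampled frame is valid if its bracketing source frames are
        src_idx = np.clip(np.searchsorted(t, t_out, side="right") - 1, 0, len(t) - 2)
        valid_out = valid[src_idx] & valid[np.minimum(src_idx + 1, len(t) - 1)]
        t, pos, valid = t_out, pos_out, valid_out

    if cfg.lowpass and cfg.cutoff_hz > 0:
        rate = recording.nominal_rate
        nyq = rate / 2.0
        if cfg.cutoff_hz < nyq:
            b, a = butter(cfg.filter_order, cfg.cutoff_hz / nyq)
            padlen = min(3 * (max(len(a), len(b)) - 1) * 3, len(t) - 1)
            flat = pos.reshape(len(t), -1)
            flat = filtfilt(b, a, flat, axis=0, padlen=padlen)
            pos = flat.reshape(len(t), N_JOINTS, 3)

    meta["preprocessed"] = True
    return SkeletonRecording(
        t=t,
        pos=pos,
        valid=valid,
        task=recording.task,
        nominal_rate=recording.nominal_rate,
        repetition_index=recording.repetition_index,
        sensor_pitch=sensor_pitch,
        subject=recording.subject,
        meta=meta,
    )
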