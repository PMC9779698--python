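"""Core data model: tasks, skeleton recordings, subjects, feature vectors."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from .joints import N_JOINTS


class Task(str, Enum):
    """The six standardized motor tasks."""

    SCSW = "SCSW"  # short comfortable speed walk
    SMSW = "SMSW"  # short maximum speed walk
    SLW = "SLW"    # short line walk (tandem gait)
    SIP = "SIP"    # stepping in place
    SAS = "SAS"    # standing up and sitting down
    POCO = "POCO"  # postural control


@dataclass
class Subject:
    """Demographic and anthropometric covariates of one participant."""

    subject_id: str
    age: float          # years
    sex: str            # "female" | "male"
    height: float       # cm
    weight: float       # kg
    study: str = "default"

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        for name in ("age", "height", "weight"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite, got {v}")

    @property
    def sex_code(self) -> int:
        """Dummy coding used by the confound models: female = 0, male = 1."""
        return 1 if self.sex == "male" else 0


@dataclass
class SkeletonRecording:
    """A timestamped 25-landmark 3D trajectory for one task repetition.

    Attributes
    ----------
    t : (n,) float array
        Seconds since recording start, strictly increasing.
    pos : (n, 25, 3) float array
        Landmark positions in meters, camera frame (x lateral, y up,
        z depth). NaN where a landmark is missing.
    valid : (n, 25) bool array
        True where the landmark was tracked (finite coordinates).
    task : Task
    nominal_rate : float
        Nominal sampling rate in Hz (consumer depth cameras run ~30 Hz).
    repetition_index : int
    sensor_pitch : float
        Sensor pitch in degrees (negative = tilted downward); used by the
        preprocessing tilt correction.
    subject : Subject | None
    meta : dict
        Free-form protocol metadata. POCO recordings carry
        ``meta["segment_boundary"]`` (seconds) between the eyes-open and
        eyes-closed segments.
    """

    t: np.ndarray
    pos: np.ndarray
    valid: np.ndarray
    task: Task
    nominal_rate: float = 30.0
    repetition_index: int = 1
    sensor_pitch: float = 0.0
    subject: Subject | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.pos = np.asarray(self.pos, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.task = Task(self.task)
        n = self.t.shape[0]
        if n < 2:
            raise ValueError("recording needs at least 2 frames")
        if self.pos.shape != (n, N_JOINTS, 3):
            raise ValueError(
                f"pos must have shape ({n}, {N_JOINTS}, 3), got {self.pos.shape}"
            )
        if self.valid.shape != (n, N_JOINTS):
            raise ValueError(
                f"valid must have shape ({n}, {N_JOINTS}), got {self.valid.shape}"
            )
        if not np.all(np.isfinite(self.t)) or self.t[0] < 0:
            raise ValueError("timestamps must be finite and non-negative")
        bad = np.flatnonzero(np.diff(self.t) <= 0)
        if bad.size:
            raise ValueError(
                f"timestamps must be strictly increasing; violation at frame {bad[0] + 1}"
            )
        if self.repetition_index < 1:
            raise ValueError("repetition_index must be >= 1")

    @property
    def n_frames(self) -> int:
        return self.t.shape[0]

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def joint(self, name: str) -> np.ndarray:
        """(n, 3) trajectory of one joint by canonical name."""
        from .joints import jidx

        return self.pos[:, jidx(name), :]

    def copy_with(self, **kwargs) -> "SkeletonRecording":
        out = replace(self, **kwargs)
        return out


@dataclass
class FeatureValue:
    """One spatiotemporal parameter value, or the reason it is absent."""

    value: float | None
    reason: str | None = None

    @property
    def present(self) -> bool:
        return self.value is not None


class FeatureVector(dict):
    """Mapping parameter-name -> FeatureValue for one recording or subject."""

    def set(self, name: str, value: float | None, reason: str | None = None) -> None:
        if value is not None and not np.isfinite(value):
            value, reason = None, reason or "non-finite result"
        self[name] = FeatureValue(None if value is None else float(value), reason)

    def value(self, name: str) -> float | None:
        fv = self.get(name)
        return fv.value if fv is not None else None

    def present_items(self) -> dict[str, float]:
        return {k: v.value for k, v in self.items() if v.present}
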