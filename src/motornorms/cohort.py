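"""Cohort-level machinery: quality control, repetition averaging, and
normative descriptive statistics.

The normative table reports, per parameter, the group mean, sample SD,
coefficient of variation and quartiles over per-participant averages —
the reference against which individual z-scores are later computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import ALL_KEYS, PARAMETER_INDEX
from .types import FeatureVector, SkeletonRecording, Task

QC_TOO_SHORT = "too-short"
QC_GAP_EXCEEDED = "gap-exceeded"
QC_NO_DISPLACEMENT = "no-displacement"
QC_WRONG_POSTURE = "wrong-posture"


@dataclass
class QCRules:
    """Configurable post hoc quality-control rules.

    Basic heuristics only: minimum duration per task, a gap flag from
    preprocessing, and task-specific sanity checks (walks must cover the
    measurement path; a postural-control subject must not wander off).
    """

    min_duration: dict[Task, float] = field(default_factory=lambda: {
        Task.SCSW: 2.0, Task.SMSW: 1.5, Task.SLW: 4.0,
        Task.SIP: 30.0, Task.SAS: 5.0, Task.POCO: 35.0,
    })
    walk_min_displacement: float = 1.5   # m net pelvis travel for gait tasks
    poco_max_drift: float = 0.3          # m horizontal pelvis drift for POCO


@dataclass
class QCVerdict:
    recording_id: str
    passed: bool
    reasons: list[str]

    def __post_init__(self) -> None:
        assert self.passed == (len(self.reasons) == 0)


def run_qc(
    rec: SkeletonRecording, rules: QCRules | None = None,
    recording_id: str = "",
) -> QCVerdict:
    """Deterministic pass/fail verdict for one preprocessed recording."""
    rules = rules or QCRules()
    reasons: list[str] = []
    min_dur = rules.min_duration.get(rec.task, 0.0)
    if rec.duration < min_dur:
        reasons.append(QC_TOO_SHORT)
    if rec.meta.get("qc_gap_exceeded"):
        reasons.append(QC_GAP_EXCEEDED)
    pelvis = rec.joint("spine_base")
    horiz = pelvis[:, [0, 2]]
    if rec.task in (Task.SCSW, Task.SMSW, Task.SLW):
        if np.linalg.norm(horiz[-1] - horiz[0]) < rules.walk_min_displacement:
            reasons.append(QC_NO_DISPLACEMENT)
    if rec.task == Task.POCO:
        drift = np.linalg.norm(horiz - horiz.mean(axis=0), axis=1).max()
        if drift > rules.poco_max_drift:
            reasons.append(QC_WRONG_POSTURE)
    return QCVerdict(recording_id=recording_id, passed=not reasons,
                     reasons=reasons)


def average_repetitions(vectors: list[FeatureVector]) -> FeatureVector:
    """Per-parameter arithmetic mean over the repetitions of one
    subject-task; a parameter absent in every repetition stays absent."""
    if not vectors:
        raise ValueError("need at least one passing repetition")
    out = FeatureVector()
    keys: list[str] = []
    for fv in vectors:
        for k in fv:
            if k not in keys:
                keys.append(k)
    for k in keys:
        vals = [fv[k].value for fv in vectors if k in fv and fv[k].present]
        if vals:
            out.set(k, float(np.mean(vals)))
        else:
            reasons = [fv[k].reason for fv in vectors if k in fv and fv[k].reason]
            out.set(k, None, reasons[0] if reasons else "absent in all repetitions")
    return out


@dataclass
class NormativeEntry:
    """Descriptive statistics of one parameter over the normative cohort."""

    parameter: str
    n: int
    mean: float
    sd: float
    cov: float
    q1: float
    q3: float
    rtest2: float | None = None  # mean test-fold R^2, filled by confound models

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("normative entry needs n >= 2")
        if self.sd < 0 or self.q1 > self.q3:
            raise ValueError("invalid normative entry")


def describe_parameter(values, parameter: str = "") -> NormativeEntry:
    """Mean, sample SD (n-1), CoV = SD/mean, and quartiles (linear
    interpolation between order statistics)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError(f"need >= 2 values to describe {parameter or 'a parameter'}")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    cov = sd / mean if mean != 0 else float("nan")
    q1, q3 = (float(q) for q in np.quantile(v, [0.25, 0.75], method="linear"))
    return NormativeEntry(parameter=parameter, n=int(v.size), mean=mean,
                          sd=sd, cov=cov, q1=q1, q3=q3)


def build_normative_table(features: pd.DataFrame) -> pd.DataFrame:
    """Normative table from per-subject averaged features.

    ``features``: one row per subject, one column per parameter key (NaN
    where absent). Returns one row per parameter with columns
    ``task, n, mean, sd, cov, q1, q3`` (parameters with fewer than two
    subjects appear with NaN statistics).
    """
    rows = []
    for key in ALL_KEYS:
        task = PARAMETER_INDEX[key].task.value
        if key not in features.columns:
            rows.append({"parameter": key, "task": task, "n": 0})
            continue
        col = features[key].to_numpy(dtype=float)
        col = col[np.isfinite(col)]
        if col.size < 2:
            rows.append({"parameter": key, "task": task, "n": int(col.size)})
            continue
        e = describe_parameter(col, key)
        rows.append({
            "parameter": key, "task": task, "n": e.n, "mean": e.mean,
            "sd": e.sd, "cov": e.cov, "q1": e.q1, "q3": e.q3,
        })
    return pd.DataFrame(rows).set_index("parameter")


def features_to_frame(per_subject: dict[str, FeatureVector]) -> pd.DataFrame:
    """Stack per-subject feature vectors into a subjects x parameters frame."""
    data = {
        sid: {k: fv[k].value for k in fv if fv[k].present}
        for sid, fv in per_subject.items()
    }
    frame = pd.DataFrame.from_dict(data, orient="index")
    return frame.reindex(columns=[k for k in ALL_KEYS if k in frame.columns])
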