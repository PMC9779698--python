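"""Registry of the 43 spatiotemporal parameters.

Each parameter has a stable snake_case key (used in feature vectors, CSVs
and the normative resource), the task it belongs to, a human-readable label
and the reporting unit.
"""

from __future__ import annotations

from dataclasses import dataclass

from .types import Task


@dataclass(frozen=True)
class ParameterDef:
    key: str
    task: Task
    label: str
    unit: str


def _p(key: str, task: Task, label: str, unit: str) -> ParameterDef:
    return ParameterDef(key, task, label, unit)


PARAMETERS: tuple[ParameterDef, ...] = (
    # --- short comfortable speed walk ---
    _p("scsw_gait_speed", Task.SCSW, "Gait speed", "m/s"),
    _p("scsw_step_length", Task.SCSW, "Step length", "cm"),
    _p("scsw_step_width", Task.SCSW, "Step width", "cm"),
    _p("scsw_step_duration", Task.SCSW, "Step duration", "s"),
    _p("scsw_gait_cadence", Task.SCSW, "Gait cadence", "steps/min"),
    _p("scsw_arm_angular_amplitude", Task.SCSW, "Arm angular amplitude", "deg"),
    _p("scsw_arm_symmetry_angle", Task.SCSW, "Arm symmetry angle", "n.u."),
    # --- short maximum speed walk ---
    _p("smsw_gait_speed", Task.SMSW, "Gait speed", "m/s"),
    # --- short line walk (tandem gait) ---
    _p("slw_progression_speed", Task.SLW, "Progression speed", "m/s"),
    _p("slw_progression_variability", Task.SLW, "Relative progression variability", "fraction"),
    _p("slw_roll_sway_variability", Task.SLW, "Roll sway variability", "deg"),
    _p("slw_roll_sway_speed", Task.SLW, "Roll sway speed", "deg/s"),
    _p("slw_line_walk_cadence", Task.SLW, "Line walk cadence", "steps/min"),
    _p("slw_arm_variability", Task.SLW, "Arm variability", "deg"),
    _p("slw_arm_speed", Task.SLW, "Arm speed", "deg/s"),
    # --- stepping in place ---
    _p("sip_knee_amplitude", Task.SIP, "Knee amplitude", "m"),
    _p("sip_step_duration", Task.SIP, "Step duration", "s"),
    _p("sip_stance_duration", Task.SIP, "Stance duration", "s"),
    _p("sip_stepping_cadence", Task.SIP, "Stepping cadence", "steps/min"),
    _p("sip_knee_symmetry_angle", Task.SIP, "Knee symmetry angle", "n.u."),
    _p("sip_arrhythmicity", Task.SIP, "Arrhythmicity", "%"),
    # --- standing up and sitting down ---
    _p("sas_transition_time_up", Task.SAS, "Transition time (up)", "s"),
    _p("sas_transition_time_down", Task.SAS, "Transition time (down)", "s"),
    _p("sas_ap_deflection_up", Task.SAS, "AP deflection range (up)", "m"),
    _p("sas_ap_deflection_down", Task.SAS, "AP deflection range (down)", "m"),
    # --- postural control ---
    _p("poco_pitch_range_open", Task.POCO, "Pitch sway range (open eyes)", "deg"),
    _p("poco_roll_range_open", Task.POCO, "Roll sway range (open eyes)", "deg"),
    _p("poco_3d_range_open", Task.POCO, "3D sway range (open eyes)", "deg"),
    _p("poco_pitch_speed_open", Task.POCO, "Pitch sway speed (open eyes)", "deg/s"),
    _p("poco_roll_speed_open", Task.POCO, "Roll sway speed (open eyes)", "deg/s"),
    _p("poco_3d_speed_open", Task.POCO, "3D sway speed (open eyes)", "deg/s"),
    _p("poco_pitch_range_closed", Task.POCO, "Pitch sway range (closed eyes)", "deg"),
    _p("poco_roll_range_closed", Task.POCO, "Roll sway range (closed eyes)", "deg"),
    _p("poco_3d_range_closed", Task.POCO, "3D sway range (closed eyes)", "deg"),
    _p("poco_pitch_speed_closed", Task.POCO, "Pitch sway speed (closed eyes)", "deg/s"),
    _p("poco_roll_speed_closed", Task.POCO, "Roll sway speed (closed eyes)", "deg/s"),
    _p("poco_3d_speed_closed", Task.POCO, "3D sway speed (closed eyes)", "deg/s"),
    _p("poco_rr_pitch_range", Task.POCO, "Romberg ratio of pitch sway range", "n.u."),
    _p("poco_rr_roll_range", Task.POCO, "Romberg ratio of roll sway range", "n.u."),
    _p("poco_rr_3d_range", Task.POCO, "Romberg ratio of 3D sway range", "n.u."),
    _p("poco_rr_pitch_speed", Task.POCO, "Romberg ratio of pitch sway speed", "n.u."),
    _p("poco_rr_roll_speed", Task.POCO, "Romberg ratio of roll sway speed", "n.u."),
    _p("poco_rr_3d_speed", Task.POCO, "Romberg ratio of 3D sway speed", "n.u."),
)

assert len(PARAMETERS) == 43

PARAMETER_INDEX: dict[str, ParameterDef] = {p.key: p for p in PARAMETERS}

ALL_KEYS: tuple[str, ...] = tuple(p.key for p in PARAMETERS)


def parameters_for(task: Task) -> tuple[ParameterDef, ...]:
    return tuple(p for p in PARAMETERS if p.task == task)
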