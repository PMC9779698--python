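"""Canonical 25-landmark skeleton joint set.

The landmark set follows the Kinect v2 SDK skeleton: 25 named joints in a
fixed order. Anatomical aliases used in the movement-analysis literature map
onto this set: the "pelvic center" is the spine-base joint and the
"manubrium" is the spine-shoulder joint.

Coordinate convention (right-handed camera frame):
    +x  to the subject's left when facing the sensor (lateral)
    +y  up (vertical)
    +z  from the sensor toward the subject (depth / anterior-posterior
        for a subject facing the sensor)
A subject walking toward the sensor has decreasing z.
"""

from __future__ import annotations

JOINTS: tuple[str, ...] = (
    "spine_base",
    "spine_mid",
    "neck",
    "head",
    "shoulder_left",
    "elbow_left",
    "wrist_left",
    "hand_left",
    "shoulder_right",
    "elbow_right",
    "wrist_right",
    "hand_right",
    "hip_left",
    "knee_left",
    "ankle_left",
    "foot_left",
    "hip_right",
    "knee_right",
    "ankle_right",
    "foot_right",
    "spine_shoulder",
    "hand_tip_left",
    "thumb_left",
    "hand_tip_right",
    "thumb_right",
)

N_JOINTS = len(JOINTS)

JOINT_INDEX: dict[str, int] = {name: i for i, name in enumerate(JOINTS)}

# anatomical aliases
PELVIC_CENTER = "spine_base"
MANUBRIUM = "spine_shoulder"

# axis indices in the (x, y, z) coordinate triplet
LATERAL, VERTICAL, DEPTH = 0, 1, 2


def jidx(name: str) -> int:
    """Index of a joint by canonical name (raises KeyError on unknown names)."""
    return JOINT_INDEX[name]
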