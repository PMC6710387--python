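"""Fixed upper-body geometry mapping joint angles to hand position.

A deliberately simple kinematic chain — trunk pitch, two-link arm
(upper arm 30 cm, forearm+hand 35 cm split as 25 cm forearm + 10 cm hand
lever), and a 6 cm finger offset swung by forearm supination — expressed
in the pelvis frame (x forward, y left, z up). It is a shared convention
between the simulator and the effector-attribution rule, not a per-subject
calibration: what matters is that angle changes in each joint group move
the endpoint with anatomically sensible lever arms (trunk > shoulder/elbow
> wrist > supination).
"""
from __future__ import annotations

import numpy as np

from .types import ANGLE_NAMES

# segment lengths, centimeters
TRUNK_LEN = 40.0
SHOULDER_OFFSET_Y = -18.0  # right shoulder sits to the right of midline
UPPER_ARM_LEN = 30.0
FOREARM_LEN = 25.0
HAND_LEN = 10.0  # wrist-extension lever
FINGER_OFFSET = 6.0  # supination lever

#: Joint-group membership used for effector attribution (indices into ANGLE_NAMES).
AXIAL_JOINTS = ("trunk_flexion",)
PROXIMAL_JOINTS = ("shoulder_flexion", "shoulder_abduction", "elbow_flexion")
DISTAL_JOINTS = ("forearm_supination", "wrist_extension")

GROUP_INDICES = {
    "axial": tuple(ANGLE_NAMES.index(j) for j in AXIAL_JOINTS),
    "proximal": tuple(ANGLE_NAMES.index(j) for j in PROXIMAL_JOINTS),
    "distal": tuple(ANGLE_NAMES.index(j) for j in DISTAL_JOINTS),
}


def _rotate(v: np.ndarray, axis: np.ndarray, ang: np.ndarray) -> np.ndarray:
    """Rodrigues rotation of vectors ``v`` about unit ``axis`` by ``ang`` rad.

    All arguments broadcast over leading axes; vectors are (..., 3).
    """
    ang = np.asarray(ang)[..., None]
    c, s = np.cos(ang), np.sin(ang)
    dot = np.sum(axis * v, axis=-1, keepdims=True)
    return v * c + np.cross(axis, v) * s + axis * dot * (1.0 - c)


def endpoint_from_angles(angles_deg: np.ndarray) -> np.ndarray:
    """Hand endpoint position (cm, pelvis frame) for angle rows.

    Parameters
    ----------
    angles_deg : (n, 6) or (6,) array
        Joint angles in degrees, ordered as :data:`uemotion.types.ANGLE_NAMES`.
    """
    a = np.deg2rad(np.atleast_2d(np.asarray(angles_deg, dtype=float)))
    trunk, sh_flex, sh_abd, elbow, supin, wrist = (a[:, i] for i in range(6))
    n = a.shape[0]

    down = np.broadcast_to(np.array([0.0, 0.0, -1.0]), (n, 3))
    y_axis = np.broadcast_to(np.array([0.0, 1.0, 0.0]), (n, 3))
    x_axis = np.broadcast_to(np.array([1.0, 0.0, 0.0]), (n, 3))

    # shoulder orientation: abduction about x (arm swings laterally),
    # then flexion about -y (arm swings forward)
    upper = _rotate(down, x_axis, sh_abd)
    upper = _rotate(upper, y_axis, -sh_flex)
    elbow_axis = _rotate(_rotate(y_axis, x_axis, sh_abd), y_axis, -sh_flex)

    fore = _rotate(upper, elbow_axis, -elbow)  # elbow flexion bends forearm forward
    hand = _rotate(fore, elbow_axis, -wrist)  # wrist extension tilts the hand lever

    normal = np.cross(elbow_axis, fore)
    normal = normal / np.linalg.norm(normal, axis=-1, keepdims=True)
    finger = _rotate(normal, fore, supin)

    shoulder_local = np.array([0.0, SHOULDER_OFFSET_Y, TRUNK_LEN])
    endpoint_local = (
        shoulder_local
        + UPPER_ARM_LEN * upper
        + FOREARM_LEN * fore
        + HAND_LEN * hand
        + FINGER_OFFSET * finger
    )

    # trunk flexion pitches everything forward about the pelvis y axis
    endpoint = _rotate(endpoint_local, y_axis, trunk)
    if np.asarray(angles_deg).ndim == 1:
        return endpoint[0]
    return endpoint


def group_frame_displacements(angles_deg: np.ndarray) -> dict:
    """Per-frame endpoint displacement attributable to each joint group.

    For every consecutive frame pair ``i -> i+1`` and each group, the
    displacement is the endpoint motion predicted from that group's angle
    changes with the other groups frozen at frame ``i``.

    Returns a dict ``{"axial": (n-1,), "proximal": (n-1,), "distal": (n-1,)}``
    of displacement magnitudes in centimeters.
    """
    a = np.asarray(angles_deg, dtype=float)
    if a.ndim != 2 or a.shape[0] < 2:
        return {g: np.zeros(max(a.shape[0] - 1, 0)) for g in GROUP_INDICES}
    base = endpoint_from_angles(a[:-1])
    out = {}
    for group, idx in GROUP_INDICES.items():
        moved = a[:-1].copy()
        moved[:, list(idx)] = a[1:, list(idx)]
        out[group] = np.linalg.norm(endpoint_from_angles(moved) - base, axis=-1)
    return out
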