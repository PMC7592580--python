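"""Capture-posture validation.

During a multi-view capture the patient must hold the arm away from the
trunk so the sensor sees the whole limb: abduction of at least 75 degrees
for the front and back views, at least 45 degrees for the two side views,
and no more than 5 degrees of anterior shoulder flexion.  The scanner's
on-screen silhouette turns from red to blue once the posture is compliant;
:func:`check_pose` is that feedback signal as a pure per-frame function,
and :func:`pose_from_landmarks` recovers the two angles from skeletal
landmarks.

Thresholds are inclusive (75/45/5 themselves are compliant) and the flexion
limit is applied to every view by default — a conservative reading, since
the protocol states it for the anterior capture; pass
``flexion_all_views=False`` to restrict it to front/back.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import DegeneratePoseError, InvalidParameterError, InvalidViewError

__all__ = [
    "ABDUCTION_MIN_FRONT_BACK_DEG",
    "ABDUCTION_MIN_SIDE_DEG",
    "FLEXION_MAX_DEG",
    "PoseState",
    "check_pose",
    "pose_from_landmarks",
]

ABDUCTION_MIN_FRONT_BACK_DEG = 75.0
ABDUCTION_MIN_SIDE_DEG = 45.0
FLEXION_MAX_DEG = 5.0

View = Literal["front", "back", "left", "right"]
_FRONT_BACK = ("front", "back")
_SIDES = ("left", "right")


@dataclass(frozen=True)
class PoseState:
    """One posture verdict: the angles, the view, and the feedback colour."""

    abduction_deg: float
    flexion_deg: float
    view: View
    compliant: bool

    @property
    def feedback(self) -> Literal["blue", "red"]:
        return "blue" if self.compliant else "red"


def check_pose(
    abduction_deg: float,
    flexion_deg: float,
    view: View,
    flexion_all_views: bool = True,
) -> PoseState:
    """Judge a posture against the capture criteria for one view.

    Compliant iff abduction meets the view's minimum (75 deg front/back,
    45 deg sides, inclusive) and flexion is at most 5 deg (inclusive).
    """
    if view in _FRONT_BACK:
        abduction_min = ABDUCTION_MIN_FRONT_BACK_DEG
    elif view in _SIDES:
        abduction_min = ABDUCTION_MIN_SIDE_DEG
    else:
        raise InvalidViewError(f"unknown view {view!r}")
    if not (math.isfinite(abduction_deg) and math.isfinite(flexion_deg)):
        raise InvalidParameterError("pose angles must be finite")
    if not (0.0 <= abduction_deg <= 180.0 and 0.0 <= flexion_deg <= 180.0):
        raise InvalidParameterError("pose angles must lie in [0, 180] degrees")
    flexion_applies = flexion_all_views or view in _FRONT_BACK
    compliant = abduction_deg >= abduction_min and (
        not flexion_applies or flexion_deg <= FLEXION_MAX_DEG
    )
    return PoseState(
        abduction_deg=float(abduction_deg),
        flexion_deg=float(flexion_deg),
        view=view,
        compliant=bool(compliant),
    )


def pose_from_landmarks(
    shoulder,
    elbow,
    trunk_down,
    anterior=(0.0, 1.0, 0.0),
) -> tuple[float, float]:
    """Recover (abduction, flexion) in degrees from skeletal landmarks.

    The upper-arm vector runs shoulder -> elbow.  Abduction is its angle to
    the downward trunk direction measured within the coronal plane (the
    plane orthogonal to ``anterior``); flexion is the anterior out-of-plane
    component.  ``trunk_down`` and ``anterior`` need not be normalised but
    must be non-degenerate and non-parallel.
    """
    shoulder = np.asarray(shoulder, dtype=float).reshape(3)
    elbow = np.asarray(elbow, dtype=float).reshape(3)
    arm = elbow - shoulder
    arm_norm = np.linalg.norm(arm)
    if arm_norm <= 0:
        raise DegeneratePoseError("shoulder and elbow coincide")
    arm = arm / arm_norm

    down = np.asarray(trunk_down, dtype=float).reshape(3)
    if np.linalg.norm(down) <= 0:
        raise InvalidParameterError("trunk_down must be a non-zero vector")
    down = down / np.linalg.norm(down)
    ant = np.asarray(anterior, dtype=float).reshape(3)
    # orthonormalise the anterior axis against the trunk axis
    ant = ant - (ant @ down) * down
    if np.linalg.norm(ant) <= 1e-12:
        raise InvalidParameterError("anterior direction is parallel to trunk_down")
    ant = ant / np.linalg.norm(ant)

    flexion = math.degrees(math.asin(float(np.clip(arm @ ant, -1.0, 1.0))))
    coronal = arm - (arm @ ant) * ant
    cnorm = np.linalg.norm(coronal)
    if cnorm <= 1e-12:
        # arm points straight anterior/posterior: abduction undefined, call it 90
        abduction = 90.0
    else:
        coronal = coronal / cnorm
        abduction = math.degrees(
            math.acos(float(np.clip(coronal @ down, -1.0, 1.0)))
        )
    return abduction, flexion
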