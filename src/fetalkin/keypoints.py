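"""Fetal keypoint vocabulary and joint descriptors.

Twelve joints are tracked per frame: wrists, elbows, shoulders, ankles,
knees and hips, on both sides of the body.  Every module in the package
uses the fixed ordering defined here, and every analysis row carries the
three joint descriptors derived from the keypoint name:

* ``distance_class`` -- distance from the core of the body
  (proximal: shoulder/hip, middle: elbow/knee, distal: wrist/ankle)
* ``extremity`` -- upper (wrist/elbow/shoulder) or lower (ankle/knee/hip)
* ``side`` -- left or right
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "KEYPOINTS",
    "JointDescriptor",
    "joint_descriptor",
    "DISTANCE_CLASS",
    "EXTREMITY",
]

#: Canonical keypoint order used for trajectory arrays and heatmap channels.
KEYPOINTS: tuple[str, ...] = (
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
)

DISTANCE_CLASS = {
    "shoulder": "proximal",
    "hip": "proximal",
    "elbow": "middle",
    "knee": "middle",
    "wrist": "distal",
    "ankle": "distal",
}

EXTREMITY = {
    "shoulder": "upper",
    "elbow": "upper",
    "wrist": "upper",
    "hip": "lower",
    "knee": "lower",
    "ankle": "lower",
}


@dataclass(frozen=True)
class JointDescriptor:
    """Descriptors of one keypoint used as model covariates."""

    keypoint: str
    distance_class: str  # proximal | middle | distal
    extremity: str  # upper | lower
    side: str  # left | right


def joint_descriptor(keypoint: str) -> JointDescriptor:
    """Return the :class:`JointDescriptor` for a keypoint name.

    >>> joint_descriptor("left_wrist").distance_class
    'distal'
    """
    if keypoint not in KEYPOINTS:
        raise ValueError(f"unknown keypoint {keypoint!r}")
    side, joint = keypoint.split("_", 1)
    return JointDescriptor(
        keypoint=keypoint,
        distance_class=DISTANCE_CLASS[joint],
        extremity=EXTREMITY[joint],
        side=side,
    )
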