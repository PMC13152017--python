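"""Skeleton conventions for 2D pose keypoints.

The package operates on the 17-keypoint COCO body convention emitted by
standard pose estimators. Image coordinates: origin top-left, y increases
downward, units are pixels until normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field


COCO17_NAMES = (
    "nose",
    "left_eye",
    "right_eye",
    "left_ear",
    "right_ear",
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

JOINT_GROUPS = ("wrist", "ankle", "elbow", "knee")


@dataclass(frozen=True)
class SkeletonConvention:
    """Keypoint naming and the index maps the feature extractor relies on.

    Attributes
    ----------
    keypoint_names : ordered names, exactly 17.
    joint_groups : map group -> (left index, right index) for the four
        extremity/joint groups used by the kinematic features.
    torso_anchors : indices of (left_shoulder, right_shoulder, left_hip,
        right_hip), anchoring translation/rotation/scale normalization.
    head_indices : the 5 facial keypoints (excluded from body-extent QC).
    """

    keypoint_names: tuple = COCO17_NAMES
    joint_groups: dict = field(
        default_factory=lambda: {
            "wrist": (9, 10),
            "ankle": (15, 16),
            "elbow": (7, 8),
            "knee": (13, 14),
        }
    )
    torso_anchors: tuple = (5, 6, 11, 12)
    head_indices: tuple = (0, 1, 2, 3, 4)

    def __post_init__(self) -> None:
        if len(self.keypoint_names) != 17:
            raise ValueError("skeleton must have exactly 17 keypoints")
        if set(self.joint_groups) != set(JOINT_GROUPS):
            raise ValueError(f"joint_groups must cover exactly {JOINT_GROUPS}")
        for group, (left, right) in self.joint_groups.items():
            if not (0 <= left < 17 and 0 <= right < 17):
                raise ValueError(f"{group}: keypoint index out of range")
            if left == right:
                raise ValueError(f"{group}: left/right indices must differ")

    @property
    def n_keypoints(self) -> int:
        return len(self.keypoint_names)

    @property
    def body_indices(self) -> tuple:
        """All non-facial keypoints: shoulders, elbows, wrists, hips, knees, ankles."""
        return tuple(i for i in range(17) if i not in self.head_indices)

    def index_of(self, name: str) -> int:
        return self.keypoint_names.index(name)

    def swap_left_right_indices(self) -> list:
        """Permutation that exchanges each left keypoint with its right twin."""
        perm = list(range(17))
        for name in self.keypoint_names:
            if name.startswith("left_"):
                i = self.index_of(name)
                j = self.index_of("right_" + name[len("left_"):])
                perm[i], perm[j] = j, i
        return perm


COCO17 = SkeletonConvention()
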