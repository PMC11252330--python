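"""Core pose containers: single-frame poses and per-video keypoint tracks."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .skeletons import Skeleton

__all__ = ["InstancePose", "TrackedSequence"]


@dataclass
class InstancePose:
    """One animal instance in one frame.

    ``coords`` is ``(K, 2)`` pixel coordinates (origin top-left, y down);
    ``visibility`` is the ground-truth visibility flag or, for predicted
    poses, the predicted-present flag.
    """

    skeleton: Skeleton
    coords: np.ndarray
    visibility: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.visibility = np.asarray(self.visibility, dtype=bool)
        k = len(self.skeleton)
        if self.coords.shape != (k, 2):
            raise ValidationError(
                f"coords shape {self.coords.shape} != ({k}, 2) for {self.skeleton.name}"
            )
        if self.visibility.shape != (k,):
            raise ValidationError(f"visibility shape {self.visibility.shape} != ({k},)")
        if not np.all(np.isfinite(self.coords[self.visibility])):
            raise ValidationError("non-finite coordinates at visible keypoints")

    @property
    def n_visible(self) -> int:
        return int(self.visibility.sum())


@dataclass
class TrackedSequence:
    """Per-frame keypoint coordinates and visibility for one video.

    Used for both ground-truth and predicted tracks; ``frame_indices``
    keeps the original frame numbers so that filtered sequences remain
    traceable to the source video.
    """

    video_id: str
    view: str
    skeleton: Skeleton
    coords: np.ndarray  # (F, K, 2) float64
    visibility: np.ndarray  # (F, K) bool
    frame_indices: np.ndarray = field(default=None)  # (F,) int64

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.visibility = np.asarray(self.visibility, dtype=bool)
        k = len(self.skeleton)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (k, 2):
            raise ValidationError(
                f"coords shape {self.coords.shape} incompatible with skeleton "
                f"{self.skeleton.name} (K={k})"
            )
        f = self.coords.shape[0]
        if self.visibility.shape != (f, k):
            raise ValidationError(
                f"visibility shape {self.visibility.shape} != ({f}, {k})"
            )
        if self.view != self.skeleton.view:
            raise ValidationError(
                f"sequence view {self.view!r} != skeleton view {self.skeleton.view!r}"
            )
        if self.frame_indices is None:
            self.frame_indices = np.arange(f, dtype=np.int64)
        else:
            self.frame_indices = np.asarray(self.frame_indices, dtype=np.int64)
            if self.frame_indices.shape != (f,):
                raise ValidationError("frame_indices length mismatch")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_keypoints(self) -> int:
        return len(self.skeleton)

    def pose(self, frame_pos: int) -> InstancePose:
        """Pose at positional frame index ``frame_pos`` (not original index)."""
        return InstancePose(
            skeleton=self.skeleton,
            coords=self.coords[frame_pos].copy(),
            visibility=self.visibility[frame_pos].copy(),
        )

    def keypoint_track(self, name: str) -> np.ndarray:
        """(F, 2) coordinate track of one named keypoint."""
        return self.coords[:, self.skeleton.index_of(name)]
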