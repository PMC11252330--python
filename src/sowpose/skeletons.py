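"""Skeleton registry and keypoint-subset algebra.

Five built-in skeletons are shipped as package data: ``lateral_13``,
``lateral_11``, ``lateral_6`` for the side view and ``dorsal_10``,
``dorsal_7`` for the top view.  The reduced skeletons are stored as
``parent`` + ``removed`` and derived at load time, so the subset
relationships are structural, not copied lists.

Canonical keypoint names use ``pastern_*`` (alias ``metacarpal_*``) and
``dorsal_rump`` (alias ``dorsal_tail``); the dorsal-view ``tail`` is a
distinct landmark.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional

from .errors import SkeletonError

__all__ = [
    "Skeleton",
    "KeypointDef",
    "KEYPOINT_ALIASES",
    "canonical_keypoint_name",
    "get_skeleton",
    "list_skeletons",
    "derive_subskeleton",
    "project_pose",
]

#: Accepted input spellings -> canonical names.
KEYPOINT_ALIASES: Mapping[str, str] = {
    "metacarpal_right": "pastern_right",
    "metacarpal_left": "pastern_left",
    "dorsal_tail": "dorsal_rump",
}

VIEWS = ("lateral", "dorsal")


def canonical_keypoint_name(name: str) -> str:
    """Normalize a keypoint name, resolving accepted aliases."""
    key = name.strip().lower().replace(" ", "_")
    return KEYPOINT_ALIASES.get(key, key)


@dataclass(frozen=True)
class KeypointDef:
    """A named landmark at a fixed position within one skeleton."""

    name: str
    view: str
    index: int


@dataclass(frozen=True)
class Skeleton:
    """Ordered, named keypoint set for one camera view.

    ``parent``/``removed`` record derivation provenance; when set, the
    keypoint list equals the parent's list minus ``removed`` with order
    preserved.  Edge (bone) structure is cosmetic only and not used by
    any metric.
    """

    name: str
    view: str
    keypoints: tuple[str, ...]
    parent: Optional[str] = None
    removed: frozenset[str] = field(default_factory=frozenset)
    edges: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.view not in VIEWS:
            raise SkeletonError(f"unknown view {self.view!r}; expected one of {VIEWS}")
        if not self.keypoints:
            raise SkeletonError(f"skeleton {self.name!r} has no keypoints")
        if len(set(self.keypoints)) != len(self.keypoints):
            raise SkeletonError(f"skeleton {self.name!r} has duplicate keypoint names")

    def __len__(self) -> int:
        return len(self.keypoints)

    def __contains__(self, name: str) -> bool:
        return canonical_keypoint_name(name) in self.keypoints

    def index_of(self, name: str) -> int:
        """0-based index of a keypoint (aliases accepted)."""
        canon = canonical_keypoint_name(name)
        try:
            return self.keypoints.index(canon)
        except ValueError:
            raise SkeletonError(f"keypoint {name!r} not in skeleton {self.name!r}") from None

    @property
    def keypoint_defs(self) -> tuple[KeypointDef, ...]:
        return tuple(
            KeypointDef(name=n, view=self.view, index=i) for i, n in enumerate(self.keypoints)
        )

    def to_json(self) -> dict:
        return {
            "name": self.name,
            "view": self.view,
            "keypoints": list(self.keypoints),
            "parent": self.parent,
            "removed": sorted(self.removed),
        }

    @classmethod
    def from_json(cls, doc: Mapping) -> "Skeleton":
        return cls(
            name=doc["name"],
            view=doc["view"],
            keypoints=tuple(doc["keypoints"]),
            parent=doc.get("parent"),
            removed=frozenset(doc.get("removed") or ()),
        )


def derive_subskeleton(parent: Skeleton, removed: Iterable[str], new_name: str) -> Skeleton:
    """Return ``parent`` minus ``removed``, order preserved, provenance kept."""
    removed_canon = frozenset(canonical_keypoint_name(n) for n in removed)
    unknown = removed_canon - set(parent.keypoints)
    if unknown:
        raise SkeletonError(
            f"cannot remove {sorted(unknown)} from {parent.name!r}: not present"
        )
    kept = tuple(k for k in parent.keypoints if k not in removed_canon)
    if not kept:
        raise SkeletonError(f"removing all keypoints of {parent.name!r} leaves nothing")
    return Skeleton(
        name=new_name,
        view=parent.view,
        keypoints=kept,
        parent=parent.name,
        removed=removed_canon,
    )


def _load_builtin_registry() -> dict[str, Skeleton]:
    raw = json.loads(
        resources.files("sowpose").joinpath("data/skeletons.json").read_text("utf-8")
    )
    registry: dict[str, Skeleton] = {}
    # roots first, then children derived from their parents
    for name, doc in raw.items():
        if doc.get("parent") is None:
            registry[name] = Skeleton(
                name=name, view=doc["view"], keypoints=tuple(doc["keypoints"])
            )
    for name, doc in raw.items():
        if doc.get("parent") is not None:
            parent = registry[doc["parent"]]
            registry[name] = derive_subskeleton(parent, doc["removed"], name)
            if registry[name].view != doc["view"]:
                raise SkeletonError(f"view mismatch in built-in skeleton {name!r}")
    return registry


_REGISTRY: dict[str, Skeleton] = _load_builtin_registry()


def get_skeleton(name: str) -> Skeleton:
    """Look up a built-in skeleton by name.

    Raises
    ------
    SkeletonError
        If ``name`` is not registered.
    """
    try:
        return _REGISTRY[name]
    except KeyError:
        raise SkeletonError(
            f"unknown skeleton {name!r}; available: {sorted(_REGISTRY)}"
        ) from None


def list_skeletons() -> tuple[str, ...]:
    return tuple(sorted(_REGISTRY))


def project_pose(pose, target: Skeleton):
    """Restrict a pose to ``target``'s keypoints, reordering as needed.

    Coordinates are copied verbatim; no values are altered.  Every target
    keypoint must exist in the pose's skeleton and the views must agree.
    """
    from .tracks import InstancePose  # local import to avoid a cycle

    source = pose.skeleton
    if source.view != target.view:
        raise SkeletonError(
            f"cannot project a {source.view} pose onto a {target.view} skeleton"
        )
    idx = [source.index_of(n) for n in target.keypoints]
    return InstancePose(
        skeleton=target,
        coords=pose.coords[idx].copy(),
        visibility=pose.visibility[idx].copy(),
    )


def project_sequence(seq, target: Skeleton):
    """Sequence-level counterpart of :func:`project_pose`."""
    from .tracks import TrackedSequence

    source = seq.skeleton
    if source.view != target.view:
        raise SkeletonError(
            f"cannot project a {source.view} sequence onto a {target.view} skeleton"
        )
    idx = [source.index_of(n) for n in target.keypoints]
    return TrackedSequence(
        video_id=seq.video_id,
        view=seq.view,
        skeleton=target,
        coords=seq.coords[:, idx].copy(),
        visibility=seq.visibility[:, idx].copy(),
        frame_indices=seq.frame_indices.copy(),
    )
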