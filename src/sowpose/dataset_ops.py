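"""Dataset bookkeeping: manifests, frame filtering, splitting, and I/O.

The annotation dialect is a long-format CSV with columns ``video_id``,
``view``, ``frame``, ``keypoint``, ``x``, ``y``, ``visible`` — frame
numbers 0-based, pixel origin top-left with y down, UTF-8, '.' decimal
separator.  Round-trips are lossless: coordinates are written with full
float repr.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError
from .skeletons import Skeleton, canonical_keypoint_name, list_skeletons, get_skeleton
from .tracks import TrackedSequence

__all__ = [
    "VideoRecord",
    "SplitSpec",
    "filter_fully_visible_frames",
    "split_dataset",
    "read_annotations",
    "write_annotations",
    "export_trajectories",
    "dataset_summary",
    "read_manifest",
    "write_manifest",
]

logger = logging.getLogger(__name__)

_ANNOTATION_COLUMNS = ("video_id", "view", "frame", "keypoint", "x", "y", "visible")


@dataclass
class VideoRecord:
    """One video in a dataset manifest."""

    video_id: str
    view: str
    n_frames: int
    width: int = 1920
    height: int = 1080
    fps: float = 15.0
    final_score: Optional[int] = None
    band: Optional[str] = None
    paired_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.view not in ("lateral", "dorsal"):
            raise ValidationError(f"unknown view {self.view!r}")
        if self.n_frames < 1:
            raise ValidationError("n_frames must be >= 1")


@dataclass
class SplitSpec:
    """Video-level train+validation / test split specification."""

    train_val_fraction: float = 0.85
    test_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.train_val_fraction <= 0 or self.test_fraction <= 0:
            raise ValidationError("split fractions must be positive")
        if abs(self.train_val_fraction + self.test_fraction - 1.0) > 1e-9:
            raise ValidationError(
                f"fractions must sum to 1, got "
                f"{self.train_val_fraction + self.test_fraction}"
            )


def filter_fully_visible_frames(seq: TrackedSequence) -> TrackedSequence:
    """Keep exactly the frames in which every keypoint is visible.

    Original frame indices are preserved for traceability; the result may
    be empty (logged).
    """
    keep = seq.visibility.all(axis=1)
    if not keep.any():
        logger.info("video %s: no fully visible frames", seq.video_id)
    return TrackedSequence(
        video_id=seq.video_id,
        view=seq.view,
        skeleton=seq.skeleton,
        coords=seq.coords[keep].copy(),
        visibility=seq.visibility[keep].copy(),
        frame_indices=seq.frame_indices[keep].copy(),
    )


def _pair_groups(records: Sequence[VideoRecord]) -> list[tuple[str, ...]]:
    """Group video ids so that paired lateral/dorsal videos stay together."""
    by_id = {rec.video_id: rec for rec in records}
    seen: set[str] = set()
    groups: list[tuple[str, ...]] = []
    for rec in records:
        if rec.video_id in seen:
            continue
        group = [rec.video_id]
        seen.add(rec.video_id)
        partner = rec.paired_id
        if partner and partner in by_id and partner not in seen:
            group.append(partner)
            seen.add(partner)
        groups.append(tuple(group))
    return groups


def split_dataset(
    manifest: Sequence[VideoRecord], spec: SplitSpec
) -> tuple[list[str], list[str]]:
    """Split videos into (train+validation ids, test ids).

    The test count is ``round-half-up(test_fraction * N)`` with a minimum
    of 1; sampling is uniform without replacement and deterministic for a
    fixed seed.  Paired lateral/dorsal videos always land on the same side
    (leakage guard), which may nudge the test count by one.
    """
    ids = [rec.video_id for rec in manifest]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate video ids in manifest")
    n = len(ids)
    if n < 2:
        raise ValidationError("need at least 2 videos to split")
    n_test = max(1, int(math.floor(spec.test_fraction * n + 0.5)))

    rng = np.random.default_rng(spec.seed)
    groups = _pair_groups(manifest)
    order = rng.permutation(len(groups))
    test: list[str] = []
    for gi in order:
        if len(test) >= n_test:
            break
        test.extend(groups[gi])
    test_set = set(test)
    train_val = [vid for vid in ids if vid not in test_set]
    test_sorted = [vid for vid in ids if vid in test_set]
    logger.info(
        "split %d videos -> %d train/val, %d test (seed=%d)",
        n, len(train_val), len(test_sorted), spec.seed,
    )
    return train_val, test_sorted


def _format_coord(value: float) -> str:
    return "" if not np.isfinite(value) else repr(float(value))


def write_annotations(
    seqs: Iterable[TrackedSequence], path: Union[str, Path]
) -> None:
    """Write sequences as long-format annotation CSV (lossless)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_ANNOTATION_COLUMNS)
        for seq in seqs:
            for f in range(seq.n_frames):
                frame = int(seq.frame_indices[f])
                for j, name in enumerate(seq.skeleton.keypoints):
                    x, y = seq.coords[f, j]
                    writer.writerow(
                        [
                            seq.video_id,
                            seq.view,
                            frame,
                            name,
                            _format_coord(x),
                            _format_coord(y),
                            int(seq.visibility[f, j]),
                        ]
                    )


def _infer_skeleton(view: str, keypoints: Sequence[str]) -> Skeleton:
    """Match a keypoint set against the built-ins; else make an ad-hoc skeleton."""
    kp_set = set(keypoints)
    for name in list_skeletons():
        skel = get_skeleton(name)
        if skel.view == view and set(skel.keypoints) == kp_set:
            return skel
    return Skeleton(name=f"adhoc_{view}_{len(keypoints)}", view=view,
                    keypoints=tuple(keypoints))


def read_annotations(
    path: Union[str, Path], skeleton: Optional[Skeleton] = None
) -> list[TrackedSequence]:
    """Read the annotation CSV dialect back into sequences.

    Raises :class:`ParseError` naming the offending row for missing
    columns, non-numeric coordinates, coordinate gaps at visible
    keypoints, or duplicate (video, frame, keypoint) rows.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file (no header)") from None
        if set(header) != set(_ANNOTATION_COLUMNS):
            missing = set(_ANNOTATION_COLUMNS) - set(header)
            extra = set(header) - set(_ANNOTATION_COLUMNS)
            raise ParseError(
                f"{path}: bad header; missing columns {sorted(missing)}, "
                f"unknown columns {sorted(extra)}"
            )
        col = {name: header.index(name) for name in _ANNOTATION_COLUMNS}

        data: dict[str, dict] = {}
        seen: set[tuple[str, int, str]] = set()
        for rowno, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) != len(header):
                raise ParseError(f"{path} row {rowno}: expected {len(header)} fields")
            vid = row[col["video_id"]]
            view = row[col["view"]]
            kp = canonical_keypoint_name(row[col["keypoint"]])
            try:
                frame = int(row[col["frame"]])
            except ValueError:
                raise ParseError(f"{path} row {rowno}: non-integer frame") from None
            visible_raw = row[col["visible"]].strip()
            if visible_raw not in ("0", "1"):
                raise ParseError(f"{path} row {rowno}: visible must be 0 or 1")
            visible = visible_raw == "1"
            coords = []
            for axis in ("x", "y"):
                cell = row[col[axis]].strip()
                if cell == "":
                    if visible:
                        raise ParseError(
                            f"{path} row {rowno}: empty {axis} at a visible keypoint"
                        )
                    coords.append(float("nan"))
                else:
                    try:
                        coords.append(float(cell))
                    except ValueError:
                        raise ParseError(
                            f"{path} row {rowno}: non-numeric {axis} value {cell!r}"
                        ) from None
            key = (vid, frame, kp)
            if key in seen:
                raise ParseError(
                    f"{path} row {rowno}: duplicate (video, frame, keypoint) {key}"
                )
            seen.add(key)
            entry = data.setdefault(vid, {"view": view, "keypoints": [], "rows": {}})
            if entry["view"] != view:
                raise ParseError(f"{path} row {rowno}: video {vid!r} changes view")
            if kp not in entry["keypoints"]:
                entry["keypoints"].append(kp)
            entry["rows"][(frame, kp)] = (coords[0], coords[1], visible)

    out: list[TrackedSequence] = []
    for vid, entry in data.items():
        if skeleton is not None:
            skel = skeleton
        else:
            skel = _infer_skeleton(entry["view"], entry["keypoints"])
        frames = sorted({f for f, _ in entry["rows"]})
        coords = np.full((len(frames), len(skel), 2), np.nan)
        vis = np.zeros((len(frames), len(skel)), dtype=bool)
        for fi, frame in enumerate(frames):
            for j, name in enumerate(skel.keypoints):
                rec = entry["rows"].get((frame, name))
                if rec is None:
                    continue
                coords[fi, j] = rec[:2]
                vis[fi, j] = rec[2]
        out.append(
            TrackedSequence(
                video_id=vid,
                view=entry["view"],
                skeleton=skel,
                coords=coords,
                visibility=vis,
                frame_indices=np.asarray(frames, dtype=np.int64),
            )
        )
    return out


def export_trajectories(seq: TrackedSequence, path: Union[str, Path]) -> None:
    """Write a wide coordinate-only CSV: one row per frame, (x, y) per keypoint.

    The animal-free trajectory artifact; invisible keypoints leave empty
    cells.
    """
    if seq.n_frames == 0:
        raise ValidationError("cannot export an empty sequence")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        header = ["frame"]
        for name in seq.skeleton.keypoints:
            header.extend([f"{name}_x", f"{name}_y"])
        writer.writerow(header)
        for f in range(seq.n_frames):
            row = [int(seq.frame_indices[f])]
            for j in range(len(seq.skeleton)):
                if seq.visibility[f, j]:
                    row.extend(
                        [repr(float(seq.coords[f, j, 0])), repr(float(seq.coords[f, j, 1]))]
                    )
                else:
                    row.extend(["", ""])
            writer.writerow(row)


def dataset_summary(
    manifest: Sequence[VideoRecord],
    annotations: Sequence[TrackedSequence] = (),
) -> pd.DataFrame:
    """Per-view accounting: video counts, frames, labelled frames, per-score counts."""
    ids = {rec.video_id for rec in manifest}
    if len(ids) != len(manifest):
        raise ValidationError("duplicate video ids in manifest")
    for seq in annotations:
        if seq.video_id not in ids:
            raise ValidationError(
                f"annotation references unknown video {seq.video_id!r}"
            )
    labelled: dict[str, int] = {}
    for seq in annotations:
        labelled[seq.video_id] = labelled.get(seq.video_id, 0) + seq.n_frames

    rows = []
    for view in ("lateral", "dorsal"):
        recs = [r for r in manifest if r.view == view]
        if not recs:
            continue
        row = {
            "view": view,
            "n_videos": len(recs),
            "total_frames": sum(r.n_frames for r in recs),
            "labelled_frames": sum(labelled.get(r.video_id, 0) for r in recs),
        }
        for score in range(4):
            row[f"score_{score}"] = sum(1 for r in recs if r.final_score == score)
        rows.append(row)
    summary = pd.DataFrame(rows).set_index("view")
    logger.info("dataset summary:\n%s", summary.to_string())
    return summary


def write_manifest(records: Sequence[VideoRecord], path: Union[str, Path]) -> None:
    Path(path).write_text(
        json.dumps([asdict(rec) for rec in records], indent=2), "utf-8"
    )


def read_manifest(path: Union[str, Path]) -> list[VideoRecord]:
    try:
        docs = json.loads(Path(path).read_text("utf-8"))
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON manifest: {exc}") from exc
    if not isinstance(docs, list):
        raise ParseError(f"{path}: manifest must be a JSON list")
    return [VideoRecord(**doc) for doc in docs]
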