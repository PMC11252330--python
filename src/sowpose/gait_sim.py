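"""Synthetic sow gait generator.

Produces ground-truth keypoint tracks with locomotion-score-dependent
signatures (stride asymmetry, head dipping, back arching, lateral sway),
perturbs them into "predicted" tracks, and simulates expert voting panels.

The walk model is purely kinematic — a four-phase stride cycle composed of
sinusoids — because the scoring scale is behavioural, not biomechanical.
Its contract is controllability: for asymmetry ``a`` on one limb, the
stride-asymmetry index of a noise-free output equals ``a / (2 - a)``
exactly, and all score signatures grow monotonically with the score under
the shipped presets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .config import load_gait_presets
from .errors import ValidationError
from .skeletons import Skeleton, get_skeleton
from .tracks import TrackedSequence

__all__ = [
    "GaitParams",
    "PredictionErrorModel",
    "ExpertModel",
    "preset_params",
    "simulate_sequence",
    "stride_asymmetry_index",
    "apply_prediction_error",
    "simulate_votes",
    "LIMBS",
    "LIMB_PHASES",
]

logger = logging.getLogger(__name__)

LIMBS = ("front_right", "front_left", "hind_right", "hind_left")

#: Stride-cycle phase offset of each limb (fractions of a cycle).
LIMB_PHASES: Mapping[str, float] = {
    "front_right": 0.0,
    "front_left": 0.5,
    "hind_right": 0.25,
    "hind_left": 0.75,
}

# Keypoint -> limb it rides on; hocks/pasterns swing at half amplitude.
_LIMB_OF = {
    "hoof_front_right": ("front_right", 1.0),
    "hoof_front_left": ("front_left", 1.0),
    "hoof_posterior_right": ("hind_right", 1.0),
    "hoof_posterior_left": ("hind_left", 1.0),
    "pastern_right": ("front_right", 0.5),
    "pastern_left": ("front_left", 0.5),
    "hock_right": ("hind_right", 0.5),
    "hock_left": ("hind_left", 0.5),
}

# Template body offsets (px from the moving body anchor), side view.
_LATERAL_OFFSETS = {
    "snout": (260.0, -40.0),
    "neck": (170.0, -60.0),
    "dorsal_neck": (120.0, -120.0),
    "dorsal_rump": (-160.0, -120.0),
    "rump": (-220.0, -50.0),
    "pastern_right": (145.0, 150.0),
    "pastern_left": (135.0, 150.0),
    "hock_right": (-150.0, 120.0),
    "hock_left": (-160.0, 120.0),
    "hoof_front_right": (150.0, 200.0),
    "hoof_front_left": (140.0, 200.0),
    "hoof_posterior_right": (-155.0, 200.0),
    "hoof_posterior_left": (-165.0, 200.0),
}

# Top view: x along the walking direction, y across the body.
_DORSAL_OFFSETS = {
    "head": (300.0, 0.0),
    "neck": (220.0, 0.0),
    "scapula_right": (150.0, 55.0),
    "scapula_left": (150.0, -55.0),
    "thoracic": (80.0, 0.0),
    "middle": (0.0, 0.0),
    "lumbar": (-80.0, 0.0),
    "pelvic_right": (-150.0, 50.0),
    "pelvic_left": (-150.0, -50.0),
    "tail": (-240.0, 0.0),
}

_MID_SPINE = ("dorsal_neck", "dorsal_rump")
_LEFT_HOOVES = ("hoof_front_left", "hoof_posterior_left")
#: Left-side hooves occlude more often in the lateral view (the camera
#: films the right flank), so their occlusion probability is doubled.
LEFT_HOOF_OCCLUSION_FACTOR = 2.0

_ANCHOR_START = (300.0, 560.0)  # lateral
_DORSAL_ANCHOR_START = (320.0, 540.0)


@dataclass
class GaitParams:
    """Kinematic parameters of one simulated walking sow."""

    score: int
    speed: float = 4.0
    stride_freq: float = 0.05
    stride_amp: float = 40.0
    lift_amp: float = 12.0
    affected_limb: str = "none"
    asymmetry: float = 0.0
    head_amp: float = 0.0
    arch_amp: float = 0.0
    sway_amp: float = 8.0
    noise_sd: float = 1.5
    occlusion_prob: float = 0.0
    frame_size: tuple[int, int] = (1920, 1080)
    view: Optional[str] = None

    def __post_init__(self) -> None:
        if self.score not in (0, 1, 2, 3):
            raise ValidationError(f"score must be 0..3, got {self.score}")
        for name in ("speed", "stride_amp", "lift_amp", "head_amp", "arch_amp",
                     "sway_amp", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0.0 <= self.asymmetry < 1.0:
            raise ValidationError("asymmetry must be in [0, 1)")
        if not 0.0 <= self.occlusion_prob <= 1.0:
            raise ValidationError("occlusion_prob must be in [0, 1]")
        if self.stride_freq <= 0 or self.stride_freq >= 0.5:
            raise ValidationError("stride_freq must be in (0, 0.5) cycles/frame")
        if self.affected_limb not in LIMBS + ("none",):
            raise ValidationError(f"unknown affected_limb {self.affected_limb!r}")
        if self.score == 0:
            if self.affected_limb != "none":
                raise ValidationError("score 0 requires affected_limb = none")
            if self.asymmetry != 0 or self.head_amp != 0 or self.arch_amp != 0:
                raise ValidationError(
                    "score 0 requires asymmetry = head_amp = arch_amp = 0"
                )
        elif self.affected_limb == "none":
            raise ValidationError("scores 1-3 require an affected limb")


@dataclass
class PredictionErrorModel:
    """Stand-in for pose-model prediction error.

    ``sd`` may be a scalar or a per-keypoint array; displacement is
    isotropic Gaussian, inflated to ``outlier_scale * sd`` with probability
    ``outlier_prob``, and keypoints are dropped with probability
    ``miss_prob``.
    """

    sd: Union[float, Sequence[float]] = 3.0
    outlier_prob: float = 0.0
    outlier_scale: float = 5.0
    miss_prob: float = 0.0

    def __post_init__(self) -> None:
        sd = np.atleast_1d(np.asarray(self.sd, dtype=np.float64))
        if np.any(sd < 0):
            raise ValidationError("sd must be >= 0")
        for name in ("outlier_prob", "miss_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.outlier_scale < 0:
            raise ValidationError("outlier_scale must be >= 0")

    def sd_vector(self, n_keypoints: int) -> np.ndarray:
        sd = np.atleast_1d(np.asarray(self.sd, dtype=np.float64))
        if sd.size == 1:
            return np.full(n_keypoints, float(sd[0]))
        if sd.size != n_keypoints:
            raise ValidationError(
                f"per-keypoint sd has length {sd.size}, expected {n_keypoints}"
            )
        return sd


@dataclass
class ExpertModel:
    """Confusion-matrix model of an imperfect locomotion-scoring expert.

    ``confusion[t, a]`` is the probability an expert answers score ``a``
    when the true score is ``t``.  Rows must be stochastic.
    """

    confusion: np.ndarray

    def __post_init__(self) -> None:
        self.confusion = np.asarray(self.confusion, dtype=np.float64)
        if self.confusion.shape != (4, 4):
            raise ValidationError("confusion must be 4x4")
        if np.any(self.confusion < 0):
            raise ValidationError("confusion entries must be >= 0")
        if not np.allclose(self.confusion.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("confusion rows must each sum to 1 (within 1e-9)")

    @classmethod
    def diagonal(cls, p_correct: float = 0.9) -> "ExpertModel":
        """Diagonally dominant model spreading 1-p over adjacent scores."""
        if not 0.0 < p_correct <= 1.0:
            raise ValidationError("p_correct must be in (0, 1]")
        rest = 1.0 - p_correct
        mat = np.zeros((4, 4))
        for t in range(4):
            mat[t, t] = p_correct
            neighbours = [a for a in (t - 1, t + 1) if 0 <= a <= 3]
            for a in neighbours:
                mat[t, a] += rest / len(neighbours)
        return cls(mat)


def preset_params(score: int, view: str = "lateral") -> GaitParams:
    """Default :class:`GaitParams` for a locomotion score (shipped presets)."""
    presets = load_gait_presets()
    if score not in presets:
        raise ValidationError(f"no preset for score {score}")
    flat = presets[score]
    frame_size = (int(flat.pop("frame_width")), int(flat.pop("frame_height")))
    affected = flat.pop("affected_limb")
    return GaitParams(
        view=view,
        frame_size=frame_size,
        affected_limb="none" if affected in (None, "none") else str(affected),
        **flat,
    )


def _reference_front_limb(affected: str) -> str:
    # head motion is phase-locked to the affected forelimb's cycle; for a
    # hind or absent lameness we lock to front_right so the phase is defined
    if affected in ("front_right", "front_left"):
        return affected
    return "front_right"


def simulate_sequence(
    params: GaitParams, skeleton: Skeleton, n_frames: int, seed: int
) -> TrackedSequence:
    """Generate a ground-truth track of a walking sow.

    Deterministic for fixed ``(params, seed)``.  Limbs follow a four-phase
    stride cycle (phases 0, 0.5, 0.25, 0.75); the affected limb's swing is
    scaled by ``1 - asymmetry``; the snout dips with ``head_amp``; mid-spine
    keypoints are raised by ``arch_amp``; dorsal keypoints sway laterally.
    """
    if n_frames < 1:
        raise ValidationError(f"n_frames must be >= 1, got {n_frames}")
    if params.view is not None and params.view != skeleton.view:
        raise ValidationError(
            f"params view {params.view!r} incompatible with skeleton view "
            f"{skeleton.view!r}"
        )
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames, dtype=np.float64)
    k = len(skeleton)
    coords = np.empty((n_frames, k, 2), dtype=np.float64)

    offsets = _LATERAL_OFFSETS if skeleton.view == "lateral" else _DORSAL_OFFSETS
    anchor0 = _ANCHOR_START if skeleton.view == "lateral" else _DORSAL_ANCHOR_START
    anchor_x = anchor0[0] + params.speed * t
    ref_limb = _reference_front_limb(params.affected_limb)

    # lateral sway shared by all dorsal keypoints, lobes scaled asymmetrically
    if skeleton.view == "dorsal":
        sway_phase = np.sin(2 * np.pi * (params.stride_freq * t))
        sway = params.sway_amp * sway_phase
        if params.affected_limb.endswith("left"):
            sway = np.where(sway_phase < 0, sway * (1 - params.asymmetry), sway)
        elif params.affected_limb.endswith("right"):
            sway = np.where(sway_phase > 0, sway * (1 - params.asymmetry), sway)
    else:
        sway = None

    for j, name in enumerate(skeleton.keypoints):
        try:
            off_x, off_y = offsets[name]
        except KeyError:
            raise ValidationError(
                f"no template position for keypoint {name!r} in {skeleton.view} view"
            ) from None
        x = anchor_x + off_x
        y = np.full(n_frames, anchor0[1] + off_y)

        limb_info = _LIMB_OF.get(name) if skeleton.view == "lateral" else None
        if limb_info is not None:
            limb, amp_factor = limb_info
            amp = params.stride_amp * amp_factor
            lift = params.lift_amp * amp_factor
            if limb == params.affected_limb:
                amp *= 1.0 - params.asymmetry
                lift *= 1.0 - params.asymmetry
            theta = 2 * np.pi * (params.stride_freq * t + LIMB_PHASES[limb])
            swing = np.sin(theta)
            x = x + amp * swing
            y = y - lift * np.clip(swing, 0.0, None)  # lift during swing phase

        if skeleton.view == "lateral":
            if name == "snout" and params.head_amp > 0:
                theta = 2 * np.pi * (params.stride_freq * t + LIMB_PHASES[ref_limb])
                y = y + params.head_amp * np.sin(theta)
            if name in _MID_SPINE and params.arch_amp > 0:
                y = y - params.arch_amp  # y-down: arching raises the spine
        else:
            y = y + sway

        coords[:, j, 0] = x
        coords[:, j, 1] = y

    if params.noise_sd > 0:
        coords += rng.normal(0.0, params.noise_sd, size=coords.shape)

    width, height = params.frame_size
    np.clip(coords[..., 0], 0.0, width - 1.0, out=coords[..., 0])
    np.clip(coords[..., 1], 0.0, height - 1.0, out=coords[..., 1])

    occ = np.full(k, params.occlusion_prob)
    if skeleton.view == "lateral":
        for name in _LEFT_HOOVES:
            if name in skeleton:
                occ[skeleton.index_of(name)] = min(
                    1.0, params.occlusion_prob * LEFT_HOOF_OCCLUSION_FACTOR
                )
    visibility = rng.random((n_frames, k)) >= occ[None, :]

    return TrackedSequence(
        video_id=f"sim_{skeleton.view}_s{params.score}_seed{seed}",
        view=skeleton.view,
        skeleton=skeleton,
        coords=coords,
        visibility=visibility,
    )


_HOOF_PAIRS = (
    ("hoof_front_right", "hoof_front_left"),
    ("hoof_posterior_right", "hoof_posterior_left"),
)


def _detrended_hoof_x(seq: TrackedSequence, name: str, anchor_x: np.ndarray) -> np.ndarray:
    x = seq.coords[:, seq.skeleton.index_of(name), 0] - anchor_x
    return x - x.mean()


def _count_cycles(signal: np.ndarray) -> float:
    # smoothed zero-crossing count; one cycle ~ two sign changes
    if signal.size < 5:
        return 0.0
    kernel = np.ones(5) / 5.0
    smooth = np.convolve(signal, kernel, mode="valid")
    signs = np.sign(smooth)
    signs = signs[signs != 0]
    if signs.size < 2:
        return 0.0
    return float(np.count_nonzero(np.diff(signs) != 0)) / 2.0


def stride_asymmetry_index(seq: TrackedSequence) -> float:
    """Left/right stride-asymmetry index in [0, 1].

    For each left/right hoof pair the per-limb horizontal excursion ``L``
    (range of the hoof's x track after removing body translation) gives
    ``|L_R - L_L| / (L_R + L_L)``; the sequence index is the maximum over
    pairs, i.e. the asymmetry of the lameness-dominant pair.  For a
    generator output with asymmetry ``a`` on one limb and zero noise this
    equals ``a / (2 - a)``.
    """
    skel = seq.skeleton
    missing = [n for pair in _HOOF_PAIRS for n in pair if n not in skel]
    if missing:
        raise ValidationError(
            f"sequence lacks hoof keypoints {missing}; cannot compute asymmetry"
        )
    if "rump" in skel:
        anchor_x = seq.coords[:, skel.index_of("rump"), 0]
    else:
        hoofs = {n for pair in _HOOF_PAIRS for n in pair}
        body_idx = [i for i, n in enumerate(skel.keypoints) if n not in hoofs]
        anchor_x = seq.coords[:, body_idx, 0].mean(axis=1)

    probe = _detrended_hoof_x(seq, _HOOF_PAIRS[0][0], anchor_x)
    if _count_cycles(probe) < 2.0:
        raise ValidationError("need at least 2 stride cycles to estimate asymmetry")

    best = 0.0
    for right, left in _HOOF_PAIRS:
        l_r = float(np.ptp(_detrended_hoof_x(seq, right, anchor_x)))
        l_l = float(np.ptp(_detrended_hoof_x(seq, left, anchor_x)))
        total = l_r + l_l
        sa = abs(l_r - l_l) / total if total > 0 else 0.0
        best = max(best, sa)
    return best


def apply_prediction_error(
    seq: TrackedSequence, model: PredictionErrorModel, seed: int
) -> TrackedSequence:
    """Perturb a ground-truth track into a simulated predicted track.

    Visible keypoints are displaced isotropically; dropped keypoints are
    marked not-predicted; keypoints invisible in the ground truth stay
    invisible.  Deterministic for fixed seed; with ``sd = 0`` and no
    outliers or misses the coordinates are returned bit-identical.
    """
    rng = np.random.default_rng(seed)
    f, k = seq.visibility.shape
    sd = model.sd_vector(k)

    coords = seq.coords.copy()
    normals = rng.normal(size=(f, k, 2))
    outlier = rng.random((f, k)) < model.outlier_prob
    miss = rng.random((f, k)) < model.miss_prob

    scale = np.where(outlier, sd[None, :] * model.outlier_scale, sd[None, :])
    displacement = normals * scale[..., None]
    apply = seq.visibility & (scale > 0)
    coords[apply] += displacement[apply]

    visibility = seq.visibility & ~miss
    return TrackedSequence(
        video_id=seq.video_id,
        view=seq.view,
        skeleton=seq.skeleton,
        coords=coords,
        visibility=visibility,
        frame_indices=seq.frame_indices.copy(),
    )


def simulate_votes(
    true_scores: Sequence[int],
    model: ExpertModel,
    n_experts: int,
    seed: int,
    video_ids: Optional[Sequence[str]] = None,
):
    """Simulate an expert panel scoring videos 0-3 with imperfect agreement.

    One vote per (expert, video), drawn independently from the confusion
    row of the video's true score.  Returns a
    :class:`~sowpose.consensus.VoteTable`.
    """
    from .consensus import VoteTable

    if n_experts < 1:
        raise ValidationError("n_experts must be >= 1")
    scores = [int(s) for s in true_scores]
    if any(s not in (0, 1, 2, 3) for s in scores):
        raise ValidationError("true scores must be in 0..3")
    if video_ids is None:
        video_ids = [f"v{i:04d}" for i in range(len(scores))]
    elif len(video_ids) != len(scores):
        raise ValidationError("video_ids length must match true_scores")

    rng = np.random.default_rng(seed)
    records = []
    for vid, truth in zip(video_ids, scores):
        votes = rng.choice(4, size=n_experts, p=model.confusion[truth])
        records.extend(
            (vid, f"e{e:02d}", int(v)) for e, v in enumerate(votes)
        )
    logger.info(
        "simulated %d votes (%d videos x %d experts, seed=%d)",
        len(records), len(scores), n_experts, seed,
    )
    return VoteTable.from_records(records)
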