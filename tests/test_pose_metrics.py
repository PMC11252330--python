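import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sowpose import (
    MetricConfig,
    ValidationError,
    average_precision,
    compute_oks,
    distance_average,
    evaluate,
    get_skeleton,
    instance_scale,
    make_pair,
    mean_average_precision,
    pck,
    per_keypoint_pixel_errors,
    rank_keypoints_by_error,
)
from sowpose.pose_metrics import DEFAULT_THRESHOLDS, greedy_match
from sowpose.tracks import InstancePose, TrackedSequence

from conftest import make_pose


def _pair_with_distances(skeleton, distances, cfg, gt_visible=None, pred_present=None):
    """Build an EvalPair whose per-keypoint distances equal `distances`."""
    k = len(skeleton)
    gt_coords = np.zeros((k, 2))
    gt_coords[:, 0] = np.arange(k) * 1000.0  # spread to control the bbox if needed
    pred_coords = gt_coords.copy()
    pred_coords[:, 1] += np.asarray(distances, dtype=float)
    gt = make_pose(skeleton, gt_coords,
                   np.ones(k, bool) if gt_visible is None else np.asarray(gt_visible))
    pred = make_pose(skeleton, pred_coords,
                     np.ones(k, bool) if pred_present is None else np.asarray(pred_present))
    return make_pair(gt, pred, cfg)


class TestInstanceScale:
    def test_bbox_sqrt_area(self, lateral_6):
        coords = np.zeros((6, 2))
        coords[1] = [30.0, 40.0]
        pose = make_pose(lateral_6, coords)
        assert instance_scale(pose, MetricConfig()) == pytest.approx(math.sqrt(1200))

    def test_fixed_mode(self, lateral_6):
        pose = make_pose(lateral_6, np.random.default_rng(0).normal(size=(6, 2)))
        cfg = MetricConfig(scale_mode="fixed", fixed_scale=10.0)
        assert instance_scale(pose, cfg) == 10.0

    def test_collinear_points_error(self, lateral_6):
        coords = np.zeros((6, 2))
        coords[:, 0] = np.arange(6.0)  # zero height
        with pytest.raises(ValidationError):
            instance_scale(make_pose(lateral_6, coords), MetricConfig())

    def test_area_floor(self, lateral_6):
        coords = np.zeros((6, 2))
        coords[:, 0] = np.arange(6.0)
        cfg = MetricConfig(bbox_area_floor=100.0)
        assert instance_scale(make_pose(lateral_6, coords), cfg) == 10.0

    def test_single_visible_point_error(self, lateral_6):
        vis = np.zeros(6, bool)
        vis[0] = True
        pose = make_pose(lateral_6, np.zeros((6, 2)), vis)
        with pytest.raises(ValidationError):
            instance_scale(pose, MetricConfig())


class TestOKS:
    def test_perfect_prediction(self, lateral_6, fixed_cfg):
        pair = _pair_with_distances(lateral_6, np.zeros(6), fixed_cfg)
        assert compute_oks(pair, fixed_cfg) == 1.0

    def test_single_keypoint_closed_form(self, lateral_6, fixed_cfg):
        # d = s*k*sqrt(2) gives exp(-1)
        s, k = 10.0, 0.5
        vis = np.zeros(6, bool)
        vis[0] = True
        d = np.zeros(6)
        d[0] = s * k * math.sqrt(2)
        pair = _pair_with_distances(lateral_6, d, fixed_cfg, gt_visible=vis)
        assert compute_oks(pair, fixed_cfg) == pytest.approx(math.exp(-1), abs=1e-12)

    def test_missing_prediction_penalized(self, lateral_6, fixed_cfg):
        pred_present = np.ones(6, bool)
        pred_present[2] = False
        pair = _pair_with_distances(lateral_6, np.zeros(6), fixed_cfg,
                                    pred_present=pred_present)
        # 5 exact hits over 6 visible keypoints
        assert compute_oks(pair, fixed_cfg) == pytest.approx(5 / 6, abs=1e-12)

    def test_no_visible_keypoints_error(self, lateral_6, fixed_cfg):
        pair = _pair_with_distances(lateral_6, np.zeros(6), fixed_cfg,
                                    gt_visible=np.zeros(6, bool))
        with pytest.raises(ValidationError):
            compute_oks(pair, fixed_cfg)

    def test_gaussian_error_expectation(self, lateral_13, rng):
        # E[OKS] for isotropic Gaussian error: s^2 k^2 / (s^2 k^2 + sigma^2)
        sigma, s, k = 3.0, 10.0, 0.5
        cfg = MetricConfig(scale_mode="fixed", fixed_scale=s, k=k)
        n_pairs = 10_000 // 13 + 1
        values = []
        for _ in range(n_pairs):
            d = np.linalg.norm(rng.normal(0, sigma, size=(13, 2)), axis=1)
            pair = _pair_with_distances(lateral_13, d, cfg)
            values.append(compute_oks(pair, cfg))
        expected = (s * k) ** 2 / ((s * k) ** 2 + sigma**2)
        assert np.mean(values) == pytest.approx(expected, abs=0.01)


class TestAveragePrecision:
    @pytest.mark.parametrize(
        "values,t,expected",
        [
            ([1.0, 1.0, 1.0], 0.5, 1.0),
            ([0.96, 0.60, 0.40], 0.5, 2 / 3),
            ([0.4, 0.3], 0.5, 0.0),
            ([0.5], 0.5, 1.0),  # >= is inclusive at the threshold
        ],
    )
    def test_examples(self, values, t, expected):
        assert average_precision(values, t) == pytest.approx(expected, abs=1e-12)

    def test_empty_errors(self):
        with pytest.raises(ValidationError):
            average_precision([], 0.5)

    def test_brute_force_equivalence(self, rng):
        values = rng.uniform(0, 1, size=200).tolist()
        for t in DEFAULT_THRESHOLDS:
            expected = sum(1 for v in values if v >= t) / len(values)
            assert average_precision(values, t) == pytest.approx(expected, abs=1e-15)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_threshold(self, values):
        aps = [average_precision(values, t) for t in DEFAULT_THRESHOLDS]
        assert all(a >= b for a, b in zip(aps, aps[1:]))
        assert all(0.0 <= a <= 1.0 for a in aps)


class TestMeanAveragePrecision:
    def test_single_072_gives_half(self):
        map_, mar = mean_average_precision([0.72], MetricConfig())
        assert map_ == pytest.approx(0.5, abs=1e-12)
        assert mar == pytest.approx(0.5, abs=1e-12)

    def test_all_perfect(self):
        map_, mar = mean_average_precision([1.0] * 7, MetricConfig())
        assert map_ == 1.0 and mar == 1.0

    def test_unpredicted_instances_hit_recall_only(self):
        map_, mar = mean_average_precision([1.0] * 8, MetricConfig(), n_gt_instances=10)
        assert map_ == 1.0
        assert mar == pytest.approx(0.8, abs=1e-12)

    def test_brute_force_double_loop(self, rng):
        values = rng.uniform(0, 1, size=200)
        cfg = MetricConfig()
        map_, mar = mean_average_precision(values, cfg)
        hits = 0
        for t in cfg.oks_thresholds:
            for v in values:
                hits += v >= t
        expected = hits / (len(values) * len(cfg.oks_thresholds))
        assert map_ == pytest.approx(expected, abs=1e-12)
        assert mar == pytest.approx(expected, abs=1e-12)

    def test_map_bounded_by_max_ap(self, rng):
        values = rng.uniform(0, 1, size=50)
        cfg = MetricConfig()
        map_, _ = mean_average_precision(values, cfg)
        assert map_ <= max(average_precision(values, t) for t in cfg.oks_thresholds)

    def test_empty_threshold_set_errors(self):
        cfg = MetricConfig()
        cfg.oks_thresholds = ()
        with pytest.raises(ValidationError):
            mean_average_precision([0.9], cfg)


class TestDistanceAverage:
    def test_identity_zero(self, lateral_6, fixed_cfg):
        pair = _pair_with_distances(lateral_6, np.zeros(6), fixed_cfg)
        assert distance_average([pair]) == 0.0

    def test_two_distances(self, lateral_6, fixed_cfg):
        vis = np.zeros(6, bool)
        vis[:2] = True
        d = np.array([3.0, 5.0, 0, 0, 0, 0])
        pair = _pair_with_distances(lateral_6, d, fixed_cfg, gt_visible=vis)
        assert distance_average([pair]) == pytest.approx(4.0, abs=1e-12)

    def test_rayleigh_mean(self, lateral_13, fixed_cfg, rng):
        sigma = 4.0
        pairs = []
        for _ in range(10_000 // 13 + 1):
            d = np.linalg.norm(rng.normal(0, sigma, size=(13, 2)), axis=1)
            pairs.append(_pair_with_distances(lateral_13, d, fixed_cfg))
        assert distance_average(pairs) == pytest.approx(sigma * math.sqrt(math.pi / 2), abs=0.1)

    def test_sigma_recovery_within_5pct(self, lateral_13, fixed_cfg, rng):
        sigma = 6.0
        pairs = []
        for _ in range(10_000 // 13 + 1):
            d = np.linalg.norm(rng.normal(0, sigma, size=(13, 2)), axis=1)
            pairs.append(_pair_with_distances(lateral_13, d, fixed_cfg))
        sigma_hat = distance_average(pairs) / math.sqrt(math.pi / 2)
        assert abs(sigma_hat - sigma) / sigma < 0.05

    def test_no_evaluable_error(self, lateral_6, fixed_cfg):
        pair = _pair_with_distances(lateral_6, np.zeros(6), fixed_cfg,
                                    pred_present=np.zeros(6, bool))
        with pytest.raises(ValidationError):
            distance_average([pair])


class TestPCK:
    def test_perfect_prediction(self, lateral_6, fixed_cfg):
        pair = _pair_with_distances(lateral_6, np.zeros(6), fixed_cfg)
        by_kp, mean = pck([pair], fixed_cfg)
        assert mean == 1.0
        assert all(v == 1.0 for v in by_kp.values())

    def test_boundary_is_strictly_incorrect(self, lateral_6):
        cfg = MetricConfig(scale_mode="fixed", fixed_scale=100.0, pck_alpha=0.05)
        d = np.full(6, 5.0)  # d / s == alpha exactly
        pair = _pair_with_distances(lateral_6, d, cfg)
        _, mean = pck([pair], cfg)
        assert mean == 0.0

    def test_missing_predictions_count_incorrect(self, lateral_6, fixed_cfg):
        pred_present = np.ones(6, bool)
        pred_present[0] = False
        pairs = [
            _pair_with_distances(lateral_6, np.zeros(6), fixed_cfg,
                                 pred_present=pred_present),
            _pair_with_distances(lateral_6, np.zeros(6), fixed_cfg),
        ]
        by_kp, _ = pck(pairs, fixed_cfg)
        assert by_kp[lateral_6.keypoints[0]] == pytest.approx(0.5)

    def test_rayleigh_cdf(self, lateral_13, rng):
        sigma, s, alpha = 3.0, 100.0, 0.05
        cfg = MetricConfig(scale_mode="fixed", fixed_scale=s, pck_alpha=alpha)
        pairs = []
        for _ in range(10_000 // 13 + 1):
            d = np.linalg.norm(rng.normal(0, sigma, size=(13, 2)), axis=1)
            pairs.append(_pair_with_distances(lateral_13, d, cfg))
        _, mean = pck(pairs, cfg)
        expected = 1 - math.exp(-((alpha * s) ** 2) / (2 * sigma**2))
        assert mean == pytest.approx(expected, abs=0.01)

    def test_alpha_validation(self):
        with pytest.raises(ValidationError):
            MetricConfig(pck_alpha=0.0)


class TestPixelErrors:
    def test_identity_all_zero(self, lateral_6, fixed_cfg):
        pairs = [_pair_with_distances(lateral_6, np.zeros(6), fixed_cfg)] * 3
        summary = per_keypoint_pixel_errors(pairs)
        for s in summary.values():
            assert s.n == 3 and s.mean == 0.0 and s.n_missing == 0

    def test_per_keypoint_sigma_vector(self, rng):
        from sowpose.skeletons import Skeleton

        skel = Skeleton(name="tri", view="lateral", keypoints=("a", "b", "c"))
        cfg = MetricConfig(scale_mode="fixed", fixed_scale=10.0)
        sigmas = np.array([2.0, 2.0, 6.0])
        pairs = []
        for _ in range(10_000):
            d = np.linalg.norm(rng.normal(0, sigmas[:, None], size=(3, 2)), axis=1)
            pairs.append(_pair_with_distances(skel, d, cfg))
        summary = per_keypoint_pixel_errors(pairs)
        for name, sg in zip("abc", sigmas):
            assert summary[name].mean == pytest.approx(sg * math.sqrt(math.pi / 2), abs=0.15)

    def test_never_predicted_keypoint(self, lateral_6, fixed_cfg):
        pred_present = np.ones(6, bool)
        pred_present[1] = False
        pairs = [
            _pair_with_distances(lateral_6, np.zeros(6), fixed_cfg,
                                 pred_present=pred_present)
            for _ in range(5)
        ]
        summary = per_keypoint_pixel_errors(pairs)
        hidden = summary[lateral_6.keypoints[1]]
        assert hidden.n == 0 and hidden.n_missing == 5
        assert math.isnan(hidden.mean)


class TestRanking:
    def test_largest_sigma_ranks_first(self, rng):
        from sowpose.skeletons import Skeleton

        skel = Skeleton(name="tri", view="lateral", keypoints=("a", "b", "c"))
        cfg = MetricConfig(scale_mode="fixed", fixed_scale=10.0)
        sigmas = np.array([2.0, 2.0, 6.0])
        pairs = []
        for _ in range(2000):
            d = np.linalg.norm(rng.normal(0, sigmas[:, None], size=(3, 2)), axis=1)
            pairs.append(_pair_with_distances(skel, d, cfg))
        ranked = rank_keypoints_by_error(per_keypoint_pixel_errors(pairs))
        assert ranked[0] == "c"

    def test_tie_break_stable(self, lateral_6, fixed_cfg):
        pairs = [_pair_with_distances(lateral_6, np.zeros(6), fixed_cfg)] * 4
        ranked = rank_keypoints_by_error(per_keypoint_pixel_errors(pairs))
        assert ranked == list(lateral_6.keypoints)

    def test_single_keypoint_errors(self):
        from sowpose.skeletons import Skeleton
        from sowpose.pose_metrics import ErrorSummary

        summary = {"a": ErrorSummary(sample=np.array([1.0, 2.0]), n_missing=0)}
        with pytest.raises(ValidationError):
            rank_keypoints_by_error(summary)


class TestBruteForceOracle:
    """Full-suite equivalence against independently coded loops, 1e-12."""

    def _random_pairs(self, skeleton, rng, n_instances=20):
        cfg = MetricConfig(scale_mode="fixed", fixed_scale=25.0, k=0.3)
        pairs = []
        for _ in range(n_instances):
            k = len(skeleton)
            gt_coords = rng.uniform(0, 500, size=(k, 2))
            pred_coords = gt_coords + rng.normal(0, 8, size=(k, 2))
            gt_vis = rng.random(k) > 0.15
            if not gt_vis.any():
                gt_vis[0] = True
            pred_vis = gt_vis & (rng.random(k) > 0.1)
            gt = InstancePose(skeleton, gt_coords, gt_vis)
            pred = InstancePose(skeleton, pred_coords, pred_vis)
            pairs.append(make_pair(gt, pred, cfg))
        return pairs, cfg

    def test_oks_matches_loop(self, lateral_13, rng):
        pairs, cfg = self._random_pairs(lateral_13, rng)
        for pair in pairs:
            num = den = 0.0
            for i in range(13):
                if not pair.gt.visibility[i]:
                    continue
                den += 1
                if pair.pred.visibility[i]:
                    dx = pair.gt.coords[i, 0] - pair.pred.coords[i, 0]
                    dy = pair.gt.coords[i, 1] - pair.pred.coords[i, 1]
                    num += math.exp(-(dx * dx + dy * dy) / (2 * 25.0**2 * 0.3**2))
            assert compute_oks(pair, cfg) == pytest.approx(num / den, abs=1e-12)

    def test_dist_avg_matches_loop(self, lateral_13, rng):
        pairs, cfg = self._random_pairs(lateral_13, rng)
        total, count = 0.0, 0
        for pair in pairs:
            for i in range(13):
                if pair.gt.visibility[i] and pair.pred.visibility[i]:
                    total += math.dist(pair.gt.coords[i], pair.pred.coords[i])
                    count += 1
        assert distance_average(pairs) == pytest.approx(total / count, abs=1e-12)

    def test_pck_matches_loop(self, lateral_13, rng):
        pairs, cfg = self._random_pairs(lateral_13, rng)
        by_kp, mean = pck(pairs, cfg)
        for i, name in enumerate(lateral_13.keypoints):
            correct = total = 0
            for pair in pairs:
                if not pair.gt.visibility[i]:
                    continue
                total += 1
                if pair.pred.visibility[i]:
                    d = math.dist(pair.gt.coords[i], pair.pred.coords[i])
                    if d / pair.s < cfg.pck_alpha:
                        correct += 1
            if total:
                assert by_kp[name] == pytest.approx(correct / total, abs=1e-12)
            else:
                assert name not in by_kp

    def test_map_matches_triple_loop(self, lateral_13, rng):
        pairs, cfg = self._random_pairs(lateral_13, rng)
        oks_values = [compute_oks(p, cfg) for p in pairs]
        map_, mar = mean_average_precision(oks_values, cfg)
        acc = 0.0
        for t in cfg.oks_thresholds:
            hits = sum(1 for v in oks_values if v >= t)
            acc += hits / len(oks_values)
        assert map_ == pytest.approx(acc / len(cfg.oks_thresholds), abs=1e-12)


class TestInvariances:
    @given(st.floats(-300, 300), st.floats(-300, 300))
    @settings(max_examples=30, deadline=None)
    def test_translation_invariance(self, dx, dy, ):
        skeleton = get_skeleton("lateral_6")
        rng = np.random.default_rng(17)
        cfg = MetricConfig()
        gt_coords = rng.uniform(0, 300, size=(6, 2))
        pred_coords = gt_coords + rng.normal(0, 5, size=(6, 2))
        gt = InstancePose(skeleton, gt_coords, np.ones(6, bool))
        pred = InstancePose(skeleton, pred_coords, np.ones(6, bool))
        base = make_pair(gt, pred, cfg)
        shift = np.array([dx, dy])
        gt2 = InstancePose(skeleton, gt_coords + shift, np.ones(6, bool))
        pred2 = InstancePose(skeleton, pred_coords + shift, np.ones(6, bool))
        moved = make_pair(gt2, pred2, cfg)
        assert compute_oks(moved, cfg) == pytest.approx(compute_oks(base, cfg), rel=1e-9)
        assert distance_average([moved]) == pytest.approx(distance_average([base]), rel=1e-9)

    @given(st.floats(0.1, 20.0))
    @settings(max_examples=30, deadline=None)
    def test_scale_covariance(self, c):
        skeleton = get_skeleton("lateral_6")
        rng = np.random.default_rng(23)
        cfg = MetricConfig()
        gt_coords = rng.uniform(0, 300, size=(6, 2))
        pred_coords = gt_coords + rng.normal(0, 5, size=(6, 2))
        ones = np.ones(6, bool)
        base = make_pair(InstancePose(skeleton, gt_coords, ones),
                         InstancePose(skeleton, pred_coords, ones), cfg)
        scaled = make_pair(InstancePose(skeleton, gt_coords * c, ones),
                           InstancePose(skeleton, pred_coords * c, ones), cfg)
        assert compute_oks(scaled, cfg) == pytest.approx(compute_oks(base, cfg), rel=1e-9)
        assert pck([scaled], cfg)[1] == pck([base], cfg)[1]
        assert distance_average([scaled]) == pytest.approx(
            c * distance_average([base]), rel=1e-9
        )


class TestEvaluate:
    def _sequences(self, lateral_6, sd=0.0, n_frames=30):
        from sowpose import (
            PredictionErrorModel,
            apply_prediction_error,
            simulate_sequence,
            GaitParams,
        )

        params = GaitParams(score=0, noise_sd=0.0, occlusion_prob=0.0, view="lateral")
        gt = simulate_sequence(params, lateral_6, n_frames, seed=0)
        pred = apply_prediction_error(gt, PredictionErrorModel(sd=sd), seed=1)
        return [gt], [pred]

    def test_perfect_prediction_report(self, lateral_6):
        gt, pred = self._sequences(lateral_6, sd=0.0)
        report = evaluate(gt, pred)
        assert report.mean_oks == 1.0
        assert report.map == 1.0 and report.mar == 1.0
        assert report.dist_avg == 0.0
        assert report.pck_mean == 1.0

    def test_disjoint_video_ids_error(self, lateral_6):
        gt, pred = self._sequences(lateral_6)
        pred[0].video_id = "other"
        with pytest.raises(ValidationError):
            evaluate(gt, pred)

    def test_frame_count_mismatch_error(self, lateral_6):
        gt, pred = self._sequences(lateral_6)
        pred[0].coords = pred[0].coords[:-1]
        pred[0].visibility = pred[0].visibility[:-1]
        pred[0].frame_indices = pred[0].frame_indices[:-1]
        with pytest.raises(ValidationError):
            evaluate(gt, pred)

    def test_report_serializes(self, lateral_6, tmp_path):
        gt, pred = self._sequences(lateral_6, sd=2.0)
        report = evaluate(gt, pred)
        report.save(tmp_path / "out")
        assert (tmp_path / "out" / "report.json").exists()
        assert (tmp_path / "out" / "keypoint_errors.csv").exists()

    def test_all_scores_in_unit_interval(self, lateral_6):
        gt, pred = self._sequences(lateral_6, sd=6.0)
        report = evaluate(gt, pred)
        assert 0.0 <= report.mean_oks <= 1.0
        assert 0.0 <= report.map <= 1.0
        assert 0.0 <= report.mar <= 1.0
        assert 0.0 <= report.pck_mean <= 1.0
        assert all(0.0 <= v <= 1.0 for v in report.ap_by_threshold.values())


class TestGreedyMatch:
    def test_matches_obvious_pairing(self, lateral_6):
        rng = np.random.default_rng(4)
        cfg = MetricConfig()
        ones = np.ones(6, bool)
        gts, preds = [], []
        for offset in (0.0, 2000.0):
            coords = rng.uniform(0, 300, size=(6, 2)) + offset
            gts.append(InstancePose(lateral_6, coords, ones))
            preds.append(InstancePose(lateral_6, coords + rng.normal(0, 2, (6, 2)), ones))
        matches = greedy_match(gts, list(reversed(preds)), cfg)
        # instance i should match the reversed index 1-i
        assigned = {i: j for i, j, _ in matches}
        assert assigned == {0: 1, 1: 0}
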