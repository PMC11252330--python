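# sowpose

Tooling for sow-locomotion pose analysis: a synthetic gait generator with
lameness-score-dependent signatures, expert-vote consensus with
confidence filtering, skeleton definitions for lateral/dorsal camera
views, a pose-estimation metric suite (OKS, mAP/mAR, dist.avg, PCK,
per-keypoint pixel errors), and dataset bookkeeping (manifests, frame
filtering, train/test splitting, annotation I/O).

## Package layout

| module | contents |
| --- | --- |
| `sowpose.skeletons` | registry of the five built-in skeletons (`lateral_6/11/13`, `dorsal_7/10`), subset derivation, pose projection |
| `sowpose.gait_sim` | `simulate_sequence`, `stride_asymmetry_index`, `apply_prediction_error`, `simulate_votes`, per-score presets |
| `sowpose.consensus` | `majority_score`, `compute_dba`, `confidence_from_dba`, `detect_outlier_experts`, `build_repository`, `transfer_scores` |
| `sowpose.pose_metrics` | `compute_oks`, `average_precision`, `mean_average_precision`, `distance_average`, `pck`, `per_keypoint_pixel_errors`, `rank_keypoints_by_error`, `evaluate` |
| `sowpose.dataset_ops` | `filter_fully_visible_frames`, `split_dataset`, annotation/trajectory/manifest I/O, `dataset_summary` |

The gait model is kinematic, not biomechanical: per-score presets
(`src/sowpose/data/gait_presets.cfg`) are invented modelling choices whose
only contract is that asymmetry, head-dip and back-arch signatures grow
monotonically with the locomotion score (0 = sound, 3 = severely lame).
With asymmetry `a` on one limb and zero noise the stride-asymmetry index
of a generated sequence is exactly `a / (2 - a)`.

## CLI

A single entry point with subcommands (exit codes: 0 ok, 2 validation
error, 3 I/O error):

```bash
sowpose simulate  --out sim/ --seed 1 --skeleton lateral_6 --videos-per-score 4
sowpose consensus --votes sim/votes.csv --manifest sim/manifest.json --out repo/
sowpose evaluate  --gt sim/gt.csv --pred sim/pred.csv --out report/
sowpose split     --manifest sim/manifest.json --out split.json --seed 2
sowpose report    --manifest sim/manifest.json --annotations sim/gt.csv --out summary.csv
```

Annotations are long-format CSV (`video_id, view, frame, keypoint, x, y,
visible`); round-trips are lossless. Votes are `video_id, expert_id,
score` CSV with scores 0–3.

## Tests

```bash
python -m pytest -q
```

`tests/test_acceptance.py` holds the acceptance criteria: closed-form
Gaussian-error oracles for the metrics (mean OKS `s²k²/(s²k²+σ²)`,
dist.avg `σ√(π/2)`, PCK `1−exp(−(αs)²/(2σ²))`), brute-force loop
equivalence at 1e-12, σ recovery from dist.avg, consensus recovery with a
13-expert panel, metric invariance properties, repository arithmetic
checks, and generator score-monotonicity.

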