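# Default per-score gait presets.
# These numbers are invented modelling choices: the locomotion scoring scale
# is behavioural ("moves easily" ... "real reluctance to walk"), so the only
# contract is that asymmetry / head-dip / back-arch signatures grow
# monotonically with the score.  Units: px and cycles/frame at 1920x1080.

common.speed = 4.0
common.stride_freq = 0.05
common.stride_amp = 40.0
common.lift_amp = 12.0
common.sway_amp = 8.0
common.noise_sd = 1.5
common.occlusion_prob = 0.03
common.frame_width = 1920
common.frame_height = 1080

score0.asymmetry = 0.0
score0.head_amp = 0.0
score0.arch_amp = 0.0
score0.affected_limb = none

score1.asymmetry = 0.2
score1.head_amp = 4.0
score1.arch_amp = 2.0
score1.affected_limb = hind_left

score2.asymmetry = 0.45
score2.head_amp = 10.0
score2.arch_amp = 8.0
score2.affected_limb = hind_left
score2.speed = 3.5

score3.asymmetry = 0.7
score3.head_amp = 16.0
score3.arch_amp = 14.0
score3.affected_limb = hind_left
score3.speed = 2.5
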