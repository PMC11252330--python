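{
  "lateral_13": {
    "view": "lateral",
    "keypoints": [
      "snout",
      "hoof_front_right",
      "hoof_front_left",
      "hoof_posterior_right",
      "hoof_posterior_left",
      "rump",
      "neck",
      "pastern_right",
      "pastern_left",
      "hock_right",
      "hock_left",
      "dorsal_neck",
      "dorsal_rump"
    ],
    "parent": null,
    "removed": []
  },
  "lateral_11": {
    "view": "lateral",
    "parent": "lateral_13",
    "removed": ["dorsal_neck", "dorsal_rump"]
  },
  "lateral_6": {
    "view": "lateral",
    "parent": "lateral_13",
    "removed": [
      "dorsal_neck",
      "dorsal_rump",
      "hock_right",
      "hock_left",
      "neck",
      "pastern_right",
      "pastern_left"
    ]
  },
  "dorsal_10": {
    "view": "dorsal",
    "keypoints": [
      "head",
      "neck",
      "scapula_right",
      "scapula_left",
      "thoracic",
      "middle",
      "lumbar",
      "pelvic_right",
      "pelvic_left",
      "tail"
    ],
    "parent": null,
    "removed": []
  },
  "dorsal_7": {
    "view": "dorsal",
    "parent": "dorsal_10",
    "removed": ["head", "thoracic", "lumbar"]
  }
}
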