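{
  "screen": {
    "width_px": 1680,
    "height_px": 1050,
    "width_cm": 47.4,
    "height_cm": 29.6,
    "viewing_distance_cm": 50.0
  },
  "block_order": ["RJA", "IJA1", "IJA2"],
  "tasks": {
    "RJA": {
      "segments_ms": {"looking_down": 2000, "interaction": 2000, "ja": 4000},
      "aois": {
        "face": [690, 100, 990, 400],
        "left_object": [240, 600, 540, 900],
        "right_object": [1140, 600, 1440, 900]
      },
      "trials": [
        {"target_side": "left"},
        {"target_side": "right"},
        {"target_side": "right"},
        {"target_side": "left"}
      ]
    },
    "IJA1": {
      "segments_ms": {"looking_down": 2000, "interaction": 2000, "ja": 7000},
      "aois": {
        "face": [690, 100, 990, 400],
        "left_object": [240, 600, 540, 900],
        "right_object": [1140, 600, 1440, 900]
      },
      "trials": [
        {"target_side": "right"},
        {"target_side": "left"},
        {"target_side": "left"},
        {"target_side": "right"}
      ]
    },
    "IJA2": {
      "segments_ms": {"looking_down": 2000, "interaction": 2000, "ja": 7000},
      "aois": {
        "face": [690, 100, 990, 400],
        "left_object": [240, 600, 540, 900],
        "right_object": [1140, 600, 1440, 900]
      },
      "trials": [
        {"target_side": "left"},
        {"target_side": "right"},
        {"target_side": "left"},
        {"target_side": "right"}
      ]
    }
  }
}
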