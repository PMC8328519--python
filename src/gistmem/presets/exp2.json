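{
  "n_items": 8,
  "screen": {"width": 1366, "height": 768},
  "targets": {
    "item_vs_screen_center": 386,
    "item_vs_encoded_center": 262,
    "gist_vs_screen_center": 223,
    "min_pair_separation": 100,
    "outlier_offset": 573
  },
  "params": {
    "n_participants": 43,
    "sessions": ["S1", "S2", "S3"],
    "delay_groups": {"within_subject": 43},
    "item_error_scale": {"S1": 50, "S2": 120, "S3": 180},
    "gist_error_scale": {"S1": 50, "S2": 70, "S3": 90},
    "gist_pull": {"S1": 0.1, "S2": 0.3, "S3": 0.6},
    "outlier_weight": 0.25,
    "swap_rate": 0.0
  }
}
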