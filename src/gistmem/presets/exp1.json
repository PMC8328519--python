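{
  "n_items": 6,
  "screen": {"width": 1366, "height": 768},
  "targets": {
    "item_vs_screen_center": 348,
    "item_vs_encoded_center": 267,
    "gist_vs_screen_center": 270,
    "min_pair_separation": 160
  },
  "params": {
    "n_participants": 130,
    "sessions": ["S1", "S2"],
    "delay_groups": {"24h": 44, "1week": 43, "1month": 43},
    "item_error_scale": {"S1": 70, "S2": {"24h": 110, "1week": 150, "1month": 200}},
    "gist_error_scale": {"S1": 60, "S2": {"24h": 70, "1week": 85, "1month": 110}},
    "gist_pull": {"S1": 0.1, "S2": {"24h": 0.2, "1week": 0.4, "1month": 0.6}},
    "swap_rate": 0.02
  }
}
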