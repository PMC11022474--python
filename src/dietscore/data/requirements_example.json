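{
  "protein": {"mode": "probability", "ear": 38.0, "cv": 0.125},
  "fiber": {"mode": "reference_ratio", "reference": 25.0},
  "calcium": {"mode": "probability", "ear": 800.0, "cv": 0.1},
  "iron": {"mode": "probability",
           "curve": [[4, 0.0], [6, 0.15], [8, 0.4], [10, 0.6], [14, 0.85], [18, 0.95], [25, 1.0]]},
  "zinc": {"mode": "probability", "ear": 6.8, "cv": 0.1},
  "vitamin_a": {"mode": "probability", "ear": 500.0, "cv": 0.2},
  "folate": {"mode": "probability", "ear": 320.0, "cv": 0.1},
  "vitamin_b12": {"mode": "probability", "ear": 2.0, "cv": 0.1}
}
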