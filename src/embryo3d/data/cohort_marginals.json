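{
  "female_age": {"kind": "continuous", "mean": 35.36, "sd": 4.73, "min": 20, "max": 46, "integer": true},
  "n_prev_transfers": {"kind": "continuous", "mean": 2.57, "sd": 2.29, "min": 1, "max": 23, "integer": true},
  "amh": {"kind": "continuous", "mean": 3.0, "sd": 2.83, "min": 0.01, "max": 22.96, "integer": false},
  "day3_blastomeres": {"kind": "continuous", "mean": 8.56, "sd": 2.01, "min": 3, "max": 16, "integer": true},
  "day3_grade": {"kind": "ordinal", "mean": 1.97, "support": [1, 2, 3, 4]},
  "cryo_day": {"kind": "ordinal", "mean": 1.41, "support": [1, 2, 3]},
  "icm_grade": {"kind": "ordinal", "mean": 1.59, "support": [1, 2, 3]},
  "te_grade": {"kind": "ordinal", "mean": 1.77, "support": [1, 2, 3]},
  "avg_diameter": {"kind": "continuous", "mean": 180.8, "sd": 27.17, "min": 119.56, "max": 371.59, "integer": false}
}
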