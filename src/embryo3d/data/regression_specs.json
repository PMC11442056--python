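{
  "female_age": {
    "family": "scaled_logistic",
    "params": {"b0": -12.112, "b1": 0.286, "k": 0.506},
    "se": {"b0": 8.992, "b1": 0.217, "k": null}
  },
  "n_prev_transfers": {
    "family": "logistic",
    "params": {"b0": -0.2712, "b1": 0.166},
    "se": {"b0": 1.245, "b1": 0.175}
  },
  "amh": {
    "family": "logistic",
    "params": {"b0": 0.358, "b1": -0.046},
    "se": {"b0": 2.068, "b1": 0.158}
  },
  "day3_blastomeres": {
    "family": "scaled_gaussian",
    "params": {"sigma": 4.813, "m": 10.063, "k": 6.737},
    "se": {"sigma": 1.142, "m": 0.874, "k": 1.259}
  },
  "day3_grade": {
    "family": "scaled_logistic",
    "params": {"b0": -8.381, "b1": 2.574, "k": 0.5},
    "se": {"b0": 16.265, "b1": 5.645, "k": null}
  },
  "cryo_day": {
    "family": "linear",
    "params": {"b0": 0.852, "b1": -0.161},
    "se": {"b0": null, "b1": null}
  },
  "icm_grade": {
    "family": "linear",
    "params": {"b0": 0.789, "b1": -0.2},
    "se": {"b0": 0.011, "b1": 0.005}
  },
  "te_grade": {
    "family": "linear",
    "params": {"b0": 0.791, "b1": -0.182},
    "se": {"b0": 0.018, "b1": 0.008}
  },
  "avg_diameter": {
    "family": "logistic",
    "params": {"b0": 0.308, "b1": -0.001},
    "se": {"b0": 4.242, "b1": 0.016}
  }
}
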