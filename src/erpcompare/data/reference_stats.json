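{
  "description": "Published group summaries (mean, SD, n) of P1/N1/P2 peak latency per presentation modality, with the inferential statistics reported alongside them. Means and SDs are in ms; n = 33 per group. 'reported' holds the printed post-hoc results: test type, t, df, Cohen's d (null where not printed), and the JZS BF10 ('>1000' where only a bound was printed). Printed t signs follow the original pair ordering; compare magnitudes.",
  "alpha": 0.05,
  "n_comparisons_per_family": 3,
  "latency_summaries": {
    "P1": {
      "PC": {"mean": 121.33, "sd": 12.31, "n": 33},
      "VR": {"mean": 120.18, "sd": 22.20, "n": 33},
      "RL": {"mean": 136.66, "sd": 22.38, "n": 33}
    },
    "N1": {
      "PC": {"mean": 188.42, "sd": 10.13, "n": 33},
      "VR": {"mean": 154.88, "sd": 15.45, "n": 33},
      "RL": {"mean": 186.91, "sd": 8.95, "n": 33}
    },
    "P2": {
      "PC": {"mean": 273.53, "sd": 20.85, "n": 33},
      "VR": {"mean": 271.96, "sd": 25.24, "n": 33},
      "RL": {"mean": 259.14, "sd": 26.25, "n": 33}
    }
  },
  "reported_posthoc": [
    {"component": "P1", "pair": ["VR", "PC"], "test": "student", "t": 0.26, "df": 64, "d": null, "bf10": 0.26, "significant": false},
    {"component": "P1", "pair": ["RL", "VR"], "test": "student", "t": -3.00, "df": 64, "d": -0.74, "bf10": 10.14, "significant": true},
    {"component": "P1", "pair": ["RL", "PC"], "test": "welch", "t": -3.45, "df": 49.75, "d": -0.85, "bf10": 30.64, "significant": true},
    {"component": "N1", "pair": ["VR", "RL"], "test": "welch", "t": -10.30, "df": 51.31, "d": -2.55, "bf10": ">1000", "significant": true},
    {"component": "N1", "pair": ["VR", "PC"], "test": "welch", "t": -10.42, "df": 55.21, "d": -2.56, "bf10": ">1000", "significant": true},
    {"component": "N1", "pair": ["PC", "RL"], "test": "student", "t": 0.64, "df": 64, "d": null, "bf10": 0.30, "significant": false},
    {"component": "P2", "pair": ["RL", "PC"], "test": "student", "t": 2.47, "df": 64, "d": 0.61, "bf10": 3.14, "significant": true},
    {"component": "P2", "pair": ["RL", "VR"], "test": "student", "t": 2.02, "df": 64, "d": 0.50, "bf10": 1.40, "significant": false},
    {"component": "P2", "pair": ["PC", "VR"], "test": "student", "t": 0.28, "df": 64, "d": null, "bf10": 0.26, "significant": false}
  ]
}
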