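{
  "binning": {
    "convention": "np1",
    "include_sentinels": true,
    "note": "Frozen by calibration: the (n+1)*p positional rule applied to the metabolite weight columns WITH the -1 absence sentinels included reproduces every printed metabolite bin boundary, and the same rule applied to the 33 pathway indicator columns reproduces every printed pathway bin boundary."
  },
  "metabolite_model": {
    "n_inputs": 4,
    "categories": ["Weak", "Moderate", "Good", "Excellent"],
    "output_universe": [0.0, 100.0]
  },
  "route_model": {
    "n_inputs": 4,
    "betweenness_categories": ["Weak", "Good", "Excellent"],
    "output_universe": [0.0, 100.0]
  }
}
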