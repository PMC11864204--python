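{
  "version": "1.0",
  "note": "Acute Ni gBAM parameter sets. log K values in log10 L/mol; pH segments as [lower, upper, S_pH]; applicability ranges give the calibration/validation window of each model. The high-pH slope of the average invertebrate model is stored at full precision (mean of the C. dubia slope 1.095 and the H. azteca slope 0.9177); it is conventionally reported as 1.006.",
  "models": {
    "d_magna": {
      "log_k_ca": 3.10,
      "log_k_mg": 2.47,
      "segments": [[5.7, 8.1, 0.0]],
      "ph_range": [5.7, 8.1],
      "hardness_range": [6.2, 292.0]
    },
    "d_pulex": {
      "log_k_ca": 4.20,
      "log_k_mg": 3.60,
      "segments": [[5.6, 8.3, 0.0]],
      "ph_range": [5.6, 8.3],
      "hardness_range": [16.0, 161.0]
    },
    "c_dubia": {
      "log_k_ca": 3.30,
      "log_k_mg": 3.30,
      "segments": [[6.3, 8.1, 0.0]],
      "ph_range": [6.3, 8.1],
      "hardness_range": [15.0, 253.0]
    },
    "avg_invertebrate": {
      "log_k_ca": 3.80,
      "log_k_mg": 3.32,
      "segments": [[5.6, 8.0, 0.0], [8.0, 8.9, 1.00635]],
      "ph_range": [5.6, 8.9],
      "hardness_range": [6.2, 339.0]
    },
    "algae": {
      "log_k_ca": null,
      "log_k_mg": 3.30,
      "segments": [[5.7, 8.2, 0.143], [8.2, 8.7, 0.906]],
      "ph_range": [5.7, 8.7],
      "hardness_range": [6.3, 315.0]
    },
    "fish": {
      "log_k_ca": 3.60,
      "log_k_mg": 3.60,
      "segments": [[5.5, 8.8, 0.324]],
      "ph_range": [5.5, 8.8],
      "hardness_range": [12.0, 290.0]
    }
  }
}
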