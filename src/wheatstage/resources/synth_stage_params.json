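{
  "comment": "Per-stage appearance parameters for the synthetic wheat-canopy generator. base_color is RGB in [0,1] tracing the green-to-yellow maturation path; stripe_freq is the vertical row-pattern frequency in cycles per image width (canopy density proxy); blob_count is the expected number of bright ellipse blobs (spike emergence proxy); blob_color is the blob RGB.",
  "stages": {
    "1": {"base_color": [0.22, 0.30, 0.16], "stripe_freq": 3.0, "blob_count": 0, "blob_color": [0.55, 0.60, 0.35]},
    "2": {"base_color": [0.16, 0.42, 0.14], "stripe_freq": 6.0, "blob_count": 0, "blob_color": [0.55, 0.60, 0.35]},
    "3": {"base_color": [0.18, 0.52, 0.16], "stripe_freq": 12.0, "blob_count": 2, "blob_color": [0.55, 0.65, 0.35]},
    "4": {"base_color": [0.30, 0.55, 0.18], "stripe_freq": 18.0, "blob_count": 8, "blob_color": [0.65, 0.70, 0.35]},
    "5": {"base_color": [0.45, 0.55, 0.20], "stripe_freq": 24.0, "blob_count": 20, "blob_color": [0.80, 0.78, 0.40]},
    "6": {"base_color": [0.55, 0.52, 0.22], "stripe_freq": 27.0, "blob_count": 28, "blob_color": [0.85, 0.80, 0.45]},
    "7": {"base_color": [0.62, 0.50, 0.24], "stripe_freq": 30.0, "blob_count": 35, "blob_color": [0.90, 0.85, 0.50]}
  }
}
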