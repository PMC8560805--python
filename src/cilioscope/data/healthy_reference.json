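{
  "note": "Healthy cilium phenotype of cultured dermal fibroblasts, derived from six unrelated control lines. Ciliogenesis SD is across lines; length/IFT SDs are SDs of the six per-line bootstrap medians. These values are set-up dependent: each laboratory should refit them from its own control lines.",
  "ciliogenesis_pct": {"value": 90.0, "sd": 8.0},
  "length_um": {"value": 3.71, "sd": 0.04},
  "ift_um2": {"value": 0.43, "sd": 0.01}
}
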