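{
  "description": "Published pairwise COI distances (percent, one decimal) among 12 Stenotaenia specimens: Kimura-2-parameter model in the upper-right triangle, p-distances in the lower-left triangle; bootstrap standard errors (500 pseudoreplicates) in the parallel SE file.",
  "units": "percent",
  "upper_triangle_model": "k2p",
  "lower_triangle_model": "p",
  "suspect_se": [
    {
      "pair": ["Barbarano", "Frosinone"],
      "model": "k2p",
      "printed": "0.17",
      "note": "Anomalous format: every other SE is printed to one decimal; plausibly 1.7 but kept as printed and flagged rather than guessed."
    }
  ]
}
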