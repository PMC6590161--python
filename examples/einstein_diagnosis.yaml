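# Counterfactual framing of the same trial numbers: treat the VTE
# diagnosis itself as uncertain and independent of the utilities.
# Yields the classic disease-probability threshold (implausibly high
# at these numbers — the reason the outcome-risk framing exists).
schema_version: "1"
question: disease_probability_threshold
rounding_mode: paper
scenario:
  units: percent
  m: 7.1
  m_rx: 1.3
  h_rx: 4.8
  rv_h: 1.0
  regime: independent
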