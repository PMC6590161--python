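# Extended anticoagulation after venous thromboembolism (EINSTEIN
# extension trial arms): should rivaroxaban be continued, given the
# recurrence risk it prevents and the major-bleeding risk it adds?
# Recurrent VTE is diagnosed only when the outcome event (a new clot)
# occurs, so the disease definition contains the outcome: dependent
# regime, outcome-risk threshold.
schema_version: "1"
question: outcome_risk_threshold
rounding_mode: paper
scenario:
  units: percent
  m: 7.1        # VTE recurrence risk, placebo arm (42/594)
  m_rx: 1.3     # VTE recurrence risk, rivaroxaban arm (8/602)
  h_rx: 4.8     # major bleeding risk on rivaroxaban
  rv_h: 1.0     # bleeding valued equal to recurrence
  regime: dependent
sweep:
  parameter: h_rx
  grid_start: 0.0
  grid_stop: 0.10
  grid_step: 0.005
  rv_values: [1.0, 0.75, 0.5, 0.25, 0.05]
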