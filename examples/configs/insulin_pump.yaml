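# Clinical context II: insulin pump programmed from the patient profile.
# The dose calculator derives baid/boid/cboid from weight and glucose; the
# pump runs a full day; safety monitors and a coverage report are produced.
scenario: insulin_pump
seed: 42
horizon: 1440.0
dt: 1.0
patient: {gender: male, weight: 84.3, height: 169.8, group: 1}
initial_vitals: {gl: 119}
pump:
  basal_profile: standard
  bolus_times: [480.0, 720.0, 1140.0]   # breakfast, lunch, dinner (minutes)
corrective_times: [800.0]
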