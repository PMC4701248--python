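# Clinical context I: continuous ICU monitoring.
# An ICU patient publishes hr/rr/sbp/pt/gl; five periodic sensors sample
# them and relay the measurements through a centralizer to a bedside monitor.
scenario: icu_monitoring
seed: 42
horizon: 60.0
dt: 1.0
patient:
  gender: female
  weight: 84.3
  height: 169.8
  group: 1
initial_vitals: {hr: 87, rr: 19, sbp: 117, pt: 37.3, gl: 119}
sensors:
  - {id: cardiac_monitor, signal: hr, period: 1.0}
  - {id: breathing_monitor, signal: rr, period: 1.0}
  - {id: bp_meter, signal: sbp, period: 3.0}
  - {id: thermometer, signal: pt, period: 5.0}
  - {id: glucometer, signal: gl, period: 5.0}
interventions:
  - {time: 30.0, sign: gl, value: 175.0}   # hyperglycemic episode mid-run
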