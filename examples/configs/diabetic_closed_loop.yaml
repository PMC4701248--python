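# Clinical context III: closed-loop glucose control.
# Bergman glucose-insulin patient under PID control (gains tuned from the
# linearized insulin channel unless given here); a meal disturbance at t=60;
# the glucose channel drives the GLM vitals each step.
scenario: diabetic_closed_loop
seed: 42
horizon: 600.0
dt: 0.5
patient: {gender: female, weight: 84.3, height: 169.8, group: 1}
disturbances:
  - {start: 60.0, duration: 30.0, channel: D, magnitude: 2.0}
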