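"""Operating point, linearization and the transfer-function view.

Computes the closed-form equilibrium of the glucose-insulin kinetics
under a constant insulin infusion, linearizes the model there (the
Jacobian is upper triangular, so stability is read off the diagonal),
and derives the insulin-channel transfer function used to tune the PID
controller.
"""

import numpy as np

from mcpsim.bergman import BergmanParams, equilibrium_point, linearize, ss_to_transfer_gains
from mcpsim.pid import tune_pid

params = BergmanParams()
op = equilibrium_point(params, (0.0, 0.0, 0.5))  # 0.5 U/h steady infusion
print(f"equilibrium under 0.5 U/h insulin: G0={op.G0:.2f} mg/dL, "
      f"X0={op.X0:.5f} 1/min, I0={op.I0:.2f} uU/mL")
print("(glucose settles below basal because steady insulin raises the "
      "remote insulin action X)")

model = linearize(params, op)
eig = np.linalg.eigvals(model.A)
print(f"\neigenvalues of the state matrix: {np.sort(eig.real)} (all < 0: stable)")

num, den = ss_to_transfer_gains(model, "r")
dc = np.polyval(num, 0) / np.polyval(den, 0)
print(f"insulin channel static gain: {dc:.1f} mg/dL per U/h "
      "(negative: insulin lowers glucose)")

pid = tune_pid(params)
print(f"\nPID gains from the SIMC-style rule on this channel: "
      f"Kp={pid.Kp:.4f}, Ki={pid.Ki:.5f}, Kd={pid.Kd}")
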