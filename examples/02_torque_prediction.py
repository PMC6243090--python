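"""Joint torque prediction from activations.

Loads the shipped default elbow model (biceps + triceps), evaluates the
Hill-type torque at a mid-flexion pose for a few activation patterns, and
shows the gravity torque the muscles must overcome.
"""

import numpy as np

from emgnms import default_models, gravity_torques

models, anthro = default_models()
elbow = models["elbow"]
theta1, theta2 = 0.6, 1.0  # shoulder elevation, elbow flexion (rad)

print(f"elbow model muscles: {elbow.muscle_names}")
for a_bb, a_tb in [(0.0, 0.0), (0.3, 0.0), (0.3, 0.3), (0.0, 0.5)]:
    tau = elbow.predict_torque([a_bb, a_tb], theta2)
    print(f"  a_BB={a_bb:.1f}  a_TB={a_tb:.1f}  ->  tau_elbow = {tau:+.2f} N*m")

tau_sh_g, tau_el_g = gravity_torques(anthro, theta1, theta2)
print(f"gravity torques at this pose: shoulder {tau_sh_g:.2f} N*m, "
      f"elbow {tau_el_g:.2f} N*m")
print("Flexors (positive moment arm) add torque, the triceps subtracts it;")
print("co-contraction cancels while still costing muscle force.")
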