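"""Subject calibration with the linear least-squares method.

Simulates a subject whose maximal muscle forces and limb masses differ
from the normative defaults, synthesises the 40-trial isometric-reaching
protocol without measurement noise, calibrates on half the trials, and
compares the recovered parameters with the simulated truth.
"""

import numpy as np

from emgnms import (
    NoiseConfig,
    build_design,
    calibrate_linear,
    default_models,
    evaluate_model,
    sample_subject,
    split_dataset,
    synthesize_dataset,
)
from emgnms.gravity import default_masses

subject = sample_subject(1, mode="linear", noise=NoiseConfig.noiseless())
dataset = synthesize_dataset(subject, seed=2)
split = split_dataset(dataset, seed=3)
train = build_design(dataset, split.train_ids)
val = build_design(dataset, split.val_ids)

models, base_anthro = default_models()
M_a0, M_fh0 = default_masses(dataset.body_mass)
anthro0 = base_anthro.with_masses(M_a=M_a0, M_fh=M_fh0)

for joint, true_model in (("elbow", subject.true_model_elbow),
                          ("shoulder", subject.true_model_shoulder)):
    fit = calibrate_linear(train, models[joint], anthro0)
    metrics = evaluate_model(fit.model, fit.anthro, val)
    print(f"[{joint}]  validation E_RMS = {metrics['e_rms']:.3f} N*m, "
          f"R2 = {metrics['r2']:.4f}")
    for name, F_hat, F_true in zip(fit.model.muscle_names,
                                   fit.details["F_O_hat"],
                                   [m.F_O for m in true_model.muscles]):
        print(f"    F_O[{name}]  fitted {F_hat:7.1f} N   true {F_true:7.1f} N "
              f"({100 * abs(F_hat / F_true - 1):.1f}% off)")
print("Recovery errors of a few percent reflect the envelope-extraction")
print("residual of the causal EMG filters, the only error source here.")
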