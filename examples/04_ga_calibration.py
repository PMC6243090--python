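"""Deep subject calibration with the genetic algorithm.

Simulates a subject whose full parameter set (12 per muscle plus link
masses) deviates from the defaults, runs the bounded real-coded GA on the
training split of the elbow model, and reports the best-cost trace and
validation fit.
"""

from emgnms import (
    GAConfig,
    NoiseConfig,
    build_design,
    calibrate_ga,
    default_models,
    evaluate_model,
    sample_subject,
    split_dataset,
    synthesize_dataset,
)
from emgnms.gravity import default_masses

subject = sample_subject(1, mode="full", noise=NoiseConfig.noiseless())
dataset = synthesize_dataset(subject, seed=2)
split = split_dataset(dataset, seed=3)
train = build_design(dataset, split.train_ids)
val = build_design(dataset, split.val_ids)

models, base_anthro = default_models()
M_a0, M_fh0 = default_masses(dataset.body_mass)
anthro0 = base_anthro.with_masses(M_a=M_a0, M_fh=M_fh0)

fit = calibrate_ga(train, models["elbow"], anthro0,
                   GAConfig(seed=5, max_generations=200))
trace = fit.details["trace"]
print("best-cost trace (N*m):")
for g in range(0, len(trace), max(1, len(trace) // 8)):
    print(f"  generation {g:4d}   E_RMS {trace[g]:.3f}")
print(f"stopped after {fit.details['n_generations']} generations "
      f"({fit.details['stop_reason']}); after the local polish the training "
      f"cost is {fit.details['best_cost']:.3f} N*m")
metrics = evaluate_model(fit.model, fit.anthro, val)
print(f"validation: E_RMS = {metrics['e_rms']:.3f} N*m, R2 = {metrics['r2']:.4f}")
print("The trace is non-increasing (elitism); the deep calibration absorbs")
print("geometry mismatch the linear method cannot represent.")
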