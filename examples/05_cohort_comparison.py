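"""Three-condition comparison on a small synthetic cohort.

Simulates three subjects with realistic EMG noise, calibrates each with
the linear and GA methods on the training split, and prints mean +/- SD
validation performance for the non-optimised, linear, and GA conditions —
the structure of a calibration-method comparison study.
"""

import warnings

warnings.filterwarnings("ignore")

from emgnms.study import run_cohort_study

report = run_cohort_study(n_subjects=3, seed=7)
print(f"{'joint':9s} {'condition':14s} {'E_RMS (N*m)':>14s} {'R2':>12s}")
for row in report.summary():
    if row["metric"] == "e_rms":
        r2 = next(r for r in report.summary()
                  if r["joint"] == row["joint"] and r["condition"] == row["condition"]
                  and r["metric"] == "r2")
        print(f"{row['joint']:9s} {row['condition']:14s} "
              f"{row['mean']:7.2f} ± {row['sd']:4.2f} "
              f"{r2['mean']:7.3f} ± {r2['sd']:4.2f}")
print("Both calibrations beat the normative model; the GA's extra freedom")
print("helps most at the elbow, where the two modelled muscles dominate.")
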