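# emgnms

EMG-driven neuromusculoskeletal torque estimation for the shoulder and
elbow, with two subject-calibration routes.

Myo-controlled exoskeletons and rehabilitation robots need the user's
intended joint torques decoded from muscle activity in real time, and they
need the decoder calibrated to a new user in minutes, not hours. `emgnms`
implements a deliberately minimal Hill-type model for that setting —
isometric, stiff-tendon, four muscles (biceps brachii BB, triceps brachii
TB, anterior deltoid AD, posterior deltoid PD) — and the two calibration
strategies whose trade-off the package exists to study:

* **Linear calibration (LO):** one maximal force per muscle plus gravity
  mass scale factors, solved by ordinary least squares in milliseconds;
* **GA calibration:** 12 parameters per muscle plus the link masses
  (50 genes for the shoulder, 25 for the elbow), minimised by a bounded
  real-coded genetic algorithm with a local finishing step.

## The model

Surface EMG is conditioned into an excitation
(20 Hz high-pass → rectify → MVC-normalise → 5 Hz low-pass, then the
80 ms electromechanical delay, all causal), mapped to activation by
`a(u) = (e^{Au} − 1)/(e^A − 1)` with shape factor `A ∈ [−3, 0]`, and
converted to joint torque by

    τ^p = Σ_i F_O^i [ f_l(l̃_i) a_i + f_P(l̃_i) ] cos φ_i · r_i(θ),

with Gaussian active force–length curve `f_l`, pennation
`φ = arcsin(l_o sin φ_o / l)`, and cubic fiber-length and moment-arm
curves `l(θ)`, `r(θ)`. A two-link gravity model
(`τ_el^g = M_fh l_2 g sin(θ1+θ2)`, shoulder analogously) separates the
posture-holding torque from the external torque `τ^e` that both
calibrations fit: `E_RMS = rms(τ^m − (τ^p − τ^g))`.

Because the seven-subject recordings behind the original study are not
public, the package ships a first-class synthetic protocol generator
(5 sagittal poses × 4 force directions × 2 repetitions at 15 N, 1200 Hz,
4-channel EMG + MVC recordings) with known ground truth, used by the test
suite for end-to-end parameter-recovery and method-comparison studies.
See `docs/methods.md` for assumptions, parameters and limitations.

## Worked example

Calibrate a simulated subject whose maximal forces and limb masses differ
from the normative defaults (`examples/03_linear_calibration.py`):

```text
[elbow]  validation E_RMS = 0.040 N*m, R2 = 0.9997
    F_O[BB]  fitted  2420.1 N   true  2395.1 N (1.0% off)
    F_O[TB]  fitted  2658.1 N   true  2636.5 N (0.8% off)
[shoulder]  validation E_RMS = 0.052 N*m, R2 = 0.9998
    F_O[BB]  fitted  1570.9 N   true  1552.0 N (1.2% off)
    F_O[TB]  fitted  1786.3 N   true  1769.3 N (1.0% off)
    F_O[AD]  fitted  3276.4 N   true  3245.6 N (0.9% off)
    F_O[PD]  fitted  2702.1 N   true  2674.3 N (1.0% off)
```

The least-squares fit recovers every maximal force to ~1% on noiseless
data; the residual is the envelope-extraction error of the causal filters.
A three-subject cohort with realistic EMG noise
(`examples/05_cohort_comparison.py`) reproduces the qualitative result the
method comparison is about — both calibrations beat the normative model,
and the GA's extra freedom matters most at the elbow:

```text
joint     condition         E_RMS (N*m)           R2
elbow     non-optimized     3.39 ± 1.35  -1.344 ± 1.87
elbow     linear            1.29 ± 0.12   0.690 ± 0.06
elbow     ga                0.50 ± 0.07   0.953 ± 0.01
shoulder  non-optimized     8.77 ± 5.67  -5.056 ± 7.25
shoulder  linear            0.98 ± 0.33   0.937 ± 0.04
shoulder  ga                0.89 ± 0.36   0.946 ± 0.04
```

The other scripts in `examples/` walk through EMG conditioning, torque
prediction, and a single GA run with its convergence trace. A thin CLI
(`emgnms simulate|fit-linear|fit-ga|evaluate`) wraps the same library
calls for shell use.

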