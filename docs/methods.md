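# Methods

`emgnms` implements a deliberately minimal EMG-driven neuromusculoskeletal
(NMS) model for predicting isometric shoulder- and elbow-flexion/extension
torques from surface EMG, together with two subject-calibration routes and a
synthetic protocol generator used to validate both end to end.

## The torque model

**EMG conditioning.** Raw EMG is high-pass filtered (20 Hz, 2nd-order
Butterworth), full-wave rectified, normalised by the per-muscle MVC
amplitude, and low-pass filtered (5 Hz, 2nd-order Butterworth) into the
linear envelope `e(t)`. Filtering is causal by default, matching real-time
myo-control use; a zero-phase option exists for offline analysis but every
shipped test uses the causal path. Initial conditions are zero-state and the
first 0.5 s of any recording is flagged as filter transient and excluded
from calibration. The neural excitation is the delayed envelope
`u(t) = e(t − d)` with electromechanical delay `d = 80 ms` (physiological
range 10–150 ms); fractional-sample delays use linear interpolation with
leading-edge hold. The MVC reference is the maximum of the processed
envelope over each 10 s maximal contraction, then the maximum across the
four force directions — the conservative normaliser among the common
conventions (peak vs. plateau mean), chosen because the downstream
activation map is calibrated on `u ∈ [0, 1]`. Envelopes above 1 are not
clipped; `u` is clipped to `[0, 1]` only at the activation map.

**Activation nonlinearity.** `a(u) = (e^{Au} − 1)/(e^A − 1)` with shape
factor `A ∈ [−3, 0]`; `A = 0` is resolved by its analytic limit `a = u`.
The map is strictly increasing with `a(0) = 0`, `a(1) = 1`, and `a ≥ u` for
negative `A`. Activation *dynamics* (the recursive-filter model) are
deliberately out of scope: their parameters are dominated by electrode
placement and skin condition, defeating the quick-setup goal.

**Muscle-tendon unit.** Stiff tendon, isometric (`f_v ≡ 1`), no
activation-dependent optimal length:

    F^mt = F_O [ f_l(l̃) a + f_P(l̃) ] cos φ,
    l̃ = l(θ)/l_o,   φ = arcsin(l_o sin φ_o / l),
    f_l(l̃) = exp(−(l̃ − 1)² / 2σ_A²),

with fiber length `l(θ)` and moment arm `r(θ)` cubic polynomials of the
driving joint angle and joint torque `τ^p = Σ_i F_i^mt r_i(θ)`
(flexion-positive; extensor moment arms negative; radians internally). The
passive curve is zero below optimal length and rises exponentially above,
normalised to 1 at `l̃ = 1.5` (`f_P = (e^{5(l̃−1)} − 1)/(e^{2.5} − 1)`); the
protocol never stretches fibers into that region, so it is shipped but
inert and never calibrated. The elbow model contains BB and TB driven by
elbow flexion θ2; the shoulder model contains BB, TB, AD and PD driven by
shoulder elevation θ1. The two joints are calibrated as independent models,
so the bi-articular BB/TB curves are reduced to each joint's own angle —
the simplest convention consistent with per-joint calibration.

**Default parameters.** `defaults.json` ships representative values
(maximal forces, optimal lengths, pennation angles, geometry cubics) with
plausible magnitudes for an adult male arm in the style of generic
upper-limb musculoskeletal models. They are the *normative starting point*
that calibration adjusts; no test uses them as ground truth.

**Gravity model.** Two sagittal-plane links:
`τ_el^g = M_fh l_2 g sin(θ1+θ2)` and
`τ_sh^g = (M_fh L_1 + M_a l_1) g sin θ1 + τ_el^g`, with θ1 measured from
the gravity vector so both torques vanish with the arm hanging. Segment
masses default to Winter-style fractions of body mass (arm 0.028,
forearm+hand 0.016 + 0.006), shipped as named, overridable constants;
centre-of-mass distances are half the segment lengths.

## Linear calibration (OLS)

Factoring `F_O` out of each muscle's contribution gives
`τ^e = Σ_i F_O^i A_i(t) − Σ_j f_j^sc τ'^g_j(t)` with regressors
`A_i = r_i (f_l a_i + f_P) cos φ_i` evaluated at the default geometry and
default `A = −0.2` (the linear route calibrates neither). The gravity
regressors are the *per-link mass contributions*: at the shoulder the
`M_a`-proportional term and the `M_fh`-proportional term (which includes
the elbow term), at the elbow the single `M_fh` term. This decomposition
spans the same space as scaling the two joint gravity torques but makes
each scale factor exactly a mass ratio (`f^sc ≈ 1` means the default mass
was right), so fitted factors fold directly back into the anthropometry
and every calibration method evaluates through one torque path. Shoulder:
6 coefficients; elbow: 3. Plain unconstrained least squares — the fitted
maximal forces or scale factors can come out negative on noisy,
ill-conditioned data; they are flagged with a warning but carried exactly,
because clamping them would break both OLS train-optimality and the exact
equivalence between the torque-model and regressor routes. Rank-deficient
designs raise, naming the collinear columns.

## GA calibration

Twelve parameters per muscle (`A, F_O, l_o, σ_A`, four fiber-length and
four moment-arm coefficients) plus the link masses: 50 genes for the
shoulder, 25 for the elbow. Bounds: `A ∈ [−3, 0)` (upper bound realised as
−10⁻⁶), `F_O ∈ F_O′·[0.7, 4]`, `σ_A ± 10%`, everything else ±30% of its
default; a default coefficient of exactly zero degenerates the ±% interval
and is widened to ±10⁻⁶ with a warning. The cost is the RMS error between
measured and predicted external torque over the training samples — the
same cost the linear route minimises; chromosomes whose decoded geometry
is invalid at a training pose (negative fiber length, arcsin domain) score
a 10⁶ penalty instead of raising, keeping the population size fixed.

The optimiser is a bounded real-coded GA: two populations of 10, tournament
selection (k = 2), BLX-0.5 crossover, per-gene Gaussian mutation (σ = 10%
of range, p = 0.1) with clipping to the box, one elite per population, and
best-individual migration every 10 generations. The default chromosome is
always included in the initial population. Stopping: best-cost improvement
≤ 10⁻⁵ N·m over 50 consecutive generations, or 500 generations. Every run
requires an explicit seed.

Two additions proved necessary once the estimation problem was studied on
synthetic ground truth:

* **Gauge fixing.** The data determine only the products `F_O·r(θ)` and the
  ratio `l(θ)/l_o`: jointly rescaling the moment-arm coefficients by λ and
  `F_O` by 1/λ (or `l_o` together with the fiber-length coefficients)
  changes no prediction. The reported chromosome is therefore the
  representative on each ridge closest to the normative defaults, clipped
  to the bounds — the calibrated *torque model* is unchanged (verified to
  machine precision), only the reported parameterisation is canonical.
* **Memetic polish.** The plain GA reliably stalls 2–4× above the
  attainable cost floor in 25/50-dimensional search spaces. A bounded
  L-BFGS-B descent in bound-normalised coordinates (raw genes span seven
  orders of magnitude) is run from the GA best, from its gauge-fixed image
  and from the default chromosome, keeping the lowest cost. The step only
  ever decreases the training cost; it can be disabled
  (`GAConfig(polish=False)`).

### Identifiability

With five poses, one driving angle per joint and a multiplicative model,
most of the 12 genes per muscle are weakly identified: parameter sets
differing by >40% in individual `F_O` values can sit within 0.02 N·m of
training cost on noiseless data. Recovery claims are therefore scoped:
maximal forces and masses are recovered to a few percent when the search
bounds are centred on the truth (drift resistance), and by the linear route
when the truth differs from the defaults only in linearly calibrated
parameters. Torque *prediction* quality does not suffer from the
degeneracy — that is the quantity the method exists to deliver.

## Synthetic protocol generator

Emulates the isometric-reaching study design: five sagittal-plane poses
spanning the workspace (θ1 from 0.35 to 1.15 rad, θ2 from 1.45 down to
0.40 rad), four end-effector force directions (±vertical, ±horizontal) at
15 N, two repetitions — 40 trials at 1200 Hz, plus four 10 s MVC
recordings (one per direction; each muscle reaches full activation in at
least one). Trial timing is 2 s rest, 2 s ramp, 2 s hold, 2 s release; the
study it emulates held targets only 0.2 s, but a longer hold gives the
estimators a stationary segment and costs nothing in simulation. Measured
torques come from the planar two-link Jacobian, `τ = Jᵀ F` (the planar
reduction of a 3-axis force sensor at the handle), plus Gaussian sensor
noise (default σ = 0.1 N·m).

Ground-truth subjects draw their parameters uniformly inside the GA search
bounds (`mode="full"`), or only the linearly calibrated ones
(`mode="linear"`); the activation shape factor of the bi-articular muscles
is shared between the two per-joint models because one EMG channel can
carry only one recruitment curve. Subjects whose muscles cannot balance
gravity plus the 15 N targets with activations in [0, 1] at every pose
(≈40% of unconstrained draws) are rejected and redrawn deterministically —
so accepted-subject marginals are uniform only for parameters outside the
feasibility screen, such as `A`.

Trial synthesis inverts the model chain. Required activations solve a
bounded least-distance problem (`M a = τ_g + s(t) τ_e`, `a ∈ [0, 1]`,
nearest a per-trial random co-contraction bias drawn from `[0, 0.1]`); the
balance is linear in `a`, so interpolating between the rest and peak
solutions satisfies it at every sample exactly. The co-contraction bias is
behavioural variability, not noise: without it the minimum-norm solution
makes every muscle's activation the same affine function of the force ramp
within a trial, and the shoulder OLS design becomes pathologically
collinear in a way real co-activation variability prevents. Excitation
follows from the analytic inverse of the activation map; the raw EMG is a
carrier amplitude-modulated by the excitation profile advanced by
`d + √2/ω_c` (the electromechanical delay plus the DC group delay of the
envelope low-pass), so the causal conditioning chain recovers it in phase.
The carrier is band-limited (20–450 Hz) Gaussian noise normalised to unit
rectified mean, with optional additive noise at a configurable amplitude
SNR (default 10); the noiseless mode uses a 151.3 Hz tone — chosen
incommensurate with the 1200 Hz sampling rate, since a commensurate tone
(e.g. 150 Hz = 8 samples/cycle) locks the sampled rectified mean to a
phase-dependent value and biases the envelope by several percent.

**What the generator does not emulate:** activation dynamics, fatigue,
electrode crosstalk and placement drift, non-Gaussian EMG statistics,
trial-to-trial pose error, 3-D shoulder kinematics, and real co-activation
strategies beyond the random bias. Passing recovery tests therefore show
the estimators are correct *given the model class*; they do not certify
performance on human data, where the model itself is misspecified.

## Evaluation

The two repetitions of each (pose, direction) cell are split one to
training, one to validation by a seeded fair coin (20/20). Metrics are the
RMS error `E_RMS` between measured and predicted external torque and the
coefficient of determination `R² = 1 − SS_res/SS_tot`, computed on the
concatenated samples of a trial set (per-trial-then-average is the other
convention; concatenation weights every sample equally and is what the
calibration cost uses). `R²` may be negative on validation; a
squared-correlation variant sits behind a flag. The three-condition
comparison (non-optimised defaults / linear / GA) checks fit provenance
against the split and raises on leakage. Cohort studies report
per-subject metrics and mean ± SD; the hypothesis-testing layer of a human
study (repeated-measures ANOVA and post-hoc machinery) is replaced by
descriptive statistics and a Wilcoxon signed-rank check in the test suite.

## Problem sizes and numerical choices

Calibration and evaluation decimate the conditioned signals to 25 Hz
(stride 48 at 1200 Hz): the envelope has no content above the 5 Hz corner,
so this is lossless for estimation while keeping a GA cost evaluation
under a millisecond (~3 800 training samples). Cohort studies in the test
suite and acceptance script use 7 subjects with full GA calibration of
both joints; recovery checks use single subjects. The stacked
least-distance activation solver weights the torque-balance rows by 10⁴
and verifies the residual to 10⁻⁴·(1+|τ|), raising an infeasibility error
otherwise. OLS rank checks use the singular-value ratio at 10⁻¹².
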