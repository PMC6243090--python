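"""Synthetic subjects and isometric-reaching datasets.

The experimental protocol this module emulates: the arm is held at five
sagittal-plane poses; at each pose the subject produces an isometric
end-effector force of 15 N in four directions (up, down, front, rear),
twice each — 40 trials.  The measured external joint torques come from the
end-effector force through the planar two-link positional Jacobian,
tau = J^T F.  MVC recordings (maximum contraction held for 10 s, one per
force direction) provide the EMG normalisation reference.

A synthetic subject owns ground-truth per-joint models (parameters drawn
uniformly within the GA search bounds around the shipped defaults) and
anthropometry.  Trial synthesis inverts the model chain: the required
muscle activations are distributed by minimum sum of squared activations
subject to the torque balance tau_h = tau_g + tau_e and the box a in
[0, 1]; the excitation follows from the analytic inverse of the activation
nonlinearity; and the raw EMG is a carrier (band-limited noise, or a pure
tone in noiseless mode) amplitude-modulated by the excitation profile
advanced by the electromechanical delay.  The measured torque is the exact
Jacobian torque plus Gaussian sensor noise.

Because calibration only ever sees (EMG, angles, measured torque), any
internally consistent generator convention is admissible; ground truth is
kept separate from the fit inputs to prevent leakage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps
from scipy.optimize import lsq_linear

from .data import DIRECTIONS, Dataset, Trial
from .emg import EmgConfig, RawEmg, inverse_activation, lp_group_delay_s
from .ga import chromosome_length, decode, encode, make_bounds
from .gravity import ArmAnthropometry, default_masses, gravity_torques
from .muscle import JointModel, default_models

__all__ = [
    "NoiseConfig",
    "TrialTiming",
    "SyntheticSubject",
    "sample_subject",
    "poses_and_targets",
    "ee_force_to_joint_torque",
    "synthesize_trial",
    "synthesize_mvc_recordings",
    "synthesize_dataset",
    "InfeasibleTorqueError",
]

FORCE_TARGET_N = 15.0
#: Unit force directions in the sagittal plane (x forward, z up).
DIRECTION_VECTORS = {
    "up": np.array([0.0, 1.0]),
    "down": np.array([0.0, -1.0]),
    "front": np.array([1.0, 0.0]),
    "rear": np.array([-1.0, 0.0]),
}
#: Five (theta1, theta2) poses spanning the sagittal reachable workspace,
#: from a low near-chest configuration to a high forward reach.
PROTOCOL_POSES = (
    (0.35, 1.45),
    (0.55, 1.15),
    (0.75, 0.85),
    (0.95, 0.60),
    (1.15, 0.40),
)
_EMG_GAIN_V = 1e-3  # volts per unit of normalised envelope
# Deterministic-carrier tone frequency: incommensurate with the 1200 Hz
# sampling rate so the sampled rectified mean converges to 2/pi instead of
# locking to a phase-dependent value (8 samples/cycle at 150 Hz would bias
# the envelope by several percent).
_CARRIER_HZ = 151.3


class InfeasibleTorqueError(ValueError):
    """The required joint torques cannot be produced with activations in
    [0, 1] under the subject's true models."""


@dataclass(frozen=True)
class NoiseConfig:
    """Measurement-noise settings of the generator.

    emg_snr : amplitude SNR of the modulated EMG against additive
        broadband noise; ``inf`` plus ``carrier="sine"`` gives the
        noiseless (deterministic) mode used by recovery tests.
    torque_sd : Gaussian torque-sensor noise s.d. (N*m) per sample.
    carrier : "noise" for a band-limited stochastic carrier, "sine" for a
        deterministic tone whose rectified mean is analytically known.
    co_contraction : amplitude of the per-trial random co-activation bias
        (activation units).  Muscle redundancy lets the same torques be
        produced with varying antagonist co-contraction; real subjects
        vary it trial to trial, which is what makes the per-muscle
        regressors separable across trials.  Behavioural variability, not
        sensor noise, so it is kept in the noiseless mode.
    """

    emg_snr: float = 10.0
    torque_sd: float = 0.1
    carrier: str = "noise"
    co_contraction: float = 0.1

    @classmethod
    def noiseless(cls) -> "NoiseConfig":
        return cls(emg_snr=math.inf, torque_sd=0.0, carrier="sine")


@dataclass(frozen=True)
class TrialTiming:
    """Trial phases (s): rest, force ramp up, hold at target, release.

    The protocol's rest is 2 s; the hold is stretched to 2 s (the human
    task required only 0.2 s in target) for estimation stability.
    """

    rest_s: float = 2.0
    ramp_s: float = 2.0
    hold_s: float = 2.0
    release_s: float = 2.0

    @property
    def total_s(self) -> float:
        return self.rest_s + self.ramp_s + self.hold_s + self.release_s

    def profile(self, fs: float) -> np.ndarray:
        """Force-magnitude profile s(t) in [0, 1]."""
        n = lambda s: int(round(s * fs))
        return np.concatenate(
            [
                np.zeros(n(self.rest_s)),
                np.linspace(0.0, 1.0, n(self.ramp_s), endpoint=False),
                np.ones(n(self.hold_s)),
                np.linspace(1.0, 0.0, n(self.release_s), endpoint=False),
            ]
        )


@dataclass(frozen=True)
class SyntheticSubject:
    """Ground truth for one simulated subject."""

    subject_id: int
    true_model_elbow: JointModel
    true_model_shoulder: JointModel
    true_anthro: ArmAnthropometry
    body_mass: float
    noise: NoiseConfig = field(default_factory=NoiseConfig)

    @property
    def channel_names(self) -> tuple[str, ...]:
        return self.true_model_shoulder.muscle_names


def sample_subject(
    seed: int,
    mode: str = "full",
    noise: NoiseConfig | None = None,
    body_mass: float = 70.0,
    max_draws: int = 50,
) -> SyntheticSubject:
    """Draw a synthetic subject with true parameters inside the GA bounds.

    mode : "full" draws every calibrated parameter (12 per muscle plus the
        link masses) uniformly within its search bound; "linear" perturbs
        only the parameters the linear method calibrates (F_O and masses),
        leaving activation shape and geometry at their defaults.

    Subjects whose muscles cannot balance gravity plus the 15 N protocol
    forces at every pose (activations would exceed 1) are rejected and
    redrawn deterministically from the seed's stream.
    """
    if mode not in ("full", "linear"):
        raise ValueError("mode must be 'full' or 'linear'")
    noise = noise or NoiseConfig()
    default, default_anthro = default_models()
    M_a0, M_fh0 = default_masses(body_mass)
    base_anthro = default_anthro.with_masses(M_a=M_a0, M_fh=M_fh0)
    rng = np.random.default_rng(seed)
    for _ in range(max_draws):
        models = {}
        shared_A: dict[str, float] = {}
        anthro = base_anthro
        for joint in ("elbow", "shoulder"):
            template = default[joint]
            bounds = make_bounds(template, base_anthro)
            genes = bounds.lower + (bounds.upper - bounds.lower) * rng.random(
                bounds.n_genes
            )
            if mode == "linear":
                base = encode(template, base_anthro)
                keep = np.ones(bounds.n_genes, dtype=bool)
                for i, name in enumerate(bounds.names):
                    if name.endswith(".F_O") or name in ("M_a", "M_fh"):
                        keep[i] = False
                genes[keep] = base[keep]
            model, anthro_joint = decode(genes, template, anthro)
            # one EMG channel per muscle: share the u->a shape factor of
            # muscles that appear in both joint models
            fixed = []
            for m in model.muscles:
                if m.name in shared_A:
                    m = replace(m, A=shared_A[m.name])
                else:
                    shared_A[m.name] = m.A
                fixed.append(m)
            models[joint] = replace(model, muscles=tuple(fixed))
            if joint == "elbow":
                anthro = anthro.with_masses(M_fh=anthro_joint.M_fh)
            else:
                anthro = anthro.with_masses(
                    M_a=anthro_joint.M_a, M_fh=anthro_joint.M_fh
                )
        subject = SyntheticSubject(
            subject_id=seed,
            true_model_elbow=models["elbow"],
            true_model_shoulder=models["shoulder"],
            true_anthro=anthro,
            body_mass=body_mass,
            noise=noise,
        )
        if _subject_feasible(subject):
            return subject
    raise InfeasibleTorqueError(
        f"no feasible subject found in {max_draws} draws from seed {seed}"
    )


def poses_and_targets(anthro: ArmAnthropometry):
    """Protocol poses and force targets.

    Returns a list of (pose_id, theta1, theta2, {direction: force 2-vector}).
    Forces have magnitude 15 N; opposite directions cancel.
    """
    out = []
    for pid, (th1, th2) in enumerate(PROTOCOL_POSES, start=1):
        if not (0.0 <= th1 <= np.pi / 2 + 0.2) or not (0.0 <= th2 <= 2.6):
            raise ValueError(f"pose {pid} outside joint limits")
        forces = {d: FORCE_TARGET_N * v for d, v in DIRECTION_VECTORS.items()}
        out.append((pid, th1, th2, forces))
    return out


def hand_position(anthro: ArmAnthropometry, theta1: float, theta2: float):
    """Planar forward kinematics of the handle (x forward, z up), shoulder
    at the origin; theta1 measured from the downward vertical."""
    x = anthro.L_1 * np.sin(theta1) + anthro.L_2 * np.sin(theta1 + theta2)
    z = -anthro.L_1 * np.cos(theta1) - anthro.L_2 * np.cos(theta1 + theta2)
    return np.array([x, z])


def ee_force_to_joint_torque(
    force: np.ndarray, theta1: float, theta2: float, anthro: ArmAnthropometry
) -> tuple[float, float]:
    """(tau_sh, tau_el) = J^T F with the planar two-link positional Jacobian.

    This is how the measured torque is derived from the end-effector force
    sensor.  Flexion-positive at both joints.
    """
    L1, L2 = anthro.L_1, anthro.L_2
    c1, s1 = np.cos(theta1), np.sin(theta1)
    c12, s12 = np.cos(theta1 + theta2), np.sin(theta1 + theta2)
    J = np.array(
        [
            [L1 * c1 + L2 * c12, L2 * c12],  # dx/dtheta
            [L1 * s1 + L2 * s12, L2 * s12],  # dz/dtheta
        ]
    )
    if abs(np.linalg.det(J)) < 1e-6:
        import warnings

        warnings.warn("near-singular pose: torque mapping ill-conditioned", stacklevel=2)
    tau = J.T @ np.asarray(force, dtype=float)
    return float(tau[0]), float(tau[1])


# -- activation distribution -------------------------------------------------


def _capacity_matrix(subject: SyntheticSubject, theta1: float, theta2: float):
    """(M, passive): torque balance M a + passive = tau_h at this pose.

    Rows are (shoulder, elbow); columns follow the subject's channel order.
    M[j, i] is muscle i's torque per unit activation in joint j's model;
    muscles absent from a joint model contribute zero.
    """
    channels = subject.channel_names
    M = np.zeros((2, len(channels)))
    passive = np.zeros(2)
    for row, (model, theta) in enumerate(
        ((subject.true_model_shoulder, theta1), (subject.true_model_elbow, theta2))
    ):
        for mtu in model.muscles:
            i = channels.index(mtu.name)
            # slope of torque in a: F_O * r * f_l * cos(phi)
            M[row, i] = mtu.F_O * (
                mtu.unit_force_torque(1.0, theta) - mtu.unit_force_torque(0.0, theta)
            )
            passive[row] += mtu.F_O * float(mtu.unit_force_torque(0.0, theta))
    return M, passive


def _solve_activations(
    M: np.ndarray, tau_h: np.ndarray, a_bias: np.ndarray | float = 0.0
) -> np.ndarray:
    """Activation vector nearest ``a_bias`` with M a = tau_h and a in [0, 1].

    ``a_bias = 0`` gives the minimum-norm distribution; a positive bias
    adds torque-free co-contraction.  Solved as a heavily weighted stacked
    least-squares problem with box bounds; infeasible torques leave a
    residual and raise.
    """
    w = 1e4
    n = M.shape[1]
    X = np.vstack([w * M, np.eye(n)])
    y = np.concatenate([w * tau_h, np.broadcast_to(a_bias, (n,))])
    res = lsq_linear(X, y, bounds=(0.0, 1.0), tol=1e-14)
    err = np.abs(M @ res.x - tau_h)
    if np.any(err > 1e-4 * (1.0 + np.abs(tau_h))):
        raise InfeasibleTorqueError(
            f"required torques {tau_h} infeasible with activations in [0, 1]"
        )
    return res.x


def _subject_feasible(subject: SyntheticSubject) -> bool:
    try:
        for _, th1, th2, forces in poses_and_targets(subject.true_anthro):
            tau_g = np.array(gravity_torques(subject.true_anthro, th1, th2))
            M, passive = _capacity_matrix(subject, th1, th2)
            _solve_activations(M, tau_g - passive)
            for f in forces.values():
                tau_e = np.array(ee_force_to_joint_torque(f, th1, th2, subject.true_anthro))
                _solve_activations(M, tau_g + tau_e - passive)
    except InfeasibleTorqueError:
        return False
    return True


# -- EMG synthesis -----------------------------------------------------------


def _carrier(n: int, fs: float, rng: np.random.Generator, kind: str,
             phase: float = 0.0) -> np.ndarray:
    """Unit-rectified-mean carrier: E|c| = 1 so that the linear envelope of
    c(t) m(t) tracks m(t)."""
    if kind == "sine":
        t = np.arange(n) / fs
        return (np.pi / 2.0) * np.sin(2.0 * np.pi * _CARRIER_HZ * t + phase)
    x = rng.standard_normal(n + int(fs))  # pad for filter settling
    sos = sps.butter(4, [20.0, min(450.0, 0.45 * fs)], btype="bandpass", fs=fs,
                     output="sos")
    x = sps.sosfilt(sos, x)[int(fs):][:n]
    return x / np.mean(np.abs(x))


def _modulated_emg(
    m: np.ndarray,
    fs: float,
    rng: np.random.Generator,
    noise: NoiseConfig,
    phase: float,
) -> np.ndarray:
    """Raw EMG (volts) whose linear envelope tracks the profile m(t)."""
    c = _carrier(m.size, fs, rng, noise.carrier, phase)
    signal = c * m
    if np.isfinite(noise.emg_snr):
        sig_rms = np.sqrt(np.mean(signal**2)) or 1.0
        extra = _carrier(m.size, fs, rng, "noise")
        signal = signal + extra * sig_rms / noise.emg_snr
    return _EMG_GAIN_V * signal


def _advance(x: np.ndarray, dt_s: float, fs: float) -> np.ndarray:
    """x(t + dt) with trailing-edge hold (used to pre-compensate the
    electromechanical delay and the envelope filter's group delay)."""
    n = x.size
    t = np.arange(n) / fs
    return np.interp(t + dt_s, t, x)


def synthesize_trial(
    subject: SyntheticSubject,
    pose_id: int,
    theta1: float,
    theta2: float,
    direction: str,
    repetition: int,
    seed: int,
    fs: float = 1200.0,
    timing: TrialTiming = TrialTiming(),
    config: EmgConfig = EmgConfig(),
) -> Trial:
    """Synthesise one isometric trial by inverting the model chain.

    The ramp profile scales the external torque between rest (gravity
    only) and the full 15 N target; activations at the two endpoints are
    distributed by bounded minimum-norm least squares and interpolated
    (the torque balance is linear in the activations, so the interpolated
    profile satisfies it exactly at every sample).
    """
    rng = np.random.default_rng(seed)
    force = FORCE_TARGET_N * DIRECTION_VECTORS[direction]
    tau_e = np.array(ee_force_to_joint_torque(force, theta1, theta2, subject.true_anthro))
    tau_g = np.array(gravity_torques(subject.true_anthro, theta1, theta2))
    M, passive = _capacity_matrix(subject, theta1, theta2)
    a_bias = rng.uniform(0.0, subject.noise.co_contraction, M.shape[1])
    a_rest = _solve_activations(M, tau_g - passive, a_bias)
    a_peak = _solve_activations(M, tau_g + tau_e - passive, a_bias)

    s = timing.profile(fs)
    n = s.size
    a = a_rest[None, :] + s[:, None] * (a_peak - a_rest)[None, :]

    channels = subject.channel_names
    A_by_channel = {m.name: m.A for m in subject.true_model_shoulder.muscles}
    advance_s = config.delay_s + lp_group_delay_s(config)
    emg = np.empty((n, len(channels)))
    for i, name in enumerate(channels):
        u = np.asarray(inverse_activation(a[:, i], A_by_channel[name]))
        profile = _advance(u, advance_s, fs)
        emg[:, i] = _modulated_emg(
            profile, fs, rng, subject.noise, phase=rng.uniform(0, 2 * np.pi)
        )

    tau_e_t = s[:, None] * tau_e[None, :]
    if subject.noise.torque_sd > 0:
        tau_e_t = tau_e_t + rng.normal(0.0, subject.noise.torque_sd, tau_e_t.shape)
    return Trial(
        pose_id=pose_id,
        direction=direction,
        repetition=repetition,
        theta1=theta1,
        theta2=theta2,
        fs=fs,
        emg=emg,
        tau_m_sh=tau_e_t[:, 0],
        tau_m_el=tau_e_t[:, 1],
        force=force,
    )


def synthesize_mvc_recordings(
    subject: SyntheticSubject,
    seed: int,
    fs: float = 1200.0,
    plateau_s: float = 10.0,
    config: EmgConfig = EmgConfig(),
) -> list[RawEmg]:
    """Four MVC recordings (one per force direction), each a 10 s maximal
    plateau.  Each direction drives its agonists to full activation; the
    per-channel maximum across directions is the normalisation reference,
    and every muscle reaches a = 1 in at least one direction."""
    rng = np.random.default_rng(seed)
    n_lead = int(fs)  # 1 s ramp-in
    n_plat = int(plateau_s * fs)
    agonists = {
        "up": ("BB", "AD"),
        "down": ("TB", "PD"),
        "front": ("AD", "BB"),
        "rear": ("PD", "TB"),
    }
    recordings = []
    channels = subject.channel_names
    for direction in DIRECTIONS:
        m = np.concatenate([np.linspace(0, 1, n_lead), np.ones(n_plat)])
        emg = np.empty((m.size, len(channels)))
        for i, name in enumerate(channels):
            level = m if name in agonists[direction] else 0.15 * m
            emg[:, i] = _modulated_emg(
                level, fs, rng, subject.noise, phase=rng.uniform(0, 2 * np.pi)
            )
        recordings.append(RawEmg(emg, fs=fs, channel_names=channels))
    return recordings


def synthesize_dataset(
    subject: SyntheticSubject,
    seed: int,
    fs: float = 1200.0,
    timing: TrialTiming = TrialTiming(),
    config: EmgConfig = EmgConfig(),
) -> Dataset:
    """The full 40-trial protocol plus MVC recordings for one subject."""
    rng = np.random.default_rng(seed)
    trials = []
    for pid, th1, th2, _forces in poses_and_targets(subject.true_anthro):
        for direction in DIRECTIONS:
            for rep in (1, 2):
                trials.append(
                    synthesize_trial(
                        subject, pid, th1, th2, direction, rep,
                        seed=int(rng.integers(0, 2**31 - 1)),
                        fs=fs, timing=timing, config=config,
                    )
                )
    mvc = synthesize_mvc_recordings(subject, seed=int(rng.integers(0, 2**31 - 1)),
                                    fs=fs, config=config)
    return Dataset(
        trials=tuple(trials),
        channel_names=subject.channel_names,
        fs=fs,
        mvc_recordings=tuple(mvc),
        body_mass=subject.body_mass,
        meta={"subject_id": subject.subject_id, "noise": subject.noise.__dict__.copy()},
    )
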