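"""Trial/dataset containers and calibration design preparation.

A ``Trial`` is one isometric reaching contraction: the arm is held at a
fixed sagittal-plane pose (theta1, theta2) while the subject ramps an
end-effector force up to a 15 N target and back; raw 4-channel EMG and the
measured external joint torques are recorded synchronously.  A ``Dataset``
is the full protocol — 5 poses x 4 force directions x 2 repetitions = 40
trials — plus the MVC recordings needed for EMG normalisation.

``build_design`` runs the EMG conditioning chain once and assembles the
per-sample arrays (excitations, angles, measured torques) that both the
linear and GA calibrations, and the evaluation metrics, consume.  Filter
start-up transients are excluded, and samples are decimated: the envelope
carries no content above the 5 Hz low-pass corner, so a stride of 48 at
1200 Hz (25 Hz effective) loses nothing while keeping optimisation cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .emg import EmgConfig, RawEmg, apply_delay, compute_mvc, preprocess_emg

__all__ = ["Trial", "Dataset", "Design", "build_design"]

DIRECTIONS = ("up", "down", "front", "rear")


@dataclass(frozen=True)
class Trial:
    """One isometric contraction at a fixed arm pose."""

    pose_id: int
    direction: str
    repetition: int
    theta1: float           # shoulder elevation, rad (constant; isometric)
    theta2: float           # elbow flexion, rad
    fs: float
    emg: np.ndarray         # (n_samples, 4) raw EMG, volts
    tau_m_sh: np.ndarray    # measured external shoulder torque, N*m
    tau_m_el: np.ndarray    # measured external elbow torque, N*m
    force: np.ndarray       # (2,) peak end-effector force (x forward, z up), N

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        n = self.emg.shape[0]
        if not (len(self.tau_m_sh) == len(self.tau_m_el) == n):
            raise ValueError("EMG and torque series must share one time base")

    @property
    def trial_id(self) -> str:
        return f"p{self.pose_id}-{self.direction}-r{self.repetition}"

    @property
    def n_samples(self) -> int:
        return self.emg.shape[0]


@dataclass(frozen=True)
class Dataset:
    """Full isometric-reaching protocol for one subject."""

    trials: tuple[Trial, ...]
    channel_names: tuple[str, ...]
    fs: float
    mvc_recordings: tuple[RawEmg, ...]
    body_mass: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "trials", tuple(self.trials))
        object.__setattr__(self, "mvc_recordings", tuple(self.mvc_recordings))

    def trial_ids(self) -> tuple[str, ...]:
        return tuple(t.trial_id for t in self.trials)

    def get_trial(self, trial_id: str) -> Trial:
        for t in self.trials:
            if t.trial_id == trial_id:
                return t
        raise KeyError(trial_id)

    def validate_protocol(self) -> None:
        """Check the 5 poses x 4 directions x 2 repetitions structure."""
        seen: dict[tuple[int, str], int] = {}
        for t in self.trials:
            seen[(t.pose_id, t.direction)] = seen.get((t.pose_id, t.direction), 0) + 1
        if len(self.trials) != 40 or any(v != 2 for v in seen.values()):
            raise ValueError("protocol requires 2 repetitions of each (pose, direction)")


@dataclass(frozen=True)
class Design:
    """Per-sample calibration arrays over a set of trials.

    u : (n, 4) delayed excitations per muscle channel.
    theta1 / theta2 : (n,) joint angles (constant within a trial).
    tau_m_sh / tau_m_el : (n,) measured external torques.
    trial_index : (n,) integer index into trial_ids.
    """

    u: np.ndarray
    theta1: np.ndarray
    theta2: np.ndarray
    tau_m_sh: np.ndarray
    tau_m_el: np.ndarray
    trial_index: np.ndarray
    trial_ids: tuple[str, ...]
    channel_names: tuple[str, ...]
    fs_effective: float

    @property
    def n_samples(self) -> int:
        return self.u.shape[0]

    def tau_m(self, joint: str) -> np.ndarray:
        return self.tau_m_sh if joint == "shoulder" else self.tau_m_el

    def theta(self, joint: str) -> np.ndarray:
        """Driving angle of the given joint model."""
        return self.theta1 if joint == "shoulder" else self.theta2

    def channel_index(self, name: str) -> int:
        return self.channel_names.index(name)


def build_design(
    dataset: Dataset,
    trial_ids: tuple[str, ...] | None = None,
    config: EmgConfig = EmgConfig(),
    decimate: int = 48,
    mvc: np.ndarray | None = None,
) -> Design:
    """Condition the EMG and assemble calibration arrays for ``trial_ids``.

    The chain per trial: envelope extraction with MVC normalisation,
    electromechanical delay, exclusion of the filter transient, then
    decimation by stride.  ``mvc`` may be passed to reuse a precomputed
    reference.
    """
    if trial_ids is None:
        trial_ids = dataset.trial_ids()
    if mvc is None:
        mvc = compute_mvc(list(dataset.mvc_recordings), config)
    u_parts, th1_parts, th2_parts = [], [], []
    tsh_parts, tel_parts, idx_parts = [], [], []
    for k, tid in enumerate(trial_ids):
        trial = dataset.get_trial(tid)
        raw = RawEmg(trial.emg, fs=trial.fs, channel_names=dataset.channel_names)
        exc = preprocess_emg(raw, mvc, config)
        u = apply_delay(exc, config.delay_s)
        keep = u.valid_mask()
        sel = np.flatnonzero(keep)[::decimate]
        n = sel.size
        u_parts.append(u.e[sel])
        th1_parts.append(np.full(n, trial.theta1))
        th2_parts.append(np.full(n, trial.theta2))
        tsh_parts.append(trial.tau_m_sh[sel])
        tel_parts.append(trial.tau_m_el[sel])
        idx_parts.append(np.full(n, k, dtype=int))
    return Design(
        u=np.concatenate(u_parts, axis=0),
        theta1=np.concatenate(th1_parts),
        theta2=np.concatenate(th2_parts),
        tau_m_sh=np.concatenate(tsh_parts),
        tau_m_el=np.concatenate(tel_parts),
        trial_index=np.concatenate(idx_parts),
        trial_ids=tuple(trial_ids),
        channel_names=dataset.channel_names,
        fs_effective=dataset.fs / decimate,
    )
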