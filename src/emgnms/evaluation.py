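"""Train/validation splitting, torque-prediction metrics, and the
three-condition comparison (non-optimised / linear / GA).

The protocol records two repetitions of every (pose, direction) cell; the
split assigns, per cell, one repetition to the training set and the other
to validation by a seeded fair coin, giving 20 trials a side.  Performance
is reported as the RMS error

    E_RMS = sqrt( mean_k [ tau^m_k - (tau^p_k - tau^g_k) ]^2 )

and the coefficient of determination R^2 = 1 - SS_res/SS_tot between the
measured external torque and the model's external-torque prediction,
computed on the concatenated samples of a trial set (transients excluded).
R^2 can be negative on validation data; a squared-correlation variant is
available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import Dataset, Design, build_design
from .emg import EmgConfig, activation
from .gravity import ArmAnthropometry, gravity_torques
from .muscle import JointModel
from .results import FitResult

__all__ = [
    "SplitPlan",
    "split_dataset",
    "e_rms",
    "r_squared",
    "predict_external_torque",
    "evaluate_model",
    "PerformanceReport",
    "compare_conditions",
]

CONDITIONS = ("non-optimized", "linear", "ga")


@dataclass(frozen=True)
class SplitPlan:
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.val_ids):
            raise ValueError("train and validation sets overlap")


def split_dataset(dataset: Dataset, seed: int) -> SplitPlan:
    """One repetition per (pose, direction) to each side, by seeded coin."""
    rng = np.random.default_rng(seed)
    cells: dict[tuple[int, str], list[str]] = {}
    for t in dataset.trials:
        cells.setdefault((t.pose_id, t.direction), []).append(t.trial_id)
    train, val = [], []
    for key in sorted(cells):
        reps = cells[key]
        if len(reps) != 2:
            raise ValueError(f"(pose, direction) {key} has {len(reps)} repetitions, need 2")
        first_to_train = bool(rng.integers(0, 2))
        a, b = reps if first_to_train else reps[::-1]
        train.append(a)
        val.append(b)
    return SplitPlan(tuple(train), tuple(val))


def e_rms(tau_m: np.ndarray, tau_pred_external: np.ndarray) -> float:
    """RMS torque error (N*m) between measurement and external prediction."""
    tau_m = np.asarray(tau_m, dtype=float)
    tau_p = np.asarray(tau_pred_external, dtype=float)
    if tau_m.shape != tau_p.shape:
        raise ValueError("series lengths differ")
    if tau_m.size == 0:
        raise ValueError("empty series")
    return float(np.sqrt(np.mean((tau_m - tau_p) ** 2)))


def r_squared(
    tau_m: np.ndarray, tau_pred_external: np.ndarray, squared_correlation: bool = False
) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot (default), or the
    squared Pearson correlation when ``squared_correlation`` is set."""
    tau_m = np.asarray(tau_m, dtype=float)
    tau_p = np.asarray(tau_pred_external, dtype=float)
    if tau_m.shape != tau_p.shape:
        raise ValueError("series lengths differ")
    ss_tot = float(np.sum((tau_m - tau_m.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("constant measured torque: R^2 undefined", stacklevel=2)
        return float("nan")
    if squared_correlation:
        return float(np.corrcoef(tau_m, tau_p)[0, 1] ** 2)
    return 1.0 - float(np.sum((tau_m - tau_p) ** 2)) / ss_tot


def predict_external_torque(
    model: JointModel, anthro: ArmAnthropometry, design: Design
) -> np.ndarray:
    """Model's external torque tau^p - tau^g over the design samples."""
    theta = design.theta(model.joint)
    acts = np.column_stack(
        [
            activation(design.u[:, design.channel_index(m.name)], m.A)
            for m in model.muscles
        ]
    )
    tau_p = model.predict_torque(acts, theta)
    tau_sh_g, tau_el_g = gravity_torques(anthro, design.theta1, design.theta2)
    tau_g = tau_sh_g if model.joint == "shoulder" else tau_el_g
    return tau_p - tau_g


def evaluate_model(
    model: JointModel, anthro: ArmAnthropometry, design: Design
) -> dict:
    """E_RMS and R^2 of the external-torque prediction on a design."""
    pred = predict_external_torque(model, anthro, design)
    tau_m = design.tau_m(model.joint)
    return {"e_rms": e_rms(tau_m, pred), "r2": r_squared(tau_m, pred)}


@dataclass(frozen=True)
class PerformanceReport:
    """Metrics per (joint, condition, split) for one subject.

    entries : dict mapping (joint, condition, split) -> {"e_rms", "r2"}.
    """

    entries: dict

    def get(self, joint: str, condition: str, split: str = "validation") -> dict:
        return self.entries[(joint, condition, split)]

    def to_records(self) -> list[dict]:
        return [
            {"joint": j, "condition": c, "split": s, **metrics}
            for (j, c, s), metrics in sorted(self.entries.items())
        ]


def _check_leakage(fit: FitResult, split: SplitPlan) -> None:
    leaked = set(fit.train_trial_ids) & set(split.val_ids)
    if leaked:
        raise ValueError(
            f"{fit.method} fit for {fit.joint} was trained on validation trials: "
            f"{sorted(leaked)}"
        )


def compare_conditions(
    dataset: Dataset,
    split: SplitPlan,
    default_models: dict[str, JointModel],
    default_anthro: ArmAnthropometry,
    lo_fits: dict[str, FitResult],
    ga_fits: dict[str, FitResult],
    config: EmgConfig = EmgConfig(),
    decimate: int = 48,
) -> PerformanceReport:
    """Three-condition comparison on the train and validation splits.

    ``lo_fits`` / ``ga_fits`` map joint name to the FitResult produced on
    the training split; training on validation trials raises.
    """
    designs = {
        "train": build_design(dataset, split.train_ids, config, decimate),
        "validation": build_design(dataset, split.val_ids, config, decimate),
    }
    entries: dict = {}
    for joint, default_model in default_models.items():
        conditions = {
            "non-optimized": (default_model, default_anthro),
        }
        for name, fits in (("linear", lo_fits), ("ga", ga_fits)):
            if joint in fits:
                _check_leakage(fits[joint], split)
                conditions[name] = (fits[joint].model, fits[joint].anthro)
        for cond, (model, anthro) in conditions.items():
            for split_name, design in designs.items():
                entries[(joint, cond, split_name)] = evaluate_model(model, anthro, design)
    return PerformanceReport(entries)
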