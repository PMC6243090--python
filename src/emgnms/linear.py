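"""Linear-in-parameters subject calibration by ordinary least squares.

Factoring the maximum isometric force out of each muscle's torque
contribution makes the external-torque model linear in the calibrated
parameters:

    tau^e(t) = sum_i F_O^i A_i(t) - sum_j f_j^sc tau'^g_j(t),
    A_i(t)   = r_i(theta) [ f_l(l~) a_i(t) + f_P(l~) ] cos(phi_i),

where ``A_i`` is the unit-force torque regressor of muscle i evaluated at
the default (non-optimised) geometry and activation shape, ``tau'^g_j``
the per-link gravity contribution under the default masses, and ``f_j^sc``
a scale factor that adjusts the j-th link mass (f ~ 1 means the default
mass was right).  With the measured external torque as the target this is
ordinary least squares: 6 coefficients for the shoulder (4 forces + 2 mass
scales), 3 for the elbow (2 forces + 1 mass scale).

No sign constraint is imposed; a negative fitted maximal force is
physiologically invalid and raised as a warning, not an error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import Design
from .emg import activation
from .gravity import ArmAnthropometry, gravity_components
from .muscle import JointModel
from .results import FitResult

__all__ = ["RegressorMatrix", "LinearFit", "build_regressors", "fit_linear",
           "calibrate_linear"]


@dataclass(frozen=True)
class RegressorMatrix:
    """Design matrix of the linear reformulation for one joint."""

    A_cols: np.ndarray          # (n, n_muscles) unit-force torque regressors
    G_cols: np.ndarray          # (n, n_links) default per-link gravity series
    target: np.ndarray          # (n,) measured external torque tau^e = tau^m
    muscle_names: tuple[str, ...]
    gravity_names: tuple[str, ...]
    joint: str
    trial_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        n = self.target.shape[0]
        if self.A_cols.shape[0] != n or self.G_cols.shape[0] != n:
            raise ValueError("regressor columns and target must share one length")
        if np.isnan(self.A_cols).any() or np.isnan(self.G_cols).any() \
                or np.isnan(self.target).any():
            raise ValueError("regressors contain NaN")

    @property
    def matrix(self) -> np.ndarray:
        """Stacked [A_cols, -G_cols] matrix whose coefficients are
        (F_O per muscle, f_sc per link)."""
        return np.hstack([self.A_cols, -self.G_cols])


@dataclass(frozen=True)
class LinearFit:
    F_O_hat: np.ndarray         # per-muscle maximal forces, N
    f_sc_hat: np.ndarray        # per-link gravity (mass) scale factors
    residual_rms: float         # N*m on the training samples
    condition_number: float
    muscle_names: tuple[str, ...]
    gravity_names: tuple[str, ...]


def build_regressors(
    model: JointModel,
    anthro: ArmAnthropometry,
    design: Design,
) -> RegressorMatrix:
    """Assemble the OLS design for ``model``'s joint from conditioned data.

    Muscle regressors use the default activation shape factor of each MTU
    (the linear method does not calibrate A) and are invariant to the
    default F_O values, which are factored out.  Gravity columns are the
    per-link contributions under the default masses, one per calibrated
    link mass: (arm, forearm+hand) at the shoulder, (forearm+hand,) at the
    elbow.
    """
    theta = design.theta(model.joint)
    cols = []
    for mtu in model.muscles:
        try:
            ci = design.channel_index(mtu.name)
        except ValueError as exc:
            raise ValueError(f"EMG channel {mtu.name!r} missing from design") from exc
        a = activation(design.u[:, ci], mtu.A)
        cols.append(mtu.unit_force_torque(a, theta))
    comp = gravity_components(anthro, design.theta1, design.theta2)
    if model.joint == "shoulder":
        G = np.column_stack([comp["shoulder_a"], comp["shoulder_fh"]])
        g_names = ("M_a", "M_fh")
    else:
        G = comp["elbow_fh"][:, None]
        g_names = ("M_fh",)
    return RegressorMatrix(
        A_cols=np.column_stack(cols),
        G_cols=G,
        target=np.asarray(design.tau_m(model.joint), dtype=float),
        muscle_names=model.muscle_names,
        gravity_names=g_names,
        joint=model.joint,
        trial_ids=design.trial_ids,
    )


def fit_linear(reg: RegressorMatrix) -> LinearFit:
    """Ordinary least squares on the linear reformulation.

    Minimises the same RMS-torque cost as the GA over the training samples.
    An all-zero target returns the minimum-norm (all-zero) solution.  Rank
    deficiency raises, naming the collinear columns.
    """
    X = reg.matrix
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more samples ({n}) than parameters ({p})")
    names = reg.muscle_names + tuple(f"f_sc[{g}]" for g in reg.gravity_names)
    sv = np.linalg.svd(X, compute_uv=False)
    if sv[0] == 0.0 or sv[-1] / sv[0] < 1e-12:
        corr = np.corrcoef(X, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise ValueError(
            f"rank-deficient design: columns {names[i]!r} and {names[j]!r} "
            "are collinear"
        )
    coef, *_ = np.linalg.lstsq(X, reg.target, rcond=None)
    n_m = len(reg.muscle_names)
    F_O_hat, f_sc_hat = coef[:n_m], coef[n_m:]
    if np.any(F_O_hat < 0):
        bad = [m for m, f in zip(reg.muscle_names, F_O_hat) if f < 0]
        warnings.warn(
            f"negative fitted maximal force for {bad}: physiologically invalid",
            stacklevel=2,
        )
    residual = reg.target - X @ coef
    return LinearFit(
        F_O_hat=F_O_hat,
        f_sc_hat=f_sc_hat,
        residual_rms=float(np.sqrt(np.mean(residual**2))),
        condition_number=float(sv[0] / sv[-1]),
        muscle_names=reg.muscle_names,
        gravity_names=reg.gravity_names,
    )


def calibrate_linear(
    design: Design,
    model: JointModel,
    anthro: ArmAnthropometry,
) -> FitResult:
    """Full linear calibration: regressors, OLS, and decoded model.

    The fitted scale factors are folded back into the anthropometry
    (M_hat = f_sc * M_default), so the result evaluates through the same
    torque-prediction path as every other calibration method.
    """
    reg = build_regressors(model, anthro, design)
    fit = fit_linear(reg)
    if np.any(fit.f_sc_hat <= 0):
        warnings.warn(
            "non-positive fitted mass scale factor: physiologically invalid "
            "(kept exactly as fitted)",
            stacklevel=2,
        )
    if model.joint == "shoulder":
        new_anthro = anthro.with_masses(
            M_a=fit.f_sc_hat[0] * anthro.M_a, M_fh=fit.f_sc_hat[1] * anthro.M_fh
        )
    else:
        new_anthro = anthro.with_masses(M_fh=fit.f_sc_hat[0] * anthro.M_fh)
    return FitResult(
        method="linear",
        joint=model.joint,
        model=model.with_forces(fit.F_O_hat),
        anthro=new_anthro,
        train_trial_ids=design.trial_ids,
        details={
            "F_O_hat": fit.F_O_hat,
            "f_sc_hat": fit.f_sc_hat,
            "residual_rms": fit.residual_rms,
            "condition_number": fit.condition_number,
            "muscle_names": fit.muscle_names,
            "gravity_names": fit.gravity_names,
        },
    )
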