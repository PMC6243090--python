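"""Hill-based isometric muscle-tendon unit and joint torque prediction.

Each muscle-tendon unit (MTU) produces, under the stiff-tendon and
isometric assumptions (fiber velocity ~ 0 so the force-velocity factor is
1, and no activation dynamics),

    F^mt = F_O [ f_l(l/l_o) a + f_P(l/l_o) ] cos(phi),
    phi  = arcsin( l_o sin(phi_o) / l ),

where ``F_O`` is the maximum isometric fiber force, ``f_l`` a Gaussian
active force-length curve with unit mean and spread ``sigma_A``, ``f_P``
the passive force-length curve (zero below optimal length), and ``phi``
the pennation angle under the constant-thickness assumption.  Fiber length
``l(theta)`` and moment arm ``r(theta)`` are cubic polynomials of the
driving joint angle.  The joint torque is the sum of MTU force times
moment arm:

    tau^p = sum_i F_i^mt r_i(theta).

Sign convention: flexion-positive torques; extensor moment arms are
negative.  Angles are radians throughout.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np

from .emg import activation as _activation

__all__ = [
    "MuscleTendonUnit",
    "JointModel",
    "GeometryFit",
    "fit_geometry_curves",
    "default_models",
    "load_parameters",
    "save_parameters",
]

SCHEMA_VERSION = 1

#: Steepness of the default passive force-length curve; normalised so that
#: f_P = 1 at l/l_o = 1.5 (the curve is never optimised and the protocol
#: keeps fibers short of elongated configurations, so it rarely engages).
_PASSIVE_K = 5.0
_PASSIVE_NORM = float(np.expm1(_PASSIVE_K * 0.5))


def passive_fl(l_norm: np.ndarray | float) -> np.ndarray | float:
    """Normalised passive force: 0 below optimal length, exponential rise above.

    f_P(l~) = (exp(k (l~ - 1)) - 1) / (exp(k/2) - 1) for l~ > 1, with k = 5,
    so f_P(1.5) = 1.
    """
    l_arr = np.asarray(l_norm, dtype=float)
    out = np.where(l_arr > 1.0, np.expm1(_PASSIVE_K * (l_arr - 1.0)) / _PASSIVE_NORM, 0.0)
    return out if isinstance(l_norm, np.ndarray) else float(out)


@dataclass(frozen=True)
class MuscleTendonUnit:
    """One muscle-tendon unit with its force parameters and geometry curves.

    coeff_l / coeff_r : ascending-power cubic coefficients of fiber length
        (m) and moment arm (m) versus the driving joint angle (rad).
    """

    name: str
    F_O: float          # maximum isometric fiber force, N
    l_o: float          # optimal fiber length, m
    phi_o: float        # pennation angle at l_o, rad
    A: float            # activation shape factor, [-3, 0)
    sigma_A: float      # Gaussian active force-length spread, l/l_o units
    coeff_l: tuple[float, float, float, float]
    coeff_r: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        # F_O is positive for a physiological muscle, but an unconstrained
        # calibration may fit a negative coefficient; the calibrators flag
        # that case and the container carries the value exactly.
        if not np.isfinite(self.F_O):
            raise ValueError(f"{self.name}: F_O must be finite")
        if self.l_o <= 0:
            raise ValueError(f"{self.name}: l_o must be positive")
        if not (0.0 <= self.phi_o < np.pi / 2):
            raise ValueError(f"{self.name}: phi_o must lie in [0, pi/2)")
        if self.sigma_A <= 0:
            raise ValueError(f"{self.name}: sigma_A must be positive")
        if not (-3.0 <= self.A <= 0.0):
            raise ValueError(f"{self.name}: A must lie in [-3, 0]")
        object.__setattr__(self, "coeff_l", tuple(float(c) for c in self.coeff_l))
        object.__setattr__(self, "coeff_r", tuple(float(c) for c in self.coeff_r))
        if len(self.coeff_l) != 4 or len(self.coeff_r) != 4:
            raise ValueError(f"{self.name}: geometry curves need 4 coefficients each")

    # -- geometry -----------------------------------------------------------

    def fiber_length(self, theta: np.ndarray | float) -> np.ndarray | float:
        """Cubic fiber length l(theta), m; raises if non-positive."""
        th = np.asarray(theta, dtype=float)
        l = np.polynomial.polynomial.polyval(th, self.coeff_l)
        if np.any(l <= 0):
            raise ValueError(f"{self.name}: fiber length <= 0 at theta={theta!r}")
        return l if isinstance(theta, np.ndarray) else float(l)

    def moment_arm(self, theta: np.ndarray | float) -> np.ndarray | float:
        """Cubic moment arm r(theta), m; negative for extensors."""
        th = np.asarray(theta, dtype=float)
        r = np.polynomial.polynomial.polyval(th, self.coeff_r)
        return r if isinstance(theta, np.ndarray) else float(r)

    def pennation(self, l: np.ndarray | float) -> np.ndarray | float:
        """phi = arcsin(l_o sin(phi_o) / l) (constant-thickness assumption)."""
        l_arr = np.asarray(l, dtype=float)
        arg = self.l_o * np.sin(self.phi_o) / l_arr
        if np.any(arg > 1.0) or np.any(l_arr <= 0):
            raise ValueError(f"{self.name}: pennation undefined (fiber too short)")
        phi = np.arcsin(arg)
        return phi if isinstance(l, np.ndarray) else float(phi)

    def active_fl(self, l_norm: np.ndarray | float) -> np.ndarray | float:
        """Gaussian active force-length curve, peak 1 at l/l_o = 1."""
        x = np.asarray(l_norm, dtype=float)
        out = np.exp(-((x - 1.0) ** 2) / (2.0 * self.sigma_A**2))
        return out if isinstance(l_norm, np.ndarray) else float(out)

    # -- force --------------------------------------------------------------

    def unit_force_torque(self, a, theta):
        """Torque contribution per newton of F_O: r (f_l a + f_P) cos(phi).

        This is the regressor A_i of the linear-in-parameters reformulation;
        multiplying by F_O gives the MTU torque.
        """
        th = np.asarray(theta, dtype=float)
        a_arr = np.clip(np.asarray(a, dtype=float), 0.0, 1.0)
        l = np.polynomial.polynomial.polyval(th, self.coeff_l)
        if np.any(l <= 0):
            raise ValueError(f"{self.name}: fiber length <= 0")
        l_norm = l / self.l_o
        phi = self.pennation(l)
        out = self.moment_arm(th) * (
            self.active_fl(l_norm) * a_arr + passive_fl(l_norm)
        ) * np.cos(phi)
        return out

    def mtu_force(self, a, theta):
        """Stiff-tendon MTU force F^mt = F_O (f_l a + f_P) cos(phi), N."""
        th = np.asarray(theta, dtype=float)
        a_arr = np.clip(np.asarray(a, dtype=float), 0.0, 1.0)
        l = np.polynomial.polynomial.polyval(th, self.coeff_l)
        if np.any(l <= 0):
            raise ValueError(f"{self.name}: fiber length <= 0")
        l_norm = l / self.l_o
        phi = self.pennation(l)
        f = self.F_O * (self.active_fl(l_norm) * a_arr + passive_fl(l_norm)) * np.cos(phi)
        return f if (isinstance(a, np.ndarray) or isinstance(theta, np.ndarray)) else float(f)

    def excitation_to_activation(self, u):
        return _activation(u, self.A)


@dataclass(frozen=True)
class JointModel:
    """Per-joint EMG-driven model: 2 muscles at the elbow (BB, TB), 4 at the
    shoulder (BB, TB, AD, PD), each driven by that joint's own angle."""

    joint: str  # "elbow" | "shoulder"
    muscles: tuple[MuscleTendonUnit, ...]

    def __post_init__(self) -> None:
        if self.joint not in ("elbow", "shoulder"):
            raise ValueError("joint must be 'elbow' or 'shoulder'")
        object.__setattr__(self, "muscles", tuple(self.muscles))
        expected = 2 if self.joint == "elbow" else 4
        if len(self.muscles) != expected:
            raise ValueError(
                f"{self.joint} model needs exactly {expected} muscles, got {len(self.muscles)}"
            )

    @property
    def muscle_names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.muscles)

    def predict_torque(self, activations, theta):
        """tau^p = sum_i F_i^mt r_i(theta); flexion-positive, N*m.

        activations : (n_muscles,) or (n_samples, n_muscles).
        theta : scalar or (n_samples,) driving joint angle.
        """
        a = np.asarray(activations, dtype=float)
        if a.ndim == 1:
            if a.shape[0] != len(self.muscles):
                raise ValueError("one activation per muscle required")
            cols = a[None, :]
        else:
            if a.shape[1] != len(self.muscles):
                raise ValueError("one activation column per muscle required")
            cols = a
        th = np.atleast_1d(np.asarray(theta, dtype=float))
        tau = np.zeros(np.broadcast(cols[:, 0], th).shape, dtype=float)
        for i, mtu in enumerate(self.muscles):
            tau = tau + mtu.F_O * mtu.unit_force_torque(cols[:, i], th)
        scalar = np.ndim(activations) == 1 and np.ndim(theta) == 0
        return float(tau[0]) if scalar else tau

    def with_forces(self, F_O: np.ndarray) -> "JointModel":
        """Copy of the model with per-muscle maximum forces replaced."""
        F_O = np.asarray(F_O, dtype=float)
        if F_O.shape[0] != len(self.muscles):
            raise ValueError("one F_O per muscle required")
        return replace(
            self, muscles=tuple(replace(m, F_O=float(f)) for m, f in zip(self.muscles, F_O))
        )


# -- geometry-curve fitting --------------------------------------------------


@dataclass(frozen=True)
class GeometryFit:
    coeff: tuple[float, ...]
    adjusted_r2: float


def _adjusted_r2(y: np.ndarray, y_hat: np.ndarray, n_params: int) -> float:
    n = y.size
    ss_res = float(np.sum((y - y_hat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if n - n_params <= 0 or ss_tot == 0.0:
        warnings.warn("adjusted R^2 undefined (no residual degrees of freedom)", stacklevel=3)
        return float("nan")
    r2 = 1.0 - ss_res / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params)


def fit_polynomial_curve(theta: np.ndarray, y: np.ndarray, degree: int = 3) -> GeometryFit:
    """Least-squares cubic fit of a geometry sample table (theta, y)."""
    theta = np.asarray(theta, dtype=float)
    y = np.asarray(y, dtype=float)
    if theta.size < degree + 1:
        raise ValueError("need at least degree+1 samples")
    X = np.vander(theta, degree + 1, increasing=True)
    if np.linalg.matrix_rank(X) < degree + 1:
        raise ValueError("rank-deficient design: theta samples do not span the fit")
    coeff, *_ = np.linalg.lstsq(X, y, rcond=None)
    return GeometryFit(tuple(coeff), _adjusted_r2(y, X @ coeff, degree + 1))


def fit_active_fl_curve(l_norm: np.ndarray, f_A: np.ndarray) -> tuple[float, float]:
    """Fit sigma_A of the unit-mean Gaussian active force-length curve.

    Returns (sigma_A, adjusted_r2).  Nonlinear least squares on the Gaussian.
    """
    from scipy.optimize import curve_fit

    l_norm = np.asarray(l_norm, dtype=float)
    f_A = np.asarray(f_A, dtype=float)
    if l_norm.size < 3:
        raise ValueError("need at least 3 active force-length samples")

    def gauss(x, sigma):
        return np.exp(-((x - 1.0) ** 2) / (2.0 * sigma**2))

    (sigma,), _ = curve_fit(gauss, l_norm, f_A, p0=[0.5], bounds=(1e-6, 10.0))
    return float(sigma), _adjusted_r2(f_A, gauss(l_norm, sigma), 1)


def fit_geometry_curves(
    length_samples: tuple[np.ndarray, np.ndarray],
    moment_arm_samples: tuple[np.ndarray, np.ndarray],
    active_fl_samples: tuple[np.ndarray, np.ndarray],
) -> dict:
    """Fit the three per-muscle curves from sample tables.

    length_samples / moment_arm_samples : (theta, value) pairs, cubic fits.
    active_fl_samples : (l_norm, f_A) pair, unit-mean Gaussian fit.
    Returns dict with coeff_l, coeff_r, sigma_A and per-fit adjusted R^2.
    """
    fl = fit_polynomial_curve(*length_samples)
    fr = fit_polynomial_curve(*moment_arm_samples)
    sigma_A, r2_g = fit_active_fl_curve(*active_fl_samples)
    return {
        "coeff_l": fl.coeff,
        "coeff_r": fr.coeff,
        "sigma_A": sigma_A,
        "adjusted_r2": {"length": fl.adjusted_r2, "moment_arm": fr.adjusted_r2,
                        "active_fl": r2_g},
    }


# -- parameter files ---------------------------------------------------------


def _mtu_to_dict(m: MuscleTendonUnit) -> dict:
    return {
        "name": m.name, "F_O": m.F_O, "l_o": m.l_o, "phi_o": m.phi_o,
        "A": m.A, "sigma_A": m.sigma_A,
        "coeff_l": list(m.coeff_l), "coeff_r": list(m.coeff_r),
    }


def _mtu_from_dict(d: dict) -> MuscleTendonUnit:
    return MuscleTendonUnit(
        name=d["name"], F_O=d["F_O"], l_o=d["l_o"], phi_o=d["phi_o"],
        A=d["A"], sigma_A=d["sigma_A"],
        coeff_l=tuple(d["coeff_l"]), coeff_r=tuple(d["coeff_r"]),
    )


def save_parameters(path: str | Path, models: dict, anthropometry=None) -> None:
    """Write joint models (and optionally anthropometry) to a JSON file."""
    from .gravity import ArmAnthropometry  # local import to avoid a cycle

    payload = {"schema_version": SCHEMA_VERSION, "joints": {}}
    for joint, model in models.items():
        payload["joints"][joint] = {
            "joint": model.joint,
            "muscles": [_mtu_to_dict(m) for m in model.muscles],
        }
    if anthropometry is not None:
        payload["anthropometry"] = anthropometry.to_dict()
    Path(path).write_text(json.dumps(payload, indent=2))


def load_parameters(path: str | Path):
    """Read joint models and anthropometry from a JSON parameter file.

    Returns (models: dict[str, JointModel], anthropometry | None).
    """
    from .gravity import ArmAnthropometry

    payload = json.loads(Path(path).read_text())
    if payload.get("schema_version") != SCHEMA_VERSION:
        warnings.warn("parameter file schema version mismatch", stacklevel=2)
    models = {
        joint: JointModel(joint=blk["joint"],
                          muscles=tuple(_mtu_from_dict(m) for m in blk["muscles"]))
        for joint, blk in payload["joints"].items()
    }
    anthro = None
    if "anthropometry" in payload:
        anthro = ArmAnthropometry.from_dict(payload["anthropometry"])
    return models, anthro


def default_models():
    """Shipped default (non-optimised) joint models and anthropometry.

    The per-muscle values are representative approximations in the style of
    generic upper-limb musculoskeletal models (documented in defaults.json);
    they serve as the normative starting point that subject calibration
    adjusts, never as ground truth.
    """
    with resources.files("emgnms").joinpath("defaults.json").open() as fh:
        path_payload = json.load(fh)
    from .gravity import ArmAnthropometry

    models = {
        joint: JointModel(joint=blk["joint"],
                          muscles=tuple(_mtu_from_dict(m) for m in blk["muscles"]))
        for joint, blk in path_payload["joints"].items()
    }
    anthro = ArmAnthropometry.from_dict(path_payload["anthropometry"])
    return models, anthro
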