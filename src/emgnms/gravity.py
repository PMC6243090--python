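"""Two-dimensional arm gravity model.

The upper limb is reduced to two sagittal-plane links: the arm (shoulder to
elbow, mass ``M_a`` at distance ``l_1`` from the shoulder) and the
forearm+hand (mass ``M_fh`` at distance ``l_2`` from the elbow).  With
``theta1`` the shoulder elevation measured from the gravity vector (arm
hanging = 0) and ``theta2`` the elbow flexion relative to the upper arm,
the gravity torques the muscles must balance are

    tau_el^g = M_fh l_2 g sin(theta1 + theta2)
    tau_sh^g = M_fh L_1 g sin(theta1) + M_a l_1 g sin(theta1) + tau_el^g

Both are linear in each link mass at fixed angles — the property the
linear calibration's gravity scale factors rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ArmAnthropometry",
    "gravity_torques",
    "gravity_components",
    "default_masses",
    "WINTER_ARM_FRACTION",
    "WINTER_FOREARM_HAND_FRACTION",
]

#: Winter-style segment-mass fractions of total body mass (configurable
#: constants; the upper-arm fraction and the forearm 0.016 + hand 0.006).
WINTER_ARM_FRACTION = 0.028
WINTER_FOREARM_HAND_FRACTION = 0.022


@dataclass(frozen=True)
class ArmAnthropometry:
    """Gravity-model constants for one subject's arm.

    M_a / M_fh : arm and forearm+hand masses (kg).
    L_1 : arm (shoulder-to-elbow) length (m).
    l_1 / l_2 : centre-of-mass distances from shoulder / elbow (m), by
        convention half the segment length.
    L_2 : elbow-to-handle lever used by the end-effector Jacobian (m).
    """

    M_a: float
    M_fh: float
    L_1: float
    l_1: float
    l_2: float
    L_2: float = 0.33
    g: float = 9.81

    def __post_init__(self) -> None:
        for name in ("L_1", "l_1", "l_2", "L_2", "g"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        # masses are positive for a physical arm, but the calibrated
        # gravity scale factors may come out negative (flagged upstream)
        # and the container carries the fitted value exactly
        for name in ("M_a", "M_fh"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.l_1 > self.L_1:
            raise ValueError("l_1 cannot exceed the arm length L_1")

    def with_masses(self, M_a: float | None = None, M_fh: float | None = None):
        return replace(
            self,
            M_a=self.M_a if M_a is None else float(M_a),
            M_fh=self.M_fh if M_fh is None else float(M_fh),
        )

    def to_dict(self) -> dict:
        return {
            "M_a": self.M_a, "M_fh": self.M_fh, "L_1": self.L_1,
            "l_1": self.l_1, "l_2": self.l_2, "L_2": self.L_2, "g": self.g,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArmAnthropometry":
        return cls(**d)


def default_masses(body_mass: float) -> tuple[float, float]:
    """(M_a, M_fh) from total body mass via Winter's segment fractions."""
    if body_mass <= 0:
        raise ValueError("body mass must be positive")
    return (WINTER_ARM_FRACTION * body_mass,
            WINTER_FOREARM_HAND_FRACTION * body_mass)


def gravity_components(anthro: ArmAnthropometry, theta1, theta2):
    """Per-link gravity torque contributions at each joint.

    Returns a dict with:
      ``elbow_fh``    — forearm+hand contribution at the elbow
                        (= the whole elbow gravity torque),
      ``shoulder_a``  — arm-link (M_a-proportional) contribution at the shoulder,
      ``shoulder_fh`` — forearm+hand (M_fh-proportional) contribution at the
                        shoulder, including the elbow term.

    Scaling a link mass scales exactly its contributions, which is what the
    linear calibration's scale factors adjust.
    """
    th1 = np.asarray(theta1, dtype=float)
    th2 = np.asarray(theta2, dtype=float)
    el = anthro.M_fh * anthro.l_2 * anthro.g * np.sin(th1 + th2)
    sh_a = anthro.M_a * anthro.l_1 * anthro.g * np.sin(th1)
    sh_fh = anthro.M_fh * anthro.L_1 * anthro.g * np.sin(th1) + el
    return {"elbow_fh": el, "shoulder_a": sh_a, "shoulder_fh": sh_fh}


def gravity_torques(anthro: ArmAnthropometry, theta1, theta2):
    """(tau_sh^g, tau_el^g) in N*m at the given configuration (rad)."""
    comp = gravity_components(anthro, theta1, theta2)
    return comp["shoulder_a"] + comp["shoulder_fh"], comp["elbow_fh"]
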