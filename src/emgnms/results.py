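"""Common calibration result container."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .gravity import ArmAnthropometry
from .muscle import JointModel, _mtu_to_dict

__all__ = ["FitResult"]


@dataclass(frozen=True)
class FitResult:
    """A calibrated per-joint model with its provenance.

    method : "linear" | "ga" | "default".
    model / anthro : the calibrated joint model and (mass-adjusted)
        anthropometry; together they define the external-torque predictor
        tau^p - tau^g.
    train_trial_ids : trials the calibration saw (used to detect leakage).
    details : method-specific extras (residuals, condition number, GA trace).
    """

    method: str
    joint: str
    model: JointModel
    anthro: ArmAnthropometry
    train_trial_ids: tuple[str, ...]
    seed: int | None = None
    details: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        def _clean(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            if isinstance(v, dict):
                return {k: _clean(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [_clean(x) for x in v]
            return v

        payload = {
            "method": self.method,
            "joint": self.joint,
            "muscles": [_mtu_to_dict(m) for m in self.model.muscles],
            "anthropometry": self.anthro.to_dict(),
            "train_trial_ids": list(self.train_trial_ids),
            "seed": self.seed,
            "details": _clean(self.details),
        }
        Path(path).write_text(json.dumps(payload, indent=2))
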