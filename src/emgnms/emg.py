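"""Surface-EMG conditioning: raw signal -> excitation -> activation.

The conditioning chain follows the standard myo-control recipe: a 20 Hz
second-order Butterworth high-pass removes motion artefact and DC offset,
the signal is full-wave rectified and normalised by the muscle's maximum
voluntary contraction (MVC) amplitude, and a 5 Hz second-order Butterworth
low-pass extracts the linear envelope ``e(t)``.  The neural excitation is
the envelope shifted by the electromechanical delay, ``u(t) = e(t - d)``,
and the activation nonlinearity

    a(u) = (exp(A u) - 1) / (exp(A) - 1),    A in [-3, 0)

maps excitation to the fraction of recruited maximal muscle force.  All
filtering is causal (forward-only) by default, matching real-time use; a
zero-phase option exists for offline work.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

__all__ = [
    "EmgConfig",
    "RawEmg",
    "Excitation",
    "preprocess_emg",
    "compute_mvc",
    "apply_delay",
    "activation",
    "inverse_activation",
]

#: Duration (s) of the filter start-up flagged as transient and excluded
#: from calibration windows.
TRANSIENT_S = 0.5


@dataclass(frozen=True)
class EmgConfig:
    """Conditioning parameters.

    hp_hz / lp_hz : corner frequencies of the high- and low-pass Butterworth
        stages (Hz).  order applies to both.
    delay_s : electromechanical delay ``d`` (s); physiological range 10-150 ms.
    causal : forward-only filtering when True, zero-phase (filtfilt) otherwise.
    notch_hz : optional mains notch; None assumes the amplifier already
        applied one.
    """

    hp_hz: float = 20.0
    lp_hz: float = 5.0
    order: int = 2
    delay_s: float = 0.080
    causal: bool = True
    notch_hz: float | None = None


@dataclass(frozen=True)
class RawEmg:
    """Multichannel raw surface EMG.

    samples : array (n_samples, n_channels), volts.
    fs : sampling rate, Hz.
    channel_names : muscle labels, e.g. ("BB", "TB", "AD", "PD").
    """

    samples: np.ndarray
    fs: float
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if samples.shape[0] == 1 and len(self.channel_names) == 1:
            samples = samples.T if samples.shape[1] > 1 else samples
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 2:
            raise ValueError("samples must be a 2-D (n_samples, n_channels) array")
        if samples.shape[1] != len(self.channel_names):
            raise ValueError(
                f"{samples.shape[1]} columns but {len(self.channel_names)} channel names"
            )
        if np.isnan(samples).any():
            raise ValueError("raw EMG contains NaN")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.fs < 1000.0:
            warnings.warn(
                f"fs = {self.fs} Hz < 1 kHz: the 5-500 Hz EMG band is degraded",
                stacklevel=2,
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class Excitation:
    """Normalised linear envelope e(t) (or delayed excitation u(t)).

    e : array (n_samples, n_channels), unitless, >= 0; may exceed 1 when a
        contraction exceeds the MVC reference.
    mvc_reference : the per-channel MVC amplitude used for normalisation.
    transient_s : leading span still affected by filter start-up.
    """

    e: np.ndarray
    fs: float
    mvc_reference: np.ndarray
    channel_names: tuple[str, ...]
    transient_s: float = TRANSIENT_S

    def __post_init__(self) -> None:
        e = np.atleast_2d(np.asarray(self.e, dtype=float))
        object.__setattr__(self, "e", e)
        object.__setattr__(
            self, "mvc_reference", np.asarray(self.mvc_reference, dtype=float)
        )
        if np.any(self.mvc_reference <= 0):
            raise ValueError("mvc_reference must be positive")
        if np.any(e < -1e-12):
            raise ValueError("excitation must be non-negative")

    @property
    def transient_samples(self) -> int:
        return int(round(self.transient_s * self.fs))

    def valid_mask(self) -> np.ndarray:
        """Boolean mask of samples past the filter start-up transient."""
        mask = np.ones(self.e.shape[0], dtype=bool)
        mask[: self.transient_samples] = False
        return mask


def _butter_sos(kind: str, hz: float, order: int, fs: float) -> np.ndarray:
    return sps.butter(order, hz, btype=kind, fs=fs, output="sos")


def _filter(sos: np.ndarray, x: np.ndarray, causal: bool) -> np.ndarray:
    # zero initial state in both modes; axis 0 = time
    if causal:
        return sps.sosfilt(sos, x, axis=0)
    return sps.sosfiltfilt(sos, x, axis=0)


def envelope(raw: RawEmg, config: EmgConfig = EmgConfig()) -> np.ndarray:
    """Unnormalised linear envelope: LP(|HP(raw)|), volts."""
    x = raw.samples
    if config.notch_hz is not None:
        b, a = sps.iirnotch(config.notch_hz, Q=30.0, fs=raw.fs)
        x = sps.lfilter(b, a, x, axis=0) if config.causal else sps.filtfilt(b, a, x, axis=0)
    hp = _butter_sos("highpass", config.hp_hz, config.order, raw.fs)
    lp = _butter_sos("lowpass", config.lp_hz, config.order, raw.fs)
    rectified = np.abs(_filter(hp, x, config.causal))
    env = _filter(lp, rectified, config.causal)
    return np.clip(env, 0.0, None)


def preprocess_emg(
    raw: RawEmg,
    mvc: np.ndarray | float,
    config: EmgConfig = EmgConfig(),
) -> Excitation:
    """High-pass, rectify, MVC-normalise and low-pass the raw EMG.

    Parameters
    ----------
    mvc : per-channel MVC envelope amplitude (volts), broadcastable to the
        channel count.  Must be strictly positive.
    """
    mvc_arr = np.broadcast_to(
        np.asarray(mvc, dtype=float), (raw.samples.shape[1],)
    ).copy()
    if np.any(mvc_arr <= 0):
        raise ValueError("MVC reference must be positive for every channel")
    if raw.duration_s < 1.0:
        warnings.warn("recording shorter than 1 s: filter warm-up dominates", stacklevel=2)
    env = envelope(raw, config) / mvc_arr
    return Excitation(
        e=env, fs=raw.fs, mvc_reference=mvc_arr, channel_names=raw.channel_names
    )


def compute_mvc(
    recordings: RawEmg | list[RawEmg] | tuple[RawEmg, ...],
    config: EmgConfig = EmgConfig(),
) -> np.ndarray:
    """Per-channel MVC amplitude from maximum-contraction recordings.

    The MVC reference is the maximum of the processed envelope (high-pass,
    rectify, low-pass — no normalisation) over each recording, reduced by a
    further maximum across recordings when several (one per force direction)
    are given.  The filter start-up transient is excluded.
    """
    if isinstance(recordings, RawEmg):
        recordings = [recordings]
    if not recordings:
        raise ValueError("no MVC recordings given")
    maxima = []
    for rec in recordings:
        if rec.duration_s < 1.0:
            raise ValueError("MVC recording must be at least 1 s long")
        env = envelope(rec, config)
        skip = int(round(TRANSIENT_S * rec.fs))
        maxima.append(env[skip:].max(axis=0))
    return np.max(maxima, axis=0)


def apply_delay(exc: Excitation, d: float | None = None,
                config: EmgConfig | None = None) -> Excitation:
    """Electromechanical delay: u(t) = e(t - d).

    Fractional-sample delays are realised by linear interpolation; the
    leading edge (t < d) holds the first sample.  Length and fs preserved.
    """
    if d is None:
        d = (config or EmgConfig()).delay_s
    if d < 0:
        raise ValueError("delay must be non-negative")
    if d > 0 and not (0.010 <= d <= 0.150):
        warnings.warn(
            f"delay {d * 1e3:.0f} ms outside the physiological 10-150 ms range",
            stacklevel=2,
        )
    if d == 0:
        return exc
    n = exc.e.shape[0]
    t = np.arange(n) / exc.fs
    delayed = np.empty_like(exc.e)
    for c in range(exc.e.shape[1]):
        delayed[:, c] = np.interp(t - d, t, exc.e[:, c])
    return replace(exc, e=delayed)


def activation(u: np.ndarray | float, A: float) -> np.ndarray | float:
    """Excitation-to-activation nonlinearity a = (e^{Au} - 1)/(e^A - 1).

    ``A`` is the shape factor in [-3, 0]; negative values bend the curve
    above the identity (a >= u).  ``A = 0`` is resolved by its analytic
    limit a = u.  ``u`` is clipped to [0, 1] before the map, which is only
    calibrated on that interval.
    """
    if not (-3.0 <= A <= 0.0):
        raise ValueError(f"shape factor A = {A} outside [-3, 0]")
    u_arr = np.clip(np.asarray(u, dtype=float), 0.0, 1.0)
    if A == 0.0:
        out = u_arr
    else:
        out = np.expm1(A * u_arr) / np.expm1(A)
    return out if isinstance(u, np.ndarray) else float(out)


def inverse_activation(a: np.ndarray | float, A: float) -> np.ndarray | float:
    """Invert the activation map: u = log(1 + a (e^A - 1)) / A."""
    if not (-3.0 <= A <= 0.0):
        raise ValueError(f"shape factor A = {A} outside [-3, 0]")
    a_arr = np.clip(np.asarray(a, dtype=float), 0.0, 1.0)
    if A == 0.0:
        out = a_arr
    else:
        out = np.log1p(a_arr * np.expm1(A)) / A
    return out if isinstance(a, np.ndarray) else float(out)


def lp_group_delay_s(config: EmgConfig = EmgConfig()) -> float:
    """DC group delay of the 2nd-order Butterworth envelope low-pass (s).

    For H(s) = 1 / (s^2/wc^2 + sqrt(2) s/wc + 1) the group delay at DC is
    sqrt(2)/wc.  Used by the synthetic generator to pre-advance modulation
    profiles so the causal pipeline recovers them in phase.
    """
    wc = 2.0 * np.pi * config.lp_hz
    return float(np.sqrt(2.0) / wc)
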