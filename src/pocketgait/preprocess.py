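"""Device-to-Earth frame rotation and zero-phase low-pass filtering.

The phone sits in a pants pocket in an arbitrary, roughly fixed orientation.
Gait events are read from the *vertical* acceleration, so the device-frame
signals must first be rotated into an Earth-based frame whose Z axis points
up, regardless of how the phone was pocketed.  When the recording carries
attitude quaternions they are used directly; otherwise attitude is estimated
with a tilt-only complementary filter: the accelerometer, low-passed well
below step frequency, provides the slow gravity direction, while the
gyroscope propagates it between accelerometer updates.  Yaw is left
arbitrary — only the vertical axis and the vertical-axis angular rate are
consumed downstream, and both are yaw-invariant.

After rotation the scalar gravity magnitude (estimated from the low-passed
acceleration norm, or supplied) is subtracted from the Z channel, the series
is resampled to a uniform rate, and a zero-phase (forward-backward)
Butterworth low-pass at 3 Hz isolates the gait-band oscillations without
biasing event timing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps
from scipy.spatial.transform import Rotation

from .config import RunConfig
from .errors import OrientationError, TrialValidationError
from .io import IMUTrial


@dataclass
class EarthFrameSignal:
    """Rotated (and optionally filtered) signals on a uniform time base."""

    t: np.ndarray
    acc_earth: np.ndarray  # (n, 3), gravity removed from Z
    gyro_earth: np.ndarray  # (n, 3)
    fs: float
    filtered: bool = False
    cutoff: float | None = None
    g: float = 9.81  # scalar gravity subtracted from Z
    meta: dict = field(default_factory=dict)

    @property
    def vertical_acc(self) -> np.ndarray:
        return self.acc_earth[:, 2]

    @property
    def vertical_rate(self) -> np.ndarray:
        return self.gyro_earth[:, 2]


def _lowpass_array(x: np.ndarray, fs: float, cutoff: float, order: int) -> np.ndarray:
    sos = sps.butter(order, cutoff, btype="low", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=0)


def _tilt_quaternions(g_dir: np.ndarray) -> np.ndarray:
    """Shortest-arc quaternions (scalar-first) rotating each unit vector in
    ``g_dir`` onto Earth up ``(0, 0, 1)``; yaw-free by construction."""
    z = np.array([0.0, 0.0, 1.0])
    dot = np.clip(g_dir @ z, -1.0, 1.0)
    axis = np.cross(g_dir, z)
    axis_norm = np.linalg.norm(axis, axis=1)
    # antiparallel singularity: rotate pi about X
    degenerate = axis_norm < 1e-12
    axis = np.where(
        degenerate[:, None], np.array([1.0, 0.0, 0.0]), axis / np.where(axis_norm, axis_norm, 1.0)[:, None]
    )
    angle = np.arccos(dot)
    angle = np.where(degenerate & (dot < 0), np.pi, np.where(degenerate, 0.0, angle))
    quat = np.empty((len(g_dir), 4))
    quat[:, 0] = np.cos(angle / 2.0)
    quat[:, 1:] = np.sin(angle / 2.0)[:, None] * axis
    return quat


def estimate_orientation(trial: IMUTrial, config: RunConfig | None = None) -> np.ndarray:
    """Per-sample device-to-Earth unit quaternions (scalar-first).

    Returns the trial's own quaternions when present (modes ``auto`` and
    ``provided``); otherwise runs the gravity-vector complementary filter.
    Raises :class:`OrientationError` on free-fall-like input, where gravity
    carries no orientation information.
    """
    config = config or RunConfig()
    if trial.quat is not None and config.orientation_mode in ("auto", "provided"):
        return trial.quat
    if trial.quat is None and config.orientation_mode == "provided":
        raise OrientationError("orientation_mode='provided' but trial has no quaternions")
    if trial.duration < 2.0:
        raise OrientationError("need at least 2 s of data to estimate orientation")

    acc, gyro, t = trial.acc, trial.gyro, trial.t
    mean_norm = float(np.mean(np.linalg.norm(acc, axis=1)))
    if mean_norm < 1.0:
        raise OrientationError(
            f"mean acceleration norm {mean_norm:.2f} m/s^2 is too small "
            "(free-fall-like input); cannot estimate gravity direction"
        )

    fs = 1.0 / float(np.median(np.diff(t)))
    acc_lp = _lowpass_array(acc, fs, config.orientation_tilt_cutoff_hz, order=2)
    norms = np.linalg.norm(acc_lp, axis=1)
    norms[norms < 1e-9] = 1.0
    acc_dir = acc_lp / norms[:, None]

    # gravity direction in the device frame: gyro propagation
    # (d g/dt = -omega x g) corrected toward the low-passed accelerometer
    # direction with a small per-sample gain.
    dt = np.diff(t)
    g_hat = np.empty_like(acc_dir)
    g_hat[0] = acc_dir[0]
    gains = 2.0 * np.pi * config.orientation_tilt_cutoff_hz * dt
    np.clip(gains, 0.0, 1.0, out=gains)
    prev = g_hat[0]
    for k in range(1, len(t)):
        pred = prev - dt[k - 1] * np.cross(gyro[k - 1], prev)
        pred /= np.linalg.norm(pred)
        a = gains[k - 1]
        fused = (1.0 - a) * pred + a * acc_dir[k]
        fused /= np.linalg.norm(fused)
        g_hat[k] = fused
        prev = fused
    return _tilt_quaternions(g_hat)


def estimate_gravity(acc_earth_raw: np.ndarray, fs: float, cutoff: float = 0.25) -> float:
    """Scalar gravity from the norm of the low-passed rotated acceleration."""
    lp = _lowpass_array(acc_earth_raw, fs, cutoff, order=2)
    return float(np.median(np.linalg.norm(lp, axis=1)))


def rotate_to_earth(
    trial: IMUTrial,
    quat: np.ndarray,
    config: RunConfig | None = None,
) -> EarthFrameSignal:
    """Rotate device-frame signals to the Earth frame, remove gravity from Z,
    and resample to a uniform rate by linear interpolation.

    Rotation is an isometry: per-sample norms are preserved exactly (up to
    floating point) before gravity removal.
    """
    config = config or RunConfig()
    quat = np.asarray(quat, dtype=float)
    if quat.shape != (trial.n_samples, 4):
        raise TrialValidationError(
            f"quaternion series shape {quat.shape} does not match trial length {trial.n_samples}"
        )
    if np.max(np.abs(np.linalg.norm(quat, axis=1) - 1.0)) > 1e-6:
        raise TrialValidationError("quaternions must be unit-norm")

    rot = Rotation.from_quat(quat, scalar_first=True)
    acc_e = rot.apply(trial.acc)
    gyro_e = rot.apply(trial.gyro)

    fs_raw = 1.0 / float(np.median(np.diff(trial.t)))
    g = config.gravity_g if config.gravity_g is not None else estimate_gravity(acc_e, fs_raw)
    acc_e = acc_e.copy()
    acc_e[:, 2] -= g

    fs = config.resample_fs or trial.fs_nominal
    t0 = trial.t - trial.t[0]
    n_out = int(np.floor(t0[-1] * fs)) + 1
    t_uniform = np.arange(n_out) / fs
    acc_u = np.column_stack([np.interp(t_uniform, t0, acc_e[:, i]) for i in range(3)])
    gyro_u = np.column_stack([np.interp(t_uniform, t0, gyro_e[:, i]) for i in range(3)])
    return EarthFrameSignal(
        t=t_uniform,
        acc_earth=acc_u,
        gyro_earth=gyro_u,
        fs=float(fs),
        g=g,
        meta={"trial_id": trial.trial_id, "condition": trial.condition},
    )


def lowpass(sig: EarthFrameSignal, cutoff: float | None = None, order: int | None = None,
            config: RunConfig | None = None) -> EarthFrameSignal:
    """Zero-phase Butterworth low-pass of all six channels.

    Forward-backward application squares the magnitude response and cancels
    phase, so event timing downstream is not lag-biased.
    """
    config = config or RunConfig()
    cutoff = cutoff if cutoff is not None else config.filter_cutoff_hz
    order = order if order is not None else config.filter_order
    if sig.fs <= 2.0 * cutoff:
        raise ValueError(f"sampling rate {sig.fs} Hz must exceed twice the cutoff {cutoff} Hz")
    return replace(
        sig,
        acc_earth=_lowpass_array(sig.acc_earth, sig.fs, cutoff, order),
        gyro_earth=_lowpass_array(sig.gyro_earth, sig.fs, cutoff, order),
        filtered=True,
        cutoff=float(cutoff),
        meta=dict(sig.meta),
    )
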