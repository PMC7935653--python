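"""Reading, validating and writing pocket-IMU walking trials and gait metrics.

On-disk trial format
--------------------
A trial is a CSV file with header ``t,ax,ay,az,gx,gy,gz[,qw,qx,qy,qz][,heading]``
plus a JSON sidecar ``<stem>.meta.json`` carrying trial id, condition,
nominal sampling rate and free-form metadata.  Units are SI throughout:
seconds from trial start, m/s^2 for acceleration, rad/s for angular rate.
Quaternions are scalar-first unit quaternions rotating device-frame vectors
into the Earth frame; compass heading is in degrees.  Phone APIs that report
g-units or deg/s are supported through an explicit conversion switch on
:func:`read_trial`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import TrialFormatError, TrialValidationError

CONDITIONS = ("single_task", "dual_task")

#: standard gravity used for g-unit conversion
G0 = 9.80665

_REQUIRED_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz"]
_QUAT_COLUMNS = ["qw", "qx", "qy", "qz"]

#: float format guaranteeing bit-exact float64 round trips through text
_FLOAT_FMT = "%.17g"


@dataclass
class IMUTrial:
    """One walking trial: raw device-frame accelerometer and gyroscope series."""

    trial_id: str
    condition: str
    t: np.ndarray
    acc: np.ndarray
    gyro: np.ndarray
    quat: np.ndarray | None = None
    heading: np.ndarray | None = None
    fs_nominal: float = 100.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.quat is not None:
            self.quat = np.asarray(self.quat, dtype=float)
        if self.heading is not None:
            self.heading = np.asarray(self.heading, dtype=float)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if self.condition not in CONDITIONS:
            raise TrialValidationError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        n = len(self.t)
        if n < 2:
            raise TrialValidationError("trial must contain at least 2 samples")
        if self.acc.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise TrialValidationError(
                f"acc/gyro must be ({n}, 3); got {self.acc.shape} and {self.gyro.shape}"
            )
        dt = np.diff(self.t)
        if not np.all(dt > 0):
            raise TrialValidationError("timestamps must be strictly increasing")
        med_dt = float(np.median(dt))
        nominal_dt = 1.0 / self.fs_nominal
        if not (0.9 * nominal_dt <= med_dt <= 1.1 * nominal_dt):
            raise TrialValidationError(
                f"median sampling interval {med_dt:.4f} s deviates more than 10% "
                f"from nominal {nominal_dt:.4f} s"
            )
        if self.quat is not None:
            if self.quat.shape != (n, 4):
                raise TrialValidationError(f"quat must be ({n}, 4)")
            norms = np.linalg.norm(self.quat, axis=1)
            if np.max(np.abs(norms - 1.0)) > 1e-6:
                raise TrialValidationError("quaternion rows must be unit-norm (1e-6)")
        if self.heading is not None and self.heading.shape != (n,):
            raise TrialValidationError(f"heading must be ({n},)")
        # sampling-gap diagnostics: gaps > 1.5 nominal intervals count as
        # dropped samples; >5% dropped is flagged in meta, never rejected.
        dropped = np.sum(np.maximum(np.round(dt / nominal_dt) - 1, 0))
        frac = float(dropped) / (n + dropped) if dropped else 0.0
        flags = list(self.meta.get("flags", []))
        if frac > 0.05 and "irregular_sampling" not in flags:
            flags.append("irregular_sampling")
            self.meta["flags"] = flags

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class MetricsRecord:
    """Per-trial stride-time statistics.

    ``stride_time_variability`` is the within-trial coefficient of variation
    of stride time, in percent (100 * SD / mean).
    """

    trial_id: str
    condition: str
    n_strides: int
    stride_time_mean: float
    stride_time_sd: float
    stride_time_variability: float
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_strides < 0:
            raise TrialValidationError("n_strides must be >= 0")
        if self.n_strides >= 2:
            if not self.stride_time_mean > 0:
                raise TrialValidationError("stride_time_mean must be > 0")
            if self.stride_time_variability < 0:
                raise TrialValidationError("stride_time_variability must be >= 0")

    def to_dict(self) -> dict:
        return {
            "trial_id": self.trial_id,
            "condition": self.condition,
            "n_strides": int(self.n_strides),
            "stride_time_mean_s": float(self.stride_time_mean),
            "stride_time_sd_s": float(self.stride_time_sd),
            "stride_time_variability_pct": float(self.stride_time_variability),
            "flags": list(self.flags),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MetricsRecord":
        return cls(
            trial_id=d["trial_id"],
            condition=d["condition"],
            n_strides=int(d["n_strides"]),
            stride_time_mean=float(d["stride_time_mean_s"]),
            stride_time_sd=float(d["stride_time_sd_s"]),
            stride_time_variability=float(d["stride_time_variability_pct"]),
            flags=list(d.get("flags", [])),
        )


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def read_trial(
    path: str | Path,
    acc_units: str = "m/s^2",
    gyro_units: str = "rad/s",
) -> IMUTrial:
    """Read and validate a trial CSV (+ optional JSON sidecar).

    ``acc_units`` may be ``"m/s^2"`` or ``"g"``; ``gyro_units`` may be
    ``"rad/s"`` or ``"deg/s"``.  Non-SI inputs are converted on read.
    """
    path = Path(path)
    if not path.exists():
        raise TrialFormatError(f"no such trial file: {path}")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # malformed CSV
        raise TrialFormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrialFormatError(f"{path} is missing required columns {missing}")

    meta: dict = {}
    trial_id = path.stem
    condition = "single_task"
    fs_nominal = 100.0
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            doc = json.load(fh)
        trial_id = doc.get("trial_id", trial_id)
        condition = doc.get("condition", condition)
        fs_nominal = float(doc.get("fs_nominal", fs_nominal))
        meta = dict(doc.get("meta", {}))

    acc = df[["ax", "ay", "az"]].to_numpy(dtype=float)
    gyro = df[["gx", "gy", "gz"]].to_numpy(dtype=float)
    if acc_units == "g":
        acc = acc * G0
    elif acc_units != "m/s^2":
        raise ValueError(f"unknown acc_units {acc_units!r}")
    if gyro_units == "deg/s":
        gyro = np.deg2rad(gyro)
    elif gyro_units != "rad/s":
        raise ValueError(f"unknown gyro_units {gyro_units!r}")

    quat = None
    if all(c in df.columns for c in _QUAT_COLUMNS):
        quat = df[_QUAT_COLUMNS].to_numpy(dtype=float)
    heading = df["heading"].to_numpy(dtype=float) if "heading" in df.columns else None

    return IMUTrial(
        trial_id=trial_id,
        condition=condition,
        t=df["t"].to_numpy(dtype=float),
        acc=acc,
        gyro=gyro,
        quat=quat,
        heading=heading,
        fs_nominal=fs_nominal,
        meta=meta,
    )


def write_trial(trial: IMUTrial, path: str | Path) -> Path:
    """Write a trial as CSV with a fixed column order plus a JSON sidecar.

    Floats are serialised with 17 significant digits so that
    ``read_trial(write_trial(trial))`` reproduces every field bit-identically.
    """
    path = Path(path)
    columns = {"t": trial.t}
    for i, name in enumerate(("ax", "ay", "az")):
        columns[name] = trial.acc[:, i]
    for i, name in enumerate(("gx", "gy", "gz")):
        columns[name] = trial.gyro[:, i]
    if trial.quat is not None:
        for i, name in enumerate(_QUAT_COLUMNS):
            columns[name] = trial.quat[:, i]
    if trial.heading is not None:
        columns["heading"] = trial.heading
    pd.DataFrame(columns).to_csv(path, index=False, float_format=_FLOAT_FMT)
    sidecar = {
        "trial_id": trial.trial_id,
        "condition": trial.condition,
        "fs_nominal": trial.fs_nominal,
        "meta": trial.meta,
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return path


def write_metrics(records: list, path: str | Path, csv: bool = False) -> Path:
    """Write metric records (``MetricsRecord`` or dicts) as a JSON array.

    With ``csv=True`` an additional flat CSV is written next to the JSON.
    """
    path = Path(path)
    docs = [r.to_dict() if hasattr(r, "to_dict") else dict(r) for r in records]
    for doc in docs:
        for key, value in doc.items():
            if isinstance(value, float) and not math.isfinite(value):
                doc[key] = None
    with open(path, "w") as fh:
        json.dump(docs, fh, indent=1)
    if csv and docs:
        pd.DataFrame(docs).to_csv(path.with_suffix(".csv"), index=False)
    return path


def read_metrics(path: str | Path) -> list[dict]:
    with open(path) as fh:
        return json.load(fh)
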