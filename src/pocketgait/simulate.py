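"""Synthetic pocket-IMU walking trials with exact ground truth.

The generator emulates the study protocol — walk 10 m down a hallway, turn
180 degrees, walk 10 m back, phone in a pants pocket in an arbitrary fixed
orientation — and plays the role of the gold-standard reference system: it
knows every heel-strike time exactly, so pipeline validity can be measured
without real data.

Signal model
------------
Stride durations are drawn i.i.d. from a Normal(mean, cv * mean) truncated
at +-3 SD (truncation keeps the phase clock monotone).  A phase clock
advances 2*pi per stride, and the Earth-frame vertical acceleration is a
two-harmonic waveform

    a_v(phase) = A * [cos(2*phase) + asym * cos(phase)]

whose two peaks per stride (at phase 0 and pi) have amplitudes A*(1 + asym)
and A*(1 - asym): the alternating high/low peaks of a pocket phone loaded
asymmetrically by the two legs.  The waveform's extrema are closed-form:
its troughs sit where cos(phase) = -asym/4, so the ground-truth heel strike
(trough after each HIGH peak) is at phase arccos(-asym/4) and the toe-off
(trough after each LOW peak) at 2*pi - arccos(-asym/4), per stride.  Event
ground truth is therefore analytic, never itself detected — no circularity
between simulator and detector.

A 180-degree turn of constant yaw rate with cosine ramps is inserted at the
course midpoint, with the gait amplitude damped 50% during the turn.  White
Gaussian noise is added to every channel, gravity is added to the vertical,
and each sample is rotated from the Earth frame into the device frame by the
inverse of the fixed device orientation quaternion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .io import IMUTrial

G = 9.81

#: Table-style cohort defaults for the two walking conditions
SINGLE_TASK_DEFAULTS = dict(stride_time_mean=1.09, stride_time_cv=0.03)
DUAL_TASK_DEFAULTS = dict(stride_time_mean=1.17, stride_time_cv=0.05)

#: assumed stride lengths (m) linking stride time to walking speed
STRIDE_LENGTH_SINGLE = 1.2
STRIDE_LENGTH_DUAL = 1.15


@dataclass
class GaitSimParams:
    """Parameters of one simulated walking trial."""

    stride_time_mean: float = 1.09  # s
    stride_time_cv: float = 0.03  # fraction
    step_asymmetry: float = 0.35  # high/low peak contrast, fraction
    base_amp: float = 2.5  # m/s^2
    noise_sd: float = 0.15  # m/s^2 (gyro noise is noise_sd/10 rad/s)
    walk_speed: float = 1.1  # m/s
    course_length: float = 10.0  # m per straight leg
    turn_duration: float = 2.5  # s
    turn_angle: float = 180.0  # deg
    device_quat: np.ndarray | None = None  # scalar-first; None -> random fixed
    fs: float = 100.0  # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.6 <= self.stride_time_mean <= 2.0):
            raise ValueError("stride_time_mean must be in [0.6, 2.0] s")
        if not (0.0 <= self.stride_time_cv <= 0.2):
            raise ValueError("stride_time_cv must be in [0, 0.2]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.walk_speed <= 0 or self.course_length <= 0 or self.turn_duration <= 0:
            raise ValueError("walk_speed, course_length, turn_duration must be > 0")
        if self.device_quat is not None:
            q = np.asarray(self.device_quat, dtype=float)
            if q.shape != (4,) or abs(np.linalg.norm(q) - 1.0) > 1e-6:
                raise ValueError("device_quat must be a unit 4-vector (scalar-first)")
            self.device_quat = q


@dataclass
class SyntheticGroundTruth:
    """Exact event times and trial geometry known to the simulator."""

    heel_strikes_true: np.ndarray
    toe_offs_true: np.ndarray
    stride_times_true: np.ndarray  # == diff(heel_strikes_true)
    turn_interval: tuple
    device_quat: np.ndarray
    earth_vertical_acc: np.ndarray  # noiseless reference series
    t: np.ndarray

    def to_dict(self) -> dict:
        return {
            "heel_strikes_true": self.heel_strikes_true.tolist(),
            "toe_offs_true": self.toe_offs_true.tolist(),
            "stride_times_true": self.stride_times_true.tolist(),
            "turn_interval": list(self.turn_interval),
            "device_quat": self.device_quat.tolist(),
        }


@dataclass
class SimulatedTrial:
    participant_id: str
    trial_index: int
    condition: str
    trial: IMUTrial
    truth: SyntheticGroundTruth


def random_quaternion(rng: np.random.Generator) -> np.ndarray:
    """Uniform random unit quaternion (scalar-first)."""
    q = rng.normal(size=4)
    return q / np.linalg.norm(q)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Normal draws truncated at +-3 SD by rejection (deterministic per rng)."""
    if sd == 0:
        return np.full(size, mean)
    out = rng.normal(mean, sd, size)
    bad = np.abs(out - mean) > 3 * sd
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, int(np.sum(bad)))
        bad = np.abs(out - mean) > 3 * sd
    return out


def _turn_rate_profile(t: np.ndarray, t0: float, duration: float, angle_deg: float) -> np.ndarray:
    """Constant-rate yaw with cosine ramps, integrating exactly to angle_deg."""
    ramp = min(0.3, duration / 3.0)
    omega_c = np.deg2rad(angle_deg) / (duration - ramp)
    u = t - t0
    out = np.zeros_like(t)
    rising = (u >= 0) & (u < ramp)
    plateau = (u >= ramp) & (u <= duration - ramp)
    falling = (u > duration - ramp) & (u <= duration)
    out[rising] = omega_c * 0.5 * (1 - np.cos(np.pi * u[rising] / ramp))
    out[plateau] = omega_c
    out[falling] = omega_c * 0.5 * (1 - np.cos(np.pi * (duration - u[falling]) / ramp))
    return out


def _amplitude_envelope(t: np.ndarray, t0: float, t1: float, damp: float = 0.5) -> np.ndarray:
    """Smooth 1 -> damp -> 1 envelope over the turn interval (0.3 s ramps)."""
    ramp = min(0.3, (t1 - t0) / 3.0)
    env = np.ones_like(t)
    inside = (t >= t0 + ramp) & (t <= t1 - ramp)
    env[inside] = damp
    rising = (t >= t0) & (t < t0 + ramp)
    env[rising] = 1 - (1 - damp) * 0.5 * (1 - np.cos(np.pi * (t[rising] - t0) / ramp))
    falling = (t > t1 - ramp) & (t <= t1)
    env[falling] = 1 - (1 - damp) * 0.5 * (1 - np.cos(np.pi * (t1 - t[falling]) / ramp))
    return env


def simulate_trial(
    params: GaitSimParams,
    condition: str = "single_task",
    trial_id: str = "sim-trial",
    attach_quat: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[IMUTrial, SyntheticGroundTruth]:
    """Simulate one out-turn-back walking trial.

    Returns the device-frame :class:`IMUTrial` together with the exact
    ground truth.  ``rng`` overrides ``params.seed`` (used by the cohort
    generator to stream child seeds).
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    q_dev = (
        params.device_quat
        if params.device_quat is not None
        else random_quaternion(rng)
    )

    leg = params.course_length / params.walk_speed
    turn_t0 = leg
    turn_t1 = leg + params.turn_duration
    total = 2 * leg + params.turn_duration
    t = np.arange(int(np.floor(total * params.fs)) + 1) / params.fs

    # stride clock
    mean, sd = params.stride_time_mean, params.stride_time_cv * params.stride_time_mean
    n_strides = int(np.ceil(total / max(mean - 3 * sd, 0.1))) + 2
    durations = _truncated_normal(rng, mean, sd, n_strides)
    starts = np.concatenate([[0.0], np.cumsum(durations)])
    phase_knots = 2.0 * np.pi * np.arange(len(starts))
    phase = np.interp(t, starts, phase_knots)

    asym = params.step_asymmetry
    env = _amplitude_envelope(t, turn_t0, turn_t1)
    vertical = env * params.base_amp * (np.cos(2 * phase) + asym * np.cos(phase))
    ap = env * 0.4 * params.base_amp * np.sin(2 * phase + 0.7)
    ml = env * 0.25 * params.base_amp * np.sin(phase + 0.3)
    acc_earth = np.column_stack([ap, ml, vertical])

    omega_z = _turn_rate_profile(t, turn_t0, params.turn_duration, params.turn_angle)
    omega_x = 0.2 * np.sin(phase)
    omega_y = 0.3 * np.sin(2 * phase)
    gyro_earth = np.column_stack([omega_x, omega_y, omega_z])

    # analytic ground-truth events: troughs of cos(2p) + asym*cos(p) at
    # cos(p) = -asym/4; heel strike follows the HIGH peak (phase 0)
    theta_hs = float(np.arccos(-asym / 4.0))
    k = np.arange(len(durations))
    hs_phases = 2.0 * np.pi * k + theta_hs
    to_phases = 2.0 * np.pi * k + (2.0 * np.pi - theta_hs)
    hs_times = np.interp(hs_phases, phase_knots, starts)
    to_times = np.interp(to_phases, phase_knots, starts)
    hs_times = hs_times[hs_times <= t[-1]]
    to_times = to_times[to_times <= t[-1]]

    acc_noisy = acc_earth + rng.normal(0.0, params.noise_sd, acc_earth.shape)
    gyro_noisy = gyro_earth + rng.normal(0.0, params.noise_sd / 10.0, gyro_earth.shape)
    acc_noisy[:, 2] += G

    rot = Rotation.from_quat(q_dev, scalar_first=True)
    acc_dev = rot.inv().apply(acc_noisy)
    gyro_dev = rot.inv().apply(gyro_noisy)

    trial = IMUTrial(
        trial_id=trial_id,
        condition=condition,
        t=t,
        acc=acc_dev,
        gyro=gyro_dev,
        quat=np.tile(q_dev, (len(t), 1)) if attach_quat else None,
        fs_nominal=params.fs,
        meta={"synthetic": True},
    )
    truth = SyntheticGroundTruth(
        heel_strikes_true=hs_times,
        toe_offs_true=to_times,
        stride_times_true=np.diff(hs_times),
        turn_interval=(turn_t0, turn_t1),
        device_quat=np.asarray(q_dev, dtype=float),
        earth_vertical_acc=vertical,
        t=t,
    )
    return trial, truth


def default_params(condition: str, seed: int = 0, **overrides) -> GaitSimParams:
    """Cohort-typical parameters for a condition, with overrides."""
    if condition == "single_task":
        base = dict(SINGLE_TASK_DEFAULTS)
        base["walk_speed"] = STRIDE_LENGTH_SINGLE / base["stride_time_mean"]
    elif condition == "dual_task":
        base = dict(DUAL_TASK_DEFAULTS)
        base["walk_speed"] = STRIDE_LENGTH_DUAL / base["stride_time_mean"]
    else:
        raise ValueError(f"unknown condition {condition!r}")
    base.update(overrides)
    return GaitSimParams(seed=seed, **base)


def simulate_participant(
    params_single: GaitSimParams | None = None,
    params_dual: GaitSimParams | None = None,
    n_trials: int = 2,
    seed: "int | np.random.SeedSequence" = 0,
    participant_id: str = "P001",
    attach_quat: bool = False,
) -> list[SimulatedTrial]:
    """Simulate one participant's paired assessments (default: 2 x 2 trials).

    Each trial gets its own child RNG stream and its own random fixed phone
    orientation unless the params pin one.
    """
    params_single = params_single or default_params("single_task")
    params_dual = params_dual or default_params("dual_task")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(2 * n_trials)
    out: list[SimulatedTrial] = []
    for trial_index in range(1, n_trials + 1):
        for condition, params in (("single_task", params_single), ("dual_task", params_dual)):
            child = children[len(out)]
            rng = np.random.default_rng(child)
            trial, truth = simulate_trial(
                params,
                condition=condition,
                trial_id=f"{participant_id}-{condition}-{trial_index}",
                attach_quat=attach_quat,
                rng=rng,
            )
            trial.meta.update({"participant_id": participant_id, "trial_index": trial_index})
            out.append(SimulatedTrial(participant_id, trial_index, condition, trial, truth))
    return out


def simulate_cohort_table(
    n_participants: int = 52,
    effect_spec: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-participant covariates, clinical scores and true gait parameters.

    A latent severity factor z drives stride-time variability directly
    (true CV = base + spread * z) and each clinical score with the
    standardized loading given in ``effect_spec`` (keys ``updrs3``,
    ``moca``, ``hama``, ``hamd``; MoCA loadings should be negative — worse
    cognition with higher severity).  Scores are Normal with the cohort's
    mean/SD; the non-severity part of each score is independent noise.
    """
    effects = {"updrs3": 0.0, "moca": 0.0, "hama": 0.0, "hamd": 0.0}
    if effect_spec:
        unknown = set(effect_spec) - set(effects)
        if unknown:
            raise ValueError(f"unknown effect_spec keys: {sorted(unknown)}")
        effects.update(effect_spec)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])

    n = n_participants
    age = np.clip(rng.normal(63, 10, n), 40, 83)
    sex = (rng.random(n) < 0.37).astype(int)  # 1 = female
    education = np.clip(rng.normal(11, 3, n), 0, 22)

    z = rng.normal(size=n)  # latent severity
    cv_single = np.clip(0.03 + 0.01 * z, 0.008, 0.12)
    cv_dual = np.clip(0.05 + 0.015 * z, 0.01, 0.15)
    stride_single = np.clip(rng.normal(1.09, 0.08, n), 0.8, 1.6)
    stride_dual = stride_single + np.clip(rng.normal(0.08, 0.089, n), -0.15, 0.4)
    stride_dual = np.clip(stride_dual, 0.8, 1.9)

    score_dists = {"updrs3": (38.3, 15.1), "moca": (22.0, 4.0), "hama": (11.8, 4.0), "hamd": (11.1, 5.1)}
    scores = {}
    for name, (mu, sigma) in score_dists.items():
        lam = float(np.clip(effects[name], -1.0, 1.0))
        eps = rng.normal(size=n)
        scores[name] = mu + sigma * (lam * z + np.sqrt(1.0 - lam**2) * eps)

    df = pd.DataFrame(
        {
            "participant_id": [f"P{i + 1:03d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "education_years": education,
            "updrs3": scores["updrs3"],
            "moca": scores["moca"],
            "hama": scores["hama"],
            "hamd": scores["hamd"],
            "true_severity": z,
            "true_cv_single": cv_single,
            "true_cv_dual": cv_dual,
            "true_stride_time_single": stride_single,
            "true_stride_time_dual": stride_dual,
        }
    )
    if n < 10:
        df.attrs["warnings"] = ["small_cohort: regressions unstable below n=10"]
    return df


def simulate_cohort(
    n_participants: int = 52,
    effect_spec: dict | None = None,
    seed: int = 0,
    n_trials: int = 2,
    attach_quat: bool = False,
) -> tuple[pd.DataFrame, list[SimulatedTrial]]:
    """Full cohort: participant table plus simulated IMU trials.

    Every participant walks ``n_trials`` assessments of each condition with
    their own true stride time and CV; all randomness descends from ``seed``.
    """
    table = simulate_cohort_table(n_participants, effect_spec, seed)
    participant_seeds = np.random.SeedSequence(seed).spawn(n_participants + 1)[1:]
    trials: list[SimulatedTrial] = []
    for i, row in table.iterrows():
        p_single = GaitSimParams(
            stride_time_mean=float(row.true_stride_time_single),
            stride_time_cv=float(row.true_cv_single),
            walk_speed=STRIDE_LENGTH_SINGLE / float(row.true_stride_time_single),
        )
        p_dual = GaitSimParams(
            stride_time_mean=float(row.true_stride_time_dual),
            stride_time_cv=float(row.true_cv_dual),
            walk_speed=STRIDE_LENGTH_DUAL / float(row.true_stride_time_dual),
        )
        trials.extend(
            simulate_participant(
                p_single,
                p_dual,
                n_trials=n_trials,
                seed=participant_seeds[i],
                participant_id=str(row.participant_id),
                attach_quat=attach_quat,
            )
        )
    return table, trials
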