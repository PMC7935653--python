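"""Orientation estimation, Earth-frame rotation and zero-phase filtering."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pocketgait import (
    GaitSimParams,
    IMUTrial,
    RunConfig,
    default_params,
    estimate_orientation,
    lowpass,
    rotate_to_earth,
    simulate_trial,
)
from pocketgait.errors import OrientationError
from pocketgait.pipeline import analyze_trial
from pocketgait.preprocess import EarthFrameSignal
from pocketgait.simulate import random_quaternion


def static_trial(acc_vec, n=500, fs=100.0, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    acc = np.tile(acc_vec, (n, 1)) + rng.normal(0, noise, (n, 3))
    return IMUTrial("static", "single_task", np.arange(n) / fs, acc, np.zeros((n, 3)))


def test_provided_quaternions_returned_verbatim():
    trial, _ = simulate_trial(GaitSimParams(seed=1), attach_quat=True)
    quat = estimate_orientation(trial)
    assert quat is trial.quat


def test_flat_phone_gives_identity_tilt():
    trial = static_trial([0.0, 0.0, 9.81])
    quat = estimate_orientation(trial)
    rotated = Rotation.from_quat(quat, scalar_first=True).apply(trial.acc)
    np.testing.assert_allclose(rotated[:, 2], 9.81, atol=1e-9)


def test_phone_rotated_90_degrees_about_x():
    # gravity along device +Y: rotation must bring it to Earth +Z
    trial = static_trial([0.0, 9.81, 0.0])
    quat = estimate_orientation(trial)
    rotated = Rotation.from_quat(quat, scalar_first=True).apply(trial.acc)
    np.testing.assert_allclose(rotated[len(rotated) // 2], [0, 0, 9.81], atol=1e-6)


def test_free_fall_input_is_estimation_error():
    trial = static_trial([0.0, 0.0, 0.05])
    with pytest.raises(OrientationError, match="free-fall"):
        estimate_orientation(trial)


def test_short_trial_is_estimation_error():
    trial = static_trial([0.0, 0.0, 9.81], n=150)
    with pytest.raises(OrientationError, match="2 s"):
        estimate_orientation(trial)


def test_rotation_is_isometry():
    """Per-sample acceleration norms are preserved before gravity removal."""
    trial, _ = simulate_trial(GaitSimParams(seed=5))
    quat = estimate_orientation(trial)
    cfg = RunConfig(gravity_g=0.0)  # keep gravity in, to compare raw norms
    sig = rotate_to_earth(trial, quat, cfg)
    # compare on the original sample grid (before interpolation)
    rotated = Rotation.from_quat(quat, scalar_first=True).apply(trial.acc)
    np.testing.assert_allclose(
        np.linalg.norm(rotated, axis=1), np.linalg.norm(trial.acc, axis=1), atol=1e-9
    )
    assert sig.fs == trial.fs_nominal


def test_gravity_removed_vertical_mean_near_zero():
    trial, _ = simulate_trial(GaitSimParams(seed=2))
    sig = rotate_to_earth(trial, estimate_orientation(trial))
    assert abs(np.mean(sig.vertical_acc)) < 0.1


def test_random_fixed_orientation_recovered():
    """A trial pre-rotated by a random fixed quaternion yields the original
    Earth-frame vertical acceleration (noiseless, RMS < 0.05 m/s^2)."""
    rng = np.random.default_rng(7)
    q = random_quaternion(rng)
    params = GaitSimParams(seed=7, noise_sd=0.0, device_quat=q)
    trial, truth = simulate_trial(params)
    sig = rotate_to_earth(trial, estimate_orientation(trial))
    n = min(len(sig.t), len(truth.earth_vertical_acc))
    rms = np.sqrt(np.mean((sig.vertical_acc[:n] - truth.earth_vertical_acc[:n]) ** 2))
    assert rms < 0.05


def test_orientation_invariance_of_stride_time():
    """Pipeline stride time moves < 2 ms under any fixed re-orientation."""
    rng = np.random.default_rng(42)
    means = []
    for _ in range(3):
        params = GaitSimParams(seed=5, device_quat=random_quaternion(rng))
        trial, _ = simulate_trial(params)
        means.append(analyze_trial(trial).record.stride_time_mean)
    assert max(means) - min(means) < 0.002


def test_length_mismatch_rejected():
    trial, _ = simulate_trial(GaitSimParams(seed=1))
    from pocketgait.errors import TrialValidationError

    with pytest.raises(TrialValidationError):
        rotate_to_earth(trial, np.tile([1.0, 0, 0, 0], (10, 1)))


# --- filtering ----------------------------------------------------------------


def sine_signal(freq, fs=100.0, dur=30.0):
    t = np.arange(int(dur * fs)) / fs
    z = np.sin(2 * np.pi * freq * t)
    return EarthFrameSignal(
        t=t, acc_earth=np.column_stack([z, z, z]), gyro_earth=np.zeros((len(t), 3)), fs=fs
    )


def measured_amplitude(sig, freq):
    """Least-squares sinusoid amplitude on the central half of the trace."""
    n = len(sig.t)
    sl = slice(n // 4, 3 * n // 4)
    t = sig.t[sl]
    design = np.column_stack([np.sin(2 * np.pi * freq * t), np.cos(2 * np.pi * freq * t)])
    coef, *_ = np.linalg.lstsq(design, sig.vertical_acc[sl], rcond=None)
    return float(np.hypot(*coef))


def butterworth_zero_phase_gain(freq, cutoff=3.0, order=4):
    """Analytic magnitude response of the forward-backward Butterworth."""
    return 1.0 / (1.0 + (freq / cutoff) ** (2 * order))


def test_dc_gain_is_unity():
    t = np.arange(1000) / 100.0
    sig = EarthFrameSignal(t=t, acc_earth=np.full((1000, 3), 2.5),
                           gyro_earth=np.zeros((1000, 3)), fs=100.0)
    out = lowpass(sig)
    np.testing.assert_allclose(out.acc_earth, 2.5, atol=1e-9)
    assert out.filtered and out.cutoff == 3.0


@pytest.mark.parametrize("freq", [0.3, 0.6, 0.9, 1.2, 1.5, 1.8, 2.1, 2.4, 2.7, 2.9])
def test_passband_gain_matches_analytic_response(freq):
    out = lowpass(sine_signal(freq))
    expected = butterworth_zero_phase_gain(freq)
    assert measured_amplitude(out, freq) == pytest.approx(expected, rel=0.02)


def test_one_hz_sinusoid_passes_within_one_percent():
    out = lowpass(sine_signal(1.0))
    assert measured_amplitude(out, 1.0) == pytest.approx(1.0, abs=0.01)


def test_stopband_attenuation_bound_and_ordering():
    amps = []
    for freq in (5.0, 10.0, 20.0):
        out = lowpass(sine_signal(freq))
        amp = measured_amplitude(out, freq)
        assert amp <= butterworth_zero_phase_gain(freq) * 1.05
        amps.append(amp)
    assert amps[0] > amps[1] > amps[2]


def test_cutoff_above_nyquist_rejected():
    with pytest.raises(ValueError, match="twice the cutoff"):
        lowpass(sine_signal(1.0, fs=5.0), cutoff=3.0)
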