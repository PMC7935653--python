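"""Turn removal and gait-event detection from the filtered vertical acceleration.

The protocol is 10 m out, a 180-degree turn, 10 m back; gait is analysed only
during straight-line walking.  Turns are found by integrating the Earth-frame
vertical angular rate over a sliding window and flagging windows whose
cumulative yaw exceeds a threshold set safely below 180 degrees; flagged
spans are merged and their edges refined to where the yaw rate is actually
elevated.

Within each straight segment the filtered vertical acceleration of a pocket
phone oscillates with alternating higher and lower peaks — the two steps of
one stride load the phone-side and contralateral legs differently.  Local
maxima are picked with a prominence floor tied to the local signal spread
and a spacing floor above the physiological step-rate limit, classified
high/low against the median of their neighbouring peaks with strict
alternation enforced, and the phone-side events are then read off: the heel
strike is the trough nadir following each HIGH peak, the toe-off the trough
nadir following each LOW peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.signal import find_peaks, peak_prominences

from .config import RunConfig
from .errors import InsufficientGaitError
from .preprocess import EarthFrameSignal


@dataclass
class TurnInterval:
    t_start: float
    t_end: float
    yaw_change_deg: float

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ValueError("turn interval must have t_end > t_start")


@dataclass
class GaitEvents:
    """Straight-walking segments, classified peaks and phone-side gait events."""

    segments: list  # list of (t_start, t_end)
    peak_times: np.ndarray
    peak_amplitudes: np.ndarray
    peak_classes: np.ndarray  # 'high' / 'low'
    heel_strikes: np.ndarray  # s, strictly increasing
    toe_offs: np.ndarray
    heel_strike_segments: np.ndarray  # segment index per heel strike
    toe_off_segments: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def _merge_runs(mask: np.ndarray, gap: int) -> list[tuple[int, int]]:
    """Index runs of True in ``mask``, merging runs separated by < gap samples."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    runs: list[list[int]] = [[idx[0], idx[0]]]
    for i in idx[1:]:
        if i - runs[-1][1] < gap:
            runs[-1][1] = i
        else:
            runs.append([i, i])
    return [(a, b) for a, b in runs]


def detect_turns(sig: EarthFrameSignal, config: RunConfig | None = None) -> list[TurnInterval]:
    """Detect 180-degree turns from the vertical angular rate.

    Works on the unfiltered Earth-frame gyroscope so the turn plateau is not
    smeared by the gait-band filter.
    """
    config = config or RunConfig()
    fs = sig.fs
    omega_z = sig.vertical_rate
    yaw = integrate.cumulative_trapezoid(omega_z, sig.t, initial=0.0)

    w = max(int(round(config.turn_window_s * fs)), 2)
    thr = np.deg2rad(config.turn_yaw_threshold_deg)
    n = len(yaw)
    if n <= w:
        window_delta = np.array([abs(yaw[-1] - yaw[0])])
        starts = np.array([0])
    else:
        window_delta = np.abs(yaw[w:] - yaw[:-w])
        starts = np.arange(n - w)
    mask = np.zeros(n, dtype=bool)
    for s in starts[window_delta >= thr]:
        mask[s : s + w + 1] = True

    # smooth rate for edge refinement (0.3 s moving average)
    k = max(int(round(0.3 * fs)), 1)
    rate = np.convolve(np.abs(omega_z), np.ones(k) / k, mode="same")

    turns: list[TurnInterval] = []
    for a, b in _merge_runs(mask, max(int(round(0.5 * fs)), 1)):
        peak_rate = float(np.max(rate[a : b + 1]))
        floor = max(np.deg2rad(15.0), 0.2 * peak_rate)
        active = np.flatnonzero(rate[a : b + 1] >= floor)
        if active.size == 0:
            continue
        i0, i1 = a + active[0], a + active[-1]
        if i1 <= i0:
            continue
        yaw_change = np.rad2deg(yaw[i1] - yaw[i0])
        if abs(yaw_change) < config.turn_yaw_threshold_deg:
            continue
        turns.append(TurnInterval(float(sig.t[i0]), float(sig.t[i1]), float(yaw_change)))
    return turns


def straight_segments(
    sig: EarthFrameSignal,
    turns: list[TurnInterval],
    margin_s: float | None = None,
    min_len_s: float | None = None,
    config: RunConfig | None = None,
) -> list[tuple[float, float]]:
    """Trial span minus margin-dilated turns; segments shorter than the
    minimum length are discarded."""
    config = config or RunConfig()
    margin = margin_s if margin_s is not None else config.turn_margin_s
    min_len = min_len_s if min_len_s is not None else config.segment_min_len_s

    t0, t1 = float(sig.t[0]), float(sig.t[-1])
    blocked = sorted(
        (max(t0, turn.t_start - margin), min(t1, turn.t_end + margin)) for turn in turns
    )
    segments: list[tuple[float, float]] = []
    cursor = t0
    for a, b in blocked:
        if a > cursor:
            segments.append((cursor, a))
        cursor = max(cursor, b)
    if cursor < t1:
        segments.append((cursor, t1))
    return [(a, b) for a, b in segments if (b - a) >= min_len]


def _classify_peaks(amps: np.ndarray) -> np.ndarray:
    """Label peaks 'high'/'low' with strict alternation.

    Each peak gets a score = amplitude minus the median of its (up to 4)
    surrounding peaks.  Under strict alternation only two labelings exist
    per segment — even peaks high or odd peaks high — so the one that
    agrees best with the scores (maximum total signed score) is chosen.
    """
    n = len(amps)
    scores = np.empty(n)
    for i in range(n):
        neigh = [amps[j] for j in (i - 2, i - 1, i + 1, i + 2) if 0 <= j < n]
        scores[i] = amps[i] - np.median(neigh) if neigh else 0.0
    signs = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
    if np.sum(signs * scores) >= 0:
        labels = np.where(signs > 0, "high", "low")
    else:
        labels = np.where(signs > 0, "low", "high")
    return labels


def _refine_minimum(y: np.ndarray, i: int) -> float:
    """Sub-sample position of a local minimum by parabolic interpolation."""
    if i <= 0 or i >= len(y) - 1:
        return float(i)
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom <= 0:
        return float(i)
    return float(i + 0.5 * (y[i - 1] - y[i + 1]) / denom)


def detect_gait_events(
    sig: EarthFrameSignal,
    segments: list[tuple[float, float]],
    config: RunConfig | None = None,
) -> GaitEvents:
    """Find phone-side heel strikes and toe-offs in the filtered vertical
    acceleration within each straight-walking segment."""
    config = config or RunConfig()
    if not sig.filtered:
        raise ValueError("detect_gait_events requires a low-pass filtered signal")
    fs = sig.fs
    z = sig.vertical_acc

    # local spread of the signal, for the prominence floor
    win = max(int(round(config.events_iqr_window_s * fs)), 3)
    series = pd.Series(z)
    q75 = series.rolling(win, center=True, min_periods=1).quantile(0.75).to_numpy()
    q25 = series.rolling(win, center=True, min_periods=1).quantile(0.25).to_numpy()
    iqr = q75 - q25

    min_spacing = max(int(round(config.events_min_spacing_s * fs)), 1)
    trim = config.events_edge_trim_s

    peak_times: list[float] = []
    peak_amps: list[float] = []
    peak_cls: list[str] = []
    heel_strikes: list[float] = []
    toe_offs: list[float] = []
    hs_seg: list[int] = []
    to_seg: list[int] = []
    total_peaks_best = 0

    for seg_idx, (a, b) in enumerate(segments):
        i0 = int(np.searchsorted(sig.t, a, side="left"))
        i1 = int(np.searchsorted(sig.t, b, side="right"))
        zs = z[i0:i1]
        if len(zs) < 3:
            continue
        peaks, _ = find_peaks(zs, distance=min_spacing)
        if peaks.size:
            prom = peak_prominences(zs, peaks)[0]
            keep = prom >= config.events_min_prominence_factor * iqr[i0 + peaks]
            peaks = peaks[keep]
        total_peaks_best = max(total_peaks_best, peaks.size)
        if peaks.size < 4:
            continue

        labels = _classify_peaks(zs[peaks])
        t_seg = sig.t[i0:i1]
        for j, (p, lab) in enumerate(zip(peaks, labels)):
            peak_times.append(float(t_seg[p]))
            peak_amps.append(float(zs[p]))
            peak_cls.append(str(lab))
            if j + 1 >= len(peaks):
                continue  # no following trough inside the segment
            lo = p + int(np.argmin(zs[p : peaks[j + 1] + 1]))
            pos = _refine_minimum(zs, lo)
            t_event = float(t_seg[0] + pos / fs)
            if t_event < a + trim or t_event > b - trim:
                continue
            if lab == "high":
                heel_strikes.append(t_event)
                hs_seg.append(seg_idx)
            else:
                toe_offs.append(t_event)
                to_seg.append(seg_idx)

    if total_peaks_best < 4:
        raise InsufficientGaitError(
            "fewer than 4 acceleration peaks in every straight segment"
        )

    return GaitEvents(
        segments=list(segments),
        peak_times=np.asarray(peak_times),
        peak_amplitudes=np.asarray(peak_amps),
        peak_classes=np.asarray(peak_cls, dtype=object),
        heel_strikes=np.asarray(heel_strikes),
        toe_offs=np.asarray(toe_offs),
        heel_strike_segments=np.asarray(hs_seg, dtype=int),
        toe_off_segments=np.asarray(to_seg, dtype=int),
    )
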