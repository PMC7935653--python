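"""End-to-end analysis glue: trial -> Earth frame -> events -> metrics.

Also provides the evaluation helpers used for validity studies against
simulator ground truth: the reference metrics are computed from the true
heel strikes restricted to the *same* straight-walking windows the pipeline
analysed (turn removal plus edge trim), mirroring a validation design in
which both measurement systems analyse the same straight-line walking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .errors import InsufficientStridesError
from .events import GaitEvents, detect_gait_events, detect_turns, straight_segments
from .io import IMUTrial, MetricsRecord
from .metrics import (
    STRIDE_GATE,
    DualTaskResult,
    aggregate_participant,
    dual_task_cost,
    stride_series,
    summarize,
)
from .preprocess import EarthFrameSignal, estimate_orientation, lowpass, rotate_to_earth
from .simulate import SimulatedTrial, SyntheticGroundTruth


@dataclass
class TrialAnalysis:
    record: MetricsRecord
    events: GaitEvents
    signal_filtered: EarthFrameSignal
    signal_raw: EarthFrameSignal


def analyze_trial(trial: IMUTrial, config: RunConfig | None = None) -> TrialAnalysis:
    """Run the full single-trial pipeline and return metrics plus internals."""
    config = config or RunConfig()
    quat = estimate_orientation(trial, config)
    earth = rotate_to_earth(trial, quat, config)
    filtered = lowpass(earth, config=config)
    turns = detect_turns(earth, config)  # unfiltered gyro: crisp turn edges
    segments = straight_segments(earth, turns, config=config)
    events = detect_gait_events(filtered, segments, config)
    strides = stride_series(events)
    record = summarize(strides, trial_id=trial.trial_id, condition=trial.condition)
    return TrialAnalysis(record=record, events=events, signal_filtered=filtered, signal_raw=earth)


def reference_metrics(
    truth: SyntheticGroundTruth,
    segments: list[tuple[float, float]],
    config: RunConfig | None = None,
    trial_id: str = "reference",
    condition: str = "single_task",
) -> MetricsRecord:
    """Gold-standard-analog metrics from true heel strikes.

    True events are restricted to the given straight-walking windows with
    the same edge trim the detector applies; strides never span windows.
    """
    config = config or RunConfig()
    trim = config.events_edge_trim_s
    strides: list[float] = []
    for a, b in segments:
        hs = truth.heel_strikes_true
        hs = hs[(hs >= a + trim) & (hs <= b - trim)]
        for d in np.diff(hs):
            if STRIDE_GATE[0] < d < STRIDE_GATE[1]:
                strides.append(float(d))
    if len(strides) < 2:
        raise InsufficientStridesError("fewer than 2 reference strides in the analysis windows")
    x = np.asarray(strides)
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    return MetricsRecord(
        trial_id=trial_id,
        condition=condition,
        n_strides=len(x),
        stride_time_mean=mean,
        stride_time_sd=sd,
        stride_time_variability=100.0 * sd / mean,
    )


def analyze_simulated(sim: SimulatedTrial, config: RunConfig | None = None) -> dict:
    """Analyse one simulated trial and pair it with its reference metrics."""
    analysis = analyze_trial(sim.trial, config)
    ref = reference_metrics(
        sim.truth,
        analysis.events.segments,
        config,
        trial_id=sim.trial.trial_id,
        condition=sim.condition,
    )
    return {
        "participant_id": sim.participant_id,
        "trial_index": sim.trial_index,
        "condition": sim.condition,
        "app": analysis.record,
        "ref": ref,
        "analysis": analysis,
    }


def cohort_validity_table(
    sims: list[SimulatedTrial],
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Long table of app vs reference metrics, one row per analysed trial."""
    rows = []
    for sim in sims:
        res = analyze_simulated(sim, config)
        app, ref = res["app"], res["ref"]
        rows.append(
            {
                "participant_id": res["participant_id"],
                "trial_index": res["trial_index"],
                "condition": res["condition"],
                "app_stride_time_mean": app.stride_time_mean,
                "app_stride_time_sd": app.stride_time_sd,
                "app_stride_time_variability": app.stride_time_variability,
                "app_n_strides": app.n_strides,
                "ref_stride_time_mean": ref.stride_time_mean,
                "ref_stride_time_sd": ref.stride_time_sd,
                "ref_stride_time_variability": ref.stride_time_variability,
                "ref_n_strides": ref.n_strides,
            }
        )
    return pd.DataFrame(rows)


def match_events(
    detected: np.ndarray,
    reference: np.ndarray,
    tolerance_s: float = 0.05,
) -> tuple[int, int, int]:
    """Greedy one-to-one matching of detected to reference event times.

    Returns (true positives, n detected, n reference); sensitivity is
    tp / n_reference and precision tp / n_detected.
    """
    detected = np.asarray(detected, dtype=float)
    reference = np.asarray(reference, dtype=float)
    used = np.zeros(len(reference), dtype=bool)
    tp = 0
    for d in detected:
        if not len(reference):
            break
        i = int(np.argmin(np.abs(reference - d)))
        if not used[i] and abs(reference[i] - d) <= tolerance_s:
            used[i] = True
            tp += 1
    return tp, len(detected), len(reference)


def participant_results(
    analyses: list[dict],
) -> dict[str, DualTaskResult]:
    """Aggregate per-trial app metrics into per-participant dual-task results."""
    by_participant: dict[str, dict[int, dict[str, MetricsRecord]]] = {}
    for res in analyses:
        by_participant.setdefault(res["participant_id"], {}).setdefault(
            res["trial_index"], {}
        )[res["condition"]] = res["app"]
    out: dict[str, DualTaskResult] = {}
    for pid, trials in by_participant.items():
        results = [
            dual_task_cost(pair["single_task"], pair["dual_task"])
            for pair in trials.values()
            if "single_task" in pair and "dual_task" in pair
        ]
        if results:
            out[pid] = aggregate_participant(results)
    return out
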