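"""Stride-time metrics and dual-task cost.

Stride time is the interval between two consecutive heel strikes of the same
(phone-side) foot; it is computed only within a straight-walking segment,
never across a removed turn.  Stride time variability is the within-trial
coefficient of variation, 100 * SD / mean, in percent, using the sample
(n-1) SD.  The dual-task cost (DTC) of a metric is its percent change from
the single- to the dual-task condition; positive DTC means worse dual-task
walking (longer or more variable strides).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientStridesError, UndefinedCostError
from .events import GaitEvents
from .io import MetricsRecord

#: physiological stride-duration gate (s); values outside are dropped + flagged
STRIDE_GATE = (0.3, 3.0)


@dataclass
class StrideSeries:
    """Ordered stride durations, one per consecutive heel-strike pair."""

    stride_times: np.ndarray
    segment_index: np.ndarray
    flags: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.stride_times)


def stride_series(events: GaitEvents) -> StrideSeries:
    """Successive heel-strike differences within each straight segment.

    Raises :class:`InsufficientStridesError` when no segment contains two
    heel strikes.  Out-of-gate strides (outside 0.3-3 s) are dropped and
    flagged rather than propagated.
    """
    hs = np.asarray(events.heel_strikes, dtype=float)
    seg = np.asarray(events.heel_strike_segments, dtype=int)
    strides: list[float] = []
    stride_seg: list[int] = []
    flags: list[str] = []
    for s in np.unique(seg):
        ts = hs[seg == s]
        if len(ts) < 2:
            continue
        for d in np.diff(ts):
            if STRIDE_GATE[0] < d < STRIDE_GATE[1]:
                strides.append(float(d))
                stride_seg.append(int(s))
            elif "stride_out_of_range" not in flags:
                flags.append("stride_out_of_range")
    if not strides:
        raise InsufficientStridesError("fewer than 2 heel strikes in every segment")
    return StrideSeries(
        stride_times=np.asarray(strides),
        segment_index=np.asarray(stride_seg, dtype=int),
        flags=flags,
    )


def summarize(strides: StrideSeries, trial_id: str = "", condition: str = "single_task") -> MetricsRecord:
    """Mean, sample SD and coefficient of variation (%) of stride time."""
    x = strides.stride_times
    if len(x) < 2:
        raise InsufficientStridesError("need at least 2 strides to summarise")
    flags = list(strides.flags)
    if len(x) < 5:
        flags.append("few_strides")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    return MetricsRecord(
        trial_id=trial_id,
        condition=condition,
        n_strides=len(x),
        stride_time_mean=mean,
        stride_time_sd=sd,
        stride_time_variability=100.0 * sd / mean,
        flags=flags,
    )


@dataclass
class DualTaskResult:
    """Single- and dual-task metrics for one assessment, with dual-task costs."""

    single: MetricsRecord
    dual: MetricsRecord
    dtc_stride_time: float
    dtc_variability: float

    def to_dict(self) -> dict:
        return {
            "single": self.single.to_dict(),
            "dual": self.dual.to_dict(),
            "dtc_stride_time_pct": float(self.dtc_stride_time),
            "dtc_variability_pct": float(self.dtc_variability),
        }


def dual_task_cost(single: MetricsRecord, dual: MetricsRecord) -> DualTaskResult:
    """Percent change of each metric from single- to dual-task walking."""
    if single.stride_time_mean == 0:
        raise UndefinedCostError("single-task stride time is zero; DTC undefined")
    if single.stride_time_variability == 0:
        raise UndefinedCostError("single-task stride time variability is zero; DTC undefined")
    return DualTaskResult(
        single=single,
        dual=dual,
        dtc_stride_time=100.0
        * (dual.stride_time_mean - single.stride_time_mean)
        / single.stride_time_mean,
        dtc_variability=100.0
        * (dual.stride_time_variability - single.stride_time_variability)
        / single.stride_time_variability,
    )


def _mean_record(records: list[MetricsRecord]) -> MetricsRecord:
    return MetricsRecord(
        trial_id=";".join(r.trial_id for r in records),
        condition=records[0].condition,
        n_strides=int(round(np.mean([r.n_strides for r in records]))),
        stride_time_mean=float(np.mean([r.stride_time_mean for r in records])),
        stride_time_sd=float(np.mean([r.stride_time_sd for r in records])),
        stride_time_variability=float(np.mean([r.stride_time_variability for r in records])),
        flags=sorted({f for r in records for f in r.flags}),
    )


def aggregate_participant(results: list[DualTaskResult]) -> DualTaskResult:
    """Average metrics and per-trial DTCs across a participant's assessments.

    The aggregate DTC is the mean of per-trial DTCs, not the DTC of the
    averaged metrics.
    """
    if not results:
        raise ValueError("aggregate_participant requires at least one result")
    return DualTaskResult(
        single=_mean_record([r.single for r in results]),
        dual=_mean_record([r.dual for r in results]),
        dtc_stride_time=float(np.mean([r.dtc_stride_time for r in results])),
        dtc_variability=float(np.mean([r.dtc_variability for r in results])),
    )
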