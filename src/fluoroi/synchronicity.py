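"""Population synchronicity: per-frame fraction of simultaneously active ROIs.

A ROI is active at a timepoint while some transient of it spans that time
(t_start <= t <= t_end).  The synchronicity index at frame t is the number
of active ROIs divided by the total number of detected (post-filter) ROIs,
so it lies in [0, 1].  Maximal runs of index >= threshold form synchronous
periods (default threshold 0.5: at least half the ROIs active); per period
the index peak is located and the participating ROIs are ordered by the
start time of their earliest transient peaking within the period, giving
the activation sequence of the event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .transients import Transient

__all__ = [
    "SynchronousPeriod",
    "SynchronicityProfile",
    "compute_synchronicity",
    "extract_synchronous_events",
    "activation_sequence",
    "analyze_synchronicity",
]


@dataclass
class SynchronousPeriod:
    t_begin: float
    t_end: float
    peak_time: float
    peak_value: float

    @property
    def duration(self) -> float:
        return self.t_end - self.t_begin


@dataclass
class SynchronicityProfile:
    index: np.ndarray                       # per-frame fraction in [0, 1]
    threshold: float
    frame_interval: float
    periods: list[SynchronousPeriod] = field(default_factory=list)
    activation_orders: list[list[tuple[int, float]]] = field(default_factory=list)


def compute_synchronicity(transients: list[Transient], n_rois: int,
                          n_frames: int, frame_interval: float = 1.0
                          ) -> np.ndarray:
    """index[t] = |{ROIs active at t}| / n_rois.

    The denominator is the total ROI count after false-positive removal,
    constant over time.  Sub-transients do not contribute activity windows.
    """
    if n_rois < 1:
        raise ValueError("n_rois must be >= 1")
    times = np.arange(n_frames) * frame_interval
    active: dict[int, np.ndarray] = {}
    for tr in transients:
        if tr.is_subtransient:
            continue
        win = (times >= tr.t_start) & (times <= tr.t_end)
        if tr.roi_label in active:
            active[tr.roi_label] |= win
        else:
            active[tr.roi_label] = win
    count = np.zeros(n_frames, dtype=np.int64)
    for win in active.values():
        count += win
    return count / n_rois


def extract_synchronous_events(index: np.ndarray, threshold: float = 0.5,
                               frame_interval: float = 1.0
                               ) -> list[SynchronousPeriod]:
    """Maximal runs of index >= threshold, with their peak frame (first
    frame on ties) and peak value."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    index = np.asarray(index, dtype=np.float64)
    above = index >= threshold
    periods = []
    t = 0
    n = len(index)
    while t < n:
        if not above[t]:
            t += 1
            continue
        t0 = t
        while t < n and above[t]:
            t += 1
        run = index[t0:t]
        pk = t0 + int(np.argmax(run))
        periods.append(SynchronousPeriod(
            t_begin=t0 * frame_interval,
            t_end=(t - 1) * frame_interval,
            peak_time=pk * frame_interval,
            peak_value=float(index[pk]),
        ))
    return periods


def activation_sequence(period: SynchronousPeriod,
                        transients: list[Transient]
                        ) -> list[tuple[int, float]]:
    """ROIs with a transient *peaking* inside the period, ordered by that
    transient's start time (earliest transient per ROI; ties by label).

    Returns (roi_label, t_start) pairs -- the activation order of the
    synchronous event.
    """
    first_start: dict[int, float] = {}
    for tr in transients:
        if tr.is_subtransient:
            continue
        if period.t_begin <= tr.t_peak <= period.t_end:
            cur = first_start.get(tr.roi_label)
            if cur is None or tr.t_start < cur:
                first_start[tr.roi_label] = tr.t_start
    return sorted(first_start.items(), key=lambda kv: (kv[1], kv[0]))


def analyze_synchronicity(transients: list[Transient], n_rois: int,
                          n_frames: int, frame_interval: float = 1.0,
                          threshold: float = 0.5) -> SynchronicityProfile:
    """Full synchronicity analysis: index, periods, activation orders."""
    index = compute_synchronicity(transients, n_rois, n_frames, frame_interval)
    periods = extract_synchronous_events(index, threshold, frame_interval)
    orders = [activation_sequence(p, transients) for p in periods]
    return SynchronicityProfile(index=index, threshold=threshold,
                                frame_interval=frame_interval,
                                periods=periods, activation_orders=orders)
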