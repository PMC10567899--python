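"""ROI trace integration, transient detection, kinetics and classification.

A *transient* is a discrete event on a ROI-mean dff trace: a local maximum
whose peak amplitude reaches the lowest classification edge (0.5 dff by
default).  Its extent is delimited at a configurable fraction of the peak
amplitude (50% -> FWHM, or 25%/10% for a fuller extent); crossing times are
linearly interpolated between frames, so durations have sub-frame
resolution.  Peaks contained within the span of a stronger peak are
*sub-transients* and can be excluded.  Events are classified by peak
amplitude into half-open intervals (default [0.5, 1.0), [1.0, 1.5),
[1.5, inf)); the per-class relative frequencies form the *signal
composition*.  ROIs whose trace never produces a retained transient are
false positives and are removed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import find_peaks

from .corode import Roi, RoiMap

__all__ = [
    "TransientConfig",
    "Transient",
    "integrate_roi_traces",
    "detect_transients",
    "classify_transients",
    "remove_false_positive_rois",
    "roi_statistics",
]


@dataclass
class TransientConfig:
    """Detection and classification settings.

    class_edges: ascending amplitude thresholds (dff); the lowest edge is
        also the detection threshold.
    duration_level: percent of peak amplitude at which durations are
        measured (50 = FWHM, or 25 / 10).
    exclude_subtransients: drop peaks nested inside a stronger peak's span.
    min_prominence: required peak prominence (dff); ``None`` defaults to
        half the lowest class edge.
    """

    class_edges: tuple = (0.5, 1.0, 1.5)
    duration_level: int = 50
    exclude_subtransients: bool = True
    min_prominence: float | None = None

    def validate(self) -> None:
        edges = tuple(self.class_edges)
        if len(edges) < 1 or any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("class_edges must be strictly increasing and non-empty")
        if edges[0] <= 0:
            raise ValueError("lowest class edge must be > 0")
        if self.duration_level not in (50, 25, 10):
            raise ValueError("duration_level must be 50, 25 or 10")

    @property
    def prominence(self) -> float:
        return self.min_prominence if self.min_prominence is not None \
            else self.class_edges[0] / 2.0


@dataclass
class Transient:
    """One detected event on a ROI trace.  Times in seconds (frame index x
    frame interval); amplitude and auc in dff units."""

    roi_label: int
    t_start: float
    t_peak: float
    t_end: float
    amplitude: float
    duration: float
    rise_time: float
    decay_time: float
    auc: float
    class_index: int = -1
    is_subtransient: bool = False


def integrate_roi_traces(dff: np.ndarray, rois) -> dict[int, np.ndarray]:
    """ROI-mean dff trace per ROI (boundary pixels are never in ROI pixel
    sets, so they are excluded by construction).

    ``rois`` may be a RoiMap (keys = labels) or a RoiArchive (keys = 1-based
    file order).
    """
    traces: dict[int, np.ndarray] = {}
    if isinstance(rois, RoiMap):
        items = [(r.label, r.pixels) for r in rois.rois]
    else:  # RoiArchive
        items = [(i, px) for i, px in enumerate(rois.rois.values(), start=1)]
    for label, pixels in items:
        if not pixels:
            raise ValueError(f"ROI {label} is empty")
        ys, xs = zip(*pixels)
        traces[label] = dff[:, list(ys), list(xs)].mean(axis=1)
    return traces


def _cross_time(trace: np.ndarray, level: float, peak: int, dt: float,
                direction: int) -> float:
    """Linearly interpolated time where the trace crosses ``level`` before
    (direction=-1) or after (direction=+1) the peak frame.  Clamps to the
    trace boundary when it never crosses."""
    T = len(trace)
    i = peak
    while 0 <= i + direction < T and trace[i + direction] >= level:
        i += direction
    j = i + direction
    if not 0 <= j < T:  # trace starts/ends above the level
        return i * dt
    # between frames i (>= level) and j (< level)
    frac = (trace[i] - level) / (trace[i] - trace[j])
    return (i + direction * frac) * dt


def detect_transients(trace: np.ndarray, config: TransientConfig | None = None,
                      frame_interval: float = 1.0, roi_label: int = 0
                      ) -> list[Transient]:
    """Detect and characterize transients on one ROI trace.

    Candidate peaks are local maxima with amplitude >= the lowest class edge
    and prominence >= ``config.prominence`` (plateau peaks take their center
    frame).  The crossing level is ``duration_level% x amplitude``; start /
    end are the interpolated crossings around the peak, duration their
    difference, rise/decay the peak-relative splits, and auc the trapezoidal
    integral of the positive trace over [start, end] (dff is already
    baseline-referenced, so the integration baseline is 0).
    """
    if config is None:
        config = TransientConfig()
    config.validate()
    trace = np.asarray(trace, dtype=np.float64)
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace contains non-finite samples")
    dt = frame_interval
    lowest = config.class_edges[0]
    peaks, props = find_peaks(trace, height=lowest, prominence=config.prominence,
                              plateau_size=1)
    # plateau peaks: center frame as t_peak
    centers = (props["left_edges"] + props["right_edges"]) // 2

    out: list[Transient] = []
    for p in centers:
        amp = float(trace[p])
        level = config.duration_level / 100.0 * amp
        t_start = _cross_time(trace, level, p, dt, -1)
        t_end = _cross_time(trace, level, p, dt, +1)
        if t_end <= t_start:
            continue
        i0 = int(np.ceil(t_start / dt))
        i1 = int(np.floor(t_end / dt))
        ts = np.concatenate([[t_start], np.arange(i0, i1 + 1) * dt, [t_end]])
        lev_start = level if t_start < i0 * dt else trace[i0]
        lev_end = level if t_end > i1 * dt else trace[i1]
        vs = np.concatenate([[lev_start], trace[i0:i1 + 1], [lev_end]])
        auc = float(np.trapezoid(np.maximum(vs, 0.0), ts))
        out.append(Transient(
            roi_label=roi_label,
            t_start=float(t_start),
            t_peak=float(p * dt),
            t_end=float(t_end),
            amplitude=amp,
            duration=float(t_end - t_start),
            rise_time=float(p * dt - t_start),
            decay_time=float(t_end - p * dt),
            auc=auc,
        ))

    _flag_subtransients(out)
    if config.exclude_subtransients:
        out = [t for t in out if not t.is_subtransient]
    return out


def _flag_subtransients(transients: list[Transient]) -> None:
    """A non-maximal peak occurring during the rise or decay of a stronger
    peak -- its peak time falling within the stronger event's [t_start,
    t_end] span -- is a sub-transient.  (Containment of the full crossing
    span cannot be required: a smaller peak's crossing level is lower, so
    its span is never strictly nested inside a stronger peak's.)"""
    for a in transients:
        for b in transients:
            if a is b:
                continue
            if (a.amplitude < b.amplitude and b.t_start <= a.t_peak <= b.t_end):
                a.is_subtransient = True
                break


def classify_transients(transients: list[Transient], class_edges=(0.5, 1.0, 1.5)
                        ) -> tuple[list[Transient], np.ndarray]:
    """Assign amplitude classes and compute the signal composition.

    Class i is the half-open interval [edges[i], edges[i+1]) (last interval
    unbounded).  Returns new Transient objects with ``class_index`` set, and
    the per-class relative frequencies (empty array when no transients).
    """
    edges = np.asarray(class_edges, dtype=np.float64)
    if edges.size < 1 or np.any(np.diff(edges) <= 0):
        raise ValueError("class_edges must be strictly increasing and non-empty")
    classified = []
    counts = np.zeros(edges.size, dtype=np.int64)
    for tr in transients:
        idx = int(np.searchsorted(edges, tr.amplitude, side="right")) - 1
        idx = max(idx, 0)  # retained transients always reach the lowest edge
        classified.append(replace(tr, class_index=idx))
        counts[idx] += 1
    if counts.sum() == 0:
        return classified, np.array([])
    return classified, counts / counts.sum()


def remove_false_positive_rois(roi_map: RoiMap,
                               transients_by_roi: dict[int, list[Transient]]
                               ) -> tuple[RoiMap, int]:
    """Drop ROIs with no retained transient; compact labels to 1..n.

    Returns the filtered map and the number of removed ROIs.  Idempotent,
    and never removes a ROI that still has a retained transient.
    """
    keep = [r for r in roi_map.rois
            if any(not t.is_subtransient
                   for t in transients_by_roi.get(r.label, []))]
    removed = len(roi_map.rois) - len(keep)
    labels = np.zeros_like(roi_map.labels)
    rois = []
    relabel = {}
    for new_label, r in enumerate(keep, start=1):
        labels[roi_map.labels == r.label] = new_label
        relabel[r.label] = new_label
        rois.append(Roi(label=new_label, seed=r.seed, pixels=r.pixels, area=r.area))
    new_map = RoiMap(labels=labels, boundary=roi_map.boundary.copy(), rois=rois,
                     pixel_size=roi_map.pixel_size)
    return new_map, removed


def roi_statistics(roi_labels, transients) -> dict[int, dict]:
    """Per-ROI summary: transient count, per-ROI frequency and
    inter-transient intervals.

    The per-ROI frequency is (count - 1) / (last start - first start) Hz --
    the mean rate over the active span, not over the whole recording -- and
    is only defined for ROIs with at least two transients (``None``
    otherwise).  Inter-transient intervals are successive start-time
    differences.
    """
    if isinstance(transients, dict):
        by_roi = transients
    else:
        by_roi = {}
        for tr in transients:
            by_roi.setdefault(tr.roi_label, []).append(tr)
    out: dict[int, dict] = {}
    for lab in roi_labels:
        trs = sorted((t for t in by_roi.get(lab, []) if not t.is_subtransient),
                     key=lambda t: t.t_start)
        starts = [t.t_start for t in trs]
        freq = None
        if len(starts) >= 2 and starts[-1] > starts[0]:
            freq = (len(starts) - 1) / (starts[-1] - starts[0])
        out[lab] = {
            "count": len(trs),
            "frequency": freq,
            "intervals": [b - a for a, b in zip(starts, starts[1:])],
        }
    return out
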