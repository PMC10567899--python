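"""CoRoDe: temporal-correlation-constrained region growing for ROI detection.

Seeds are the local maxima of the range projection R above the range
threshold t_R.  All seeds grow *simultaneously*: a single global priority
queue over (candidate pixel, claiming region) frontier pairs, ordered by
descending R of the candidate, pops the brightest claim first.  A candidate
joins a region only if it is still unassigned, its R clears t_R, and the
Pearson correlation between its dff time course and that of the adjacent
already-assigned pixel through which it was claimed reaches the correlation
threshold t_corr.  A pixel adjacent to two or more distinct regions when its
claim is processed becomes a *boundary pixel* and joins none.  With t_corr
= 0 the correlation test is vacuous and growth is governed by t_R alone,
approaching (but not equalling) a marker-based watershed, which is provided
here as a comparison baseline.
"""

from __future__ import annotations

import heapq
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stack_io import RoiArchive

__all__ = [
    "CorodeConfig",
    "Roi",
    "RoiMap",
    "find_seeds",
    "grow_regions",
    "watershed_baseline",
    "validate_rois",
    "roi_map_to_archive",
]

BOUNDARY_LABEL = 65535  # reserved value in exported 16-bit label maps


@dataclass
class CorodeConfig:
    """Detection parameters.

    range_threshold: minimum range-projection value (dff units) a pixel
        needs to be seeded or annexed.
    corr_threshold: minimum Pearson r (in [0, 1]) between a candidate's dff
        trace and its claiming neighbor's; 0 disables the test.
    min_roi_area: regions smaller than this many pixels are discarded.
    connectivity: 4 or 8 pixel neighborhood.
    """

    range_threshold: float = 0.6
    corr_threshold: float = 0.25
    min_roi_area: int = 4
    connectivity: int = 8

    def validate(self) -> None:
        if not 0.0 <= self.corr_threshold <= 1.0:
            raise ValueError("corr_threshold must lie in [0, 1]")
        if self.range_threshold < 0:
            raise ValueError("range_threshold must be >= 0")
        if self.min_roi_area < 1:
            raise ValueError("min_roi_area must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class Roi:
    label: int
    seed: tuple[int, int]
    pixels: frozenset
    area: float  # um^2 when calibrated, else pixels


@dataclass
class RoiMap:
    """Integer label image with boundary-pixel marks and per-ROI metadata."""

    labels: np.ndarray
    boundary: np.ndarray
    rois: list[Roi] = field(default_factory=list)
    pixel_size: float | None = None

    @property
    def n_rois(self) -> int:
        return len(self.rois)

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label


def _neighbors(connectivity: int):
    if connectivity == 4:
        return ((-1, 0), (1, 0), (0, -1), (0, 1))
    return ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))


def find_seeds(R: np.ndarray, t_R: float, connectivity: int = 8
               ) -> list[tuple[int, int]]:
    """Local maxima of R with R >= t_R, sorted by descending R.

    A plateau (connected set of equal values whose entire border is strictly
    lower) contributes one seed: the plateau member nearest its centroid
    (ties broken by (y, x) order).
    """
    R = np.asarray(R, dtype=np.float64)
    H, W = R.shape
    offs = _neighbors(connectivity)
    visited = np.zeros((H, W), dtype=bool)
    seeds: list[tuple[float, int, int]] = []
    for y0 in range(H):
        for x0 in range(W):
            if visited[y0, x0] or R[y0, x0] < t_R:
                continue
            v = R[y0, x0]
            # flood the equal-value plateau containing (y0, x0)
            plateau = []
            is_max = True
            stack = deque([(y0, x0)])
            visited[y0, x0] = True
            while stack:
                y, x = stack.popleft()
                plateau.append((y, x))
                for dy, dx in offs:
                    ny, nx = y + dy, x + dx
                    if not (0 <= ny < H and 0 <= nx < W):
                        continue
                    nv = R[ny, nx]
                    if nv == v:
                        if not visited[ny, nx]:
                            visited[ny, nx] = True
                            stack.append((ny, nx))
                    elif nv > v:
                        is_max = False
            if not is_max:
                continue
            cy = sum(p[0] for p in plateau) / len(plateau)
            cx = sum(p[1] for p in plateau) / len(plateau)
            seed = min(plateau, key=lambda p: ((p[0] - cy) ** 2 + (p[1] - cx) ** 2,
                                               p[0], p[1]))
            seeds.append((v, seed[0], seed[1]))
    seeds.sort(key=lambda s: (-s[0], s[1], s[2]))
    return [(y, x) for _, y, x in seeds]


def _normalized_traces(dff: np.ndarray) -> np.ndarray:
    """Per-pixel zero-mean unit-norm traces so Pearson r is a dot product.
    Zero-variance pixels get an all-zero row (r defined as 0)."""
    T = dff.shape[0]
    flat = dff.reshape(T, -1).astype(np.float64)
    centered = flat - flat.mean(axis=0)
    norm = np.linalg.norm(centered, axis=0)
    safe = np.where(norm > 0, norm, 1.0)
    z = centered / safe
    z[:, norm == 0] = 0.0
    return z


def grow_regions(R: np.ndarray, dff: np.ndarray, seeds, config: CorodeConfig
                 ) -> RoiMap:
    """Simultaneous correlation-constrained growth of the given seeds.

    Deterministic: the global frontier is ordered by (descending R, then
    ascending y, then x) of the candidate pixel.
    """
    config.validate()
    R = np.asarray(R, dtype=np.float64)
    H, W = R.shape
    if dff.shape[1:] != (H, W):
        raise ValueError("dff and R shapes disagree")
    offs = _neighbors(config.connectivity)
    z = _normalized_traces(dff)
    t_R, t_corr = config.range_threshold, config.corr_threshold

    labels = np.zeros((H, W), dtype=np.int32)
    boundary = np.zeros((H, W), dtype=bool)
    heap: list[tuple[float, int, int, int, int, int]] = []

    def push_neighbors(y: int, x: int, lab: int) -> None:
        for dy, dx in offs:
            ny, nx = y + dy, x + dx
            if 0 <= ny < H and 0 <= nx < W and labels[ny, nx] == 0 \
                    and not boundary[ny, nx] and R[ny, nx] >= t_R:
                heapq.heappush(heap, (-R[ny, nx], ny, nx, lab, y, x))

    seed_of: dict[int, tuple[int, int]] = {}
    for i, (sy, sx) in enumerate(seeds, start=1):
        if R[sy, sx] < t_R:
            continue
        labels[sy, sx] = i
        seed_of[i] = (sy, sx)
        push_neighbors(sy, sx, i)

    while heap:
        _, y, x, lab, vy, vx = heapq.heappop(heap)
        if labels[y, x] != 0 or boundary[y, x]:
            continue
        claimants = set()
        for dy, dx in offs:
            ny, nx = y + dy, x + dx
            if 0 <= ny < H and 0 <= nx < W and labels[ny, nx] > 0:
                claimants.add(int(labels[ny, nx]))
        if len(claimants) > 1:
            boundary[y, x] = True
            continue
        if t_corr > 0:
            r = float(z[:, vy * W + vx] @ z[:, y * W + x])
            if not r >= t_corr:
                continue
        labels[y, x] = lab
        push_neighbors(y, x, lab)

    return _finalize(labels, boundary, seed_of, config.min_roi_area)


def _finalize(labels: np.ndarray, boundary: np.ndarray,
              seed_of: dict[int, tuple[int, int]], min_area: int,
              pixel_size: float | None = None) -> RoiMap:
    """Discard undersized regions and compact labels to 1..n."""
    out = np.zeros_like(labels, dtype=np.int32)
    rois: list[Roi] = []
    next_label = 1
    for lab in sorted(seed_of):
        ys, xs = np.nonzero(labels == lab)
        if len(ys) < min_area:
            continue
        out[ys, xs] = next_label
        pixels = frozenset(zip(ys.tolist(), xs.tolist()))
        scale = pixel_size ** 2 if pixel_size else 1.0
        rois.append(Roi(label=next_label, seed=seed_of[lab], pixels=pixels,
                        area=len(pixels) * scale))
        next_label += 1
    return RoiMap(labels=out, boundary=boundary, rois=rois, pixel_size=pixel_size)


def watershed_baseline(R: np.ndarray, t_R: float, connectivity: int = 8) -> RoiMap:
    """Marker-based watershed on -R for side-by-side comparison.

    Markers are the same local-maxima seeds CoRoDe uses; flooding is
    restricted to pixels with R >= t_R.
    """
    from skimage.segmentation import watershed

    R = np.asarray(R, dtype=np.float64)
    seeds = find_seeds(R, t_R, connectivity)
    markers = np.zeros(R.shape, dtype=np.int32)
    seed_of = {}
    for i, (y, x) in enumerate(seeds, start=1):
        markers[y, x] = i
        seed_of[i] = (y, x)
    conn = 1 if connectivity == 4 else 2
    labels = watershed(-R, markers=markers, mask=R >= t_R, connectivity=conn)
    return _finalize(labels.astype(np.int32), np.zeros(R.shape, dtype=bool),
                     seed_of, min_area=1)


def validate_rois(detected: RoiMap, truth: RoiArchive, dff: np.ndarray,
                  noise_floor: float = 0.5) -> pd.DataFrame:
    """Compare detected ROIs against ground truth, one row per truth ROI.

    Each truth ROI is matched to the detected ROI of maximal pixel overlap
    (unmatched -> detected area 0).  Columns report signed / absolute /
    relative (%) area differences (detected - truth, in pixels) and the
    matched ROI's trace SNR in dB, where trace samples >= ``noise_floor``
    count as signal and the rest as noise:
    ``10 * log10(mean(signal^2) / mean(noise^2))``.
    """
    if len(truth) == 0:
        raise ValueError("empty ground-truth ROI set")
    rows = []
    det_pixels = {r.label: r.pixels for r in detected.rois}
    for name, tpix in truth.rois.items():
        overlaps = {lab: len(tpix & dpix) for lab, dpix in det_pixels.items()}
        best = max(overlaps, key=lambda k: (overlaps[k], -k)) if overlaps else None
        matched = best is not None and overlaps[best] > 0
        a_truth = len(tpix)
        a_det = len(det_pixels[best]) if matched else 0
        row = {
            "truth_roi": name,
            "matched_label": best if matched else -1,
            "area_truth_px": a_truth,
            "area_detected_px": a_det,
            "area_diff_px": a_det - a_truth,
            "abs_area_diff_px": abs(a_det - a_truth),
            "rel_area_diff_pct": abs(a_det - a_truth) / a_truth * 100.0,
            "snr_db": np.nan,
        }
        if matched:
            row["snr_db"] = trace_snr(_mean_trace(dff, det_pixels[best]), noise_floor)
        rows.append(row)
    return pd.DataFrame(rows)


def _mean_trace(dff: np.ndarray, pixels) -> np.ndarray:
    ys, xs = zip(*pixels)
    return dff[:, list(ys), list(xs)].mean(axis=1)


def trace_snr(trace: np.ndarray, noise_floor: float) -> float:
    """SNR (dB) of a ROI trace: samples >= noise_floor are signal, the rest
    noise; 10*log10 of the ratio of their mean squares."""
    trace = np.asarray(trace, dtype=np.float64)
    sig = trace[trace >= noise_floor]
    noi = trace[trace < noise_floor]
    if sig.size == 0 or noi.size == 0:
        return np.nan
    ms_noise = np.mean(noi ** 2)
    if ms_noise == 0:
        return np.inf
    return float(10.0 * np.log10(np.mean(sig ** 2) / ms_noise))


def roi_map_to_archive(roi_map: RoiMap) -> RoiArchive:
    """Convert detected regions into a named RoiArchive (source='detected')."""
    rois = {f"roi_{r.label:04d}": r.pixels for r in roi_map.rois}
    H, W = roi_map.labels.shape
    return RoiArchive(rois=rois, source="detected", height=H, width=W)
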