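"""Reading and writing image stacks, ImageJ ROI archives, and result tables.

A recording is held as a :class:`FluorescenceStack`: a ``(T, H, W)`` float
array of raw intensities plus optional spatial (``pixel_size``, um/pixel)
and temporal (``frame_interval``, s/frame) calibration.  Stacks travel to
and from disk as grayscale multi-page TIFFs (written as 32-bit float, so a
write/read round trip is bit exact).  Manually drawn ImageJ ROIs (single
``.roi`` files or ``RoiSet.zip`` archives) are rasterized onto the image
canvas by testing pixel centers against the ROI geometry.
"""

from __future__ import annotations

import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .ijroi import ROI_TYPE_NAMES, decode_roi

__all__ = [
    "FluorescenceStack",
    "RoiArchive",
    "read_stack",
    "write_stack",
    "read_imagej_rois",
    "export_tables",
]


@dataclass
class FluorescenceStack:
    """A single-channel time-lapse movie with optional calibration.

    ``data`` is indexed ``(t, y, x)``.  ``pixel_size`` is um/pixel and
    ``frame_interval`` is seconds/frame; both optional (``None`` means the
    stack is analyzed in pixel and frame units).
    """

    data: np.ndarray
    pixel_size: float | None = None
    frame_interval: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"stack must be 3D (t, y, x); got shape {self.data.shape}")
        if self.data.shape[0] < 2:
            raise ValueError("stack has fewer than 2 frames")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stack contains non-finite intensities")
        if self.pixel_size is not None and not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        if self.frame_interval is not None and not self.frame_interval > 0:
            raise ValueError("frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def height(self) -> int:
        return self.data.shape[1]

    @property
    def width(self) -> int:
        return self.data.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "FluorescenceStack":
        """Return a copy of this stack carrying new pixel data, same calibration."""
        return FluorescenceStack(
            data=data,
            pixel_size=self.pixel_size,
            frame_interval=self.frame_interval,
            name=self.name,
        )


@dataclass
class RoiArchive:
    """A named collection of pixel-mask ROIs on a fixed canvas.

    ``rois`` maps ROI name -> set of ``(y, x)`` pixel coordinates; insertion
    order is preserved.  ``source`` records whether the ROIs were imported
    (e.g. drawn in ImageJ) or detected by the pipeline.
    """

    rois: dict[str, frozenset] = field(default_factory=dict)
    source: str = "imported"
    height: int | None = None
    width: int | None = None

    def __post_init__(self) -> None:
        if self.source not in ("imported", "detected"):
            raise ValueError("source must be 'imported' or 'detected'")
        for name, pixels in self.rois.items():
            if len(pixels) == 0:
                raise ValueError(f"ROI {name!r} has an empty pixel mask")
            if self.height is not None:
                for (y, x) in pixels:
                    if not (0 <= y < self.height and 0 <= x < self.width):
                        raise ValueError(f"ROI {name!r} has out-of-bounds pixel {(y, x)}")

    def __len__(self) -> int:
        return len(self.rois)

    def names(self) -> list[str]:
        return list(self.rois)

    def masks(self) -> dict[str, np.ndarray]:
        """Rasterize all ROIs to boolean (H, W) masks."""
        if self.height is None or self.width is None:
            raise ValueError("archive has no canvas size")
        out = {}
        for name, pixels in self.rois.items():
            m = np.zeros((self.height, self.width), dtype=bool)
            ys, xs = zip(*pixels)
            m[list(ys), list(xs)] = True
            out[name] = m
        return out


def read_stack(
    path,
    frame_interval: float | None = None,
    pixel_size: float | None = None,
) -> FluorescenceStack:
    """Read a single-channel multi-page TIFF into a :class:`FluorescenceStack`.

    Explicit ``frame_interval`` / ``pixel_size`` arguments take precedence
    over anything recorded in the file.  Raises on RGB/multi-channel pages
    and on stacks with fewer than two frames.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = tifffile.imread(path)
    data = np.asarray(data)
    if data.ndim == 2:
        raise ValueError("stack has fewer than 2 frames")
    if data.ndim != 3:
        raise ValueError(
            f"expected a single-channel multi-page TIFF; got array of shape {data.shape}"
        )
    # An RGB page loads as (H, W, 3/4) and a stack of them as (T, H, W, C);
    # a trailing axis of length <= 4 on a 4D load means multi-channel data.
    return FluorescenceStack(
        data=data.astype(np.float64),
        pixel_size=pixel_size,
        frame_interval=frame_interval,
        name=path.stem,
    )


def write_stack(stack: FluorescenceStack, path) -> None:
    """Write a stack as a multi-page 32-bit float grayscale TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.data.astype(np.float32), photometric="minisblack")


def read_imagej_rois(path, height: int, width: int) -> RoiArchive:
    """Read an ImageJ ``.roi`` file or a ``.zip`` of them and rasterize.

    Each ROI is converted to its interior pixel set on a ``height x width``
    canvas by testing pixel centers ``(x + 0.5, y + 0.5)`` against the ROI
    geometry (rectangle, oval, polygon, freehand supported).  ROIs are
    clipped to the canvas; an ROI entirely outside it is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    entries: list[tuple[str, bytes]] = []
    if path.suffix.lower() == ".zip":
        with zipfile.ZipFile(path) as zf:
            for info in zf.infolist():
                if info.filename.lower().endswith(".roi"):
                    entries.append((Path(info.filename).stem, zf.read(info)))
    else:
        entries.append((path.stem, path.read_bytes()))
    if not entries:
        raise ValueError(f"no .roi entries found in {path}")

    rois: dict[str, frozenset] = {}
    for name, blob in entries:
        geom = decode_roi(blob)
        mask = _rasterize(geom, height, width)
        pixels = frozenset(zip(*np.nonzero(mask)))
        if not pixels:
            raise ValueError(f"ROI {name!r} lies entirely outside the {height}x{width} canvas")
        base, i = name, 1
        while name in rois:  # ImageJ zips can repeat names
            i += 1
            name = f"{base}-{i}"
        rois[name] = pixels
    return RoiArchive(rois=rois, source="imported", height=height, width=width)


def _rasterize(geom, height: int, width: int) -> np.ndarray:
    """Rasterize a decoded ROI geometry by the pixel-center-inside rule."""
    kind = geom["type"]
    mask = np.zeros((height, width), dtype=bool)
    top, left, bottom, right = geom["top"], geom["left"], geom["bottom"], geom["right"]
    if kind == "rectangle":
        y0, y1 = max(0, top), min(height, bottom)
        x0, x1 = max(0, left), min(width, right)
        if y1 > y0 and x1 > x0:
            mask[y0:y1, x0:x1] = True
        return mask
    if kind == "oval":
        cy, cx = (top + bottom) / 2.0, (left + right) / 2.0
        ry, rx = (bottom - top) / 2.0, (right - left) / 2.0
        if ry <= 0 or rx <= 0:
            return mask
        yy, xx = np.mgrid[0:height, 0:width]
        mask = ((yy + 0.5 - cy) / ry) ** 2 + ((xx + 0.5 - cx) / rx) ** 2 <= 1.0
        return mask
    if kind in ("polygon", "freehand"):
        from matplotlib.path import Path as MplPath

        verts = np.column_stack([geom["xs"], geom["ys"]])
        if len(verts) < 3:
            return mask
        pth = MplPath(verts)  # implicitly closed for point tests
        y0 = max(0, int(np.floor(verts[:, 1].min())))
        y1 = min(height, int(np.ceil(verts[:, 1].max())) + 1)
        x0 = max(0, int(np.floor(verts[:, 0].min())))
        x1 = min(width, int(np.ceil(verts[:, 0].max())) + 1)
        if y1 <= y0 or x1 <= x0:
            return mask
        yy, xx = np.mgrid[y0:y1, x0:x1]
        pts = np.column_stack([xx.ravel() + 0.5, yy.ravel() + 0.5])
        inside = pth.contains_points(pts).reshape(yy.shape)
        mask[y0:y1, x0:x1] = inside
        return mask
    raise ValueError(f"unsupported ImageJ ROI type: {ROI_TYPE_NAMES.get(kind, kind)!r}")


def export_tables(rois, transients, sync, out_dir, *, roi_map=None,
                  pixel_size: float | None = None) -> None:
    """Write the standard result tables (CSV) and the label-map TIFF.

    Produces ``rois.csv`` (id, area, transient count, per-ROI frequency),
    ``transients.csv`` (one row per event), ``synchronicity.csv`` (time,
    index), and, when ``roi_map`` is given, ``roi_labels.tif`` (16-bit label
    image; 0 = background, 65535 = boundary pixels).  All numbers use dot
    decimals and a fixed column order so files are locale independent.
    """
    from .transients import roi_statistics  # deferred: avoids import cycle

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    area_unit = "um2" if pixel_size else "px"
    time_unit = "s"

    tr_rows = []
    for tr in (transients or []):
        tr_rows.append({
            "roi": tr.roi_label,
            f"t_start_{time_unit}": tr.t_start,
            f"t_peak_{time_unit}": tr.t_peak,
            f"t_end_{time_unit}": tr.t_end,
            "amplitude_dff": tr.amplitude,
            f"duration_{time_unit}": tr.duration,
            f"rise_time_{time_unit}": tr.rise_time,
            f"decay_time_{time_unit}": tr.decay_time,
            "auc": tr.auc,
            "class_index": tr.class_index,
            "is_subtransient": tr.is_subtransient,
        })
    tr_cols = ["roi", f"t_start_{time_unit}", f"t_peak_{time_unit}", f"t_end_{time_unit}",
               "amplitude_dff", f"duration_{time_unit}", f"rise_time_{time_unit}",
               f"decay_time_{time_unit}", "auc", "class_index", "is_subtransient"]
    if transients is not None:
        pd.DataFrame(tr_rows, columns=tr_cols).to_csv(
            out_dir / "transients.csv", index=False, float_format="%.6g")

    if roi_map is not None or rois is not None:
        if roi_map is not None:
            areas = {r.label: r.area for r in roi_map.rois}
            labels = [r.label for r in roi_map.rois]
        else:
            # imported archive: label ROIs in file order, area = pixel count
            labels = list(range(1, len(rois) + 1))
            scale = (pixel_size ** 2) if pixel_size else 1.0
            areas = {lab: len(px) * scale
                     for lab, px in zip(labels, rois.rois.values())}
        stats = roi_statistics(labels, transients or [])
        roi_rows = []
        for lab in labels:
            st = stats[lab]
            roi_rows.append({
                "roi": lab,
                f"area_{area_unit}": areas[lab],
                "n_transients": st["count"],
                "frequency_hz": st["frequency"] if st["frequency"] is not None else "",
            })
        pd.DataFrame(roi_rows, columns=["roi", f"area_{area_unit}", "n_transients",
                                        "frequency_hz"]).to_csv(
            out_dir / "rois.csv", index=False, float_format="%.6g")

    if sync is not None:
        times = np.arange(len(sync.index)) * sync.frame_interval
        pd.DataFrame({f"time_{time_unit}": times, "index": sync.index}).to_csv(
            out_dir / "synchronicity.csv", index=False, float_format="%.6g")
        per_rows = []
        for i, p in enumerate(sync.periods):
            order = sync.activation_orders[i] if sync.activation_orders else []
            per_rows.append({
                f"t_begin_{time_unit}": p.t_begin,
                f"t_end_{time_unit}": p.t_end,
                f"peak_time_{time_unit}": p.peak_time,
                "peak_value": p.peak_value,
                "activation_order": " ".join(str(lab) for lab, _ in order),
            })
        pd.DataFrame(per_rows, columns=[f"t_begin_{time_unit}", f"t_end_{time_unit}",
                                        f"peak_time_{time_unit}", "peak_value",
                                        "activation_order"]).to_csv(
            out_dir / "synchronous_periods.csv", index=False, float_format="%.6g")

    if roi_map is not None:
        img = roi_map.labels.astype(np.uint16)
        img[roi_map.boundary] = 65535
        tifffile.imwrite(out_dir / "roi_labels.tif", img, photometric="minisblack")
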