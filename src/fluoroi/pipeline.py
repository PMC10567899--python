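"""End-to-end pipeline: preprocess -> F0 -> ROI detection -> transients ->
synchronicity -> export, driven by one config.

Every stage is deterministic; the run manifest (``manifest.json``) echoes
the fully-defaulted config plus result counts, which suffices to reproduce
a run exactly.  On any stage failure the partial outputs written so far are
removed and a stage-named error is raised.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .corode import CorodeConfig, RoiMap, find_seeds, grow_regions
from .pbase import PbaseConfig, estimate_baseline
from .preprocess import PreprocessConfig, preprocess
from .stack_io import RoiArchive, export_tables, read_imagej_rois, read_stack
from .synchronicity import analyze_synchronicity
from .transients import (TransientConfig, Transient, classify_transients,
                         detect_transients, integrate_roi_traces,
                         remove_false_positive_rois)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    """A stage failure; ``stage`` names the failing pipeline step."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    input: str = ""
    out_dir: str = "fluoroi_out"
    frame_interval: float | None = None
    pixel_size: float | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    pbase: PbaseConfig = field(default_factory=PbaseConfig)
    corode: CorodeConfig = field(default_factory=CorodeConfig)
    transients: TransientConfig = field(default_factory=TransientConfig)
    sync_threshold: float = 0.5
    roi_source: str = "detect"            # "detect" | "import"
    import_roi_path: str | None = None
    additive_detrend: bool = False        # analyze F - F0 instead of dff
    save_movies: bool = False             # also write f0/dff/range TIFFs

    def validate(self) -> None:
        if self.roi_source not in ("detect", "import"):
            raise ValueError("roi_source must be 'detect' or 'import'")
        if self.roi_source == "import" and not self.import_roi_path:
            raise ValueError("roi_source='import' requires import_roi_path")


_SECTION_TYPES = {
    "preprocess": PreprocessConfig,
    "pbase": PbaseConfig,
    "corode": CorodeConfig,
    "transients": TransientConfig,
}


def load_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file plus dotted-path overrides
    (e.g. ``{"corode.corr_threshold": 0.5}``)."""
    raw: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    for key, value in (overrides or {}).items():
        parts = key.split(".")
        node = raw
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = value

    cfg = PipelineConfig()
    for section, cls in _SECTION_TYPES.items():
        params = raw.pop(section, {}) or {}
        if not isinstance(params, dict):
            raise ValueError(f"config section {section!r} must be a mapping")
        base = getattr(cfg, section)
        for k, v in params.items():
            if not hasattr(base, k):
                raise ValueError(f"unknown key {section}.{k}")
            if k == "class_edges":
                v = tuple(v)
            setattr(base, k, v)
    sync = raw.pop("synchronicity", {}) or {}
    if "threshold" in sync:
        cfg.sync_threshold = float(sync["threshold"])
    for k, v in raw.items():
        if not hasattr(cfg, k):
            raise ValueError(f"unknown config key {k!r}")
        setattr(cfg, k, v)
    cfg.validate()
    return cfg


def _config_echo(cfg: PipelineConfig) -> dict:
    echo = asdict(cfg)
    echo["transients"]["class_edges"] = list(cfg.transients.class_edges)
    echo["preprocess"].pop("custom_denoiser", None)
    return echo


@dataclass
class PipelineResult:
    stack: object
    baseline: object
    roi_map: RoiMap | None
    roi_archive: RoiArchive | None
    traces: dict
    transients: list[Transient]
    composition: np.ndarray
    sync: object
    n_removed: int
    manifest: dict


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages in order and write the result bundle to
    ``config.out_dir``."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _cleanup() -> None:
        for p in written:
            try:
                p.unlink()
            except OSError:
                pass

    stage = "read"
    try:
        stack = read_stack(config.input, frame_interval=config.frame_interval,
                           pixel_size=config.pixel_size)
        stage = "preprocess"
        F = preprocess(stack, config.preprocess)
        stage = "pbase"
        baseline = estimate_baseline(F, config.pbase)
        dt = F.frame_interval if F.frame_interval else 1.0

        stage = "roi_detection"
        roi_map = None
        archive = None
        if config.roi_source == "detect":
            seeds = find_seeds(baseline.range_projection,
                               config.corode.range_threshold,
                               config.corode.connectivity)
            roi_map = grow_regions(baseline.range_projection, baseline.dff,
                                   seeds, config.corode)
            roi_map.pixel_size = config.pixel_size
            if config.pixel_size:
                for r in roi_map.rois:
                    r.area = len(r.pixels) * config.pixel_size ** 2
            rois_for_traces = roi_map
        else:
            archive = read_imagej_rois(config.import_roi_path,
                                       F.height, F.width)
            rois_for_traces = archive

        stage = "transients"
        if config.additive_detrend:
            signal = F.data - baseline.f0  # ratiometric inputs: F - F0
        else:
            signal = baseline.dff
        traces = integrate_roi_traces(signal, rois_for_traces)
        all_transients: list[Transient] = []
        by_roi: dict[int, list[Transient]] = {}
        for label, trace in traces.items():
            trs = detect_transients(trace, config.transients, dt, roi_label=label)
            by_roi[label] = trs
            all_transients.extend(trs)

        n_removed = 0
        if roi_map is not None:
            old_rois = list(roi_map.rois)
            roi_map, n_removed = remove_false_positive_rois(roi_map, by_roi)
            # compaction preserves label order; rebuild the old->new mapping
            relabel, new_label = {}, 1
            for r in old_rois:
                if any(not t.is_subtransient for t in by_roi.get(r.label, [])):
                    relabel[r.label] = new_label
                    new_label += 1
            all_transients = [
                Transient(**{**asdict(t), "roi_label": relabel[t.roi_label]})
                for t in all_transients if t.roi_label in relabel]
            traces = {relabel[k]: v for k, v in traces.items() if k in relabel}

        all_transients, composition = classify_transients(
            all_transients, config.transients.class_edges)

        stage = "synchronicity"
        n_rois = roi_map.n_rois if roi_map is not None else len(archive)
        sync = None
        if n_rois > 0:
            sync = analyze_synchronicity(all_transients, n_rois, F.n_frames,
                                         dt, config.sync_threshold)

        stage = "export"
        export_tables(archive if archive is not None else None,
                      all_transients, sync, out_dir, roi_map=roi_map,
                      pixel_size=config.pixel_size)
        for name in ("rois.csv", "transients.csv", "synchronicity.csv",
                     "synchronous_periods.csv", "roi_labels.tif"):
            p = out_dir / name
            if p.exists():
                written.append(p)
        if config.save_movies:
            for name, arr in (("f0.tif", baseline.f0),
                              ("dff.tif", baseline.dff)):
                tifffile.imwrite(out_dir / name, arr.astype(np.float32),
                                 photometric="minisblack")
                written.append(out_dir / name)
            tifffile.imwrite(out_dir / "range_projection.tif",
                             baseline.range_projection.astype(np.float32),
                             photometric="minisblack")
            tifffile.imwrite(out_dir / "f0_mask.tif",
                             (baseline.mask * np.uint8(255)),
                             photometric="minisblack")
            written += [out_dir / "range_projection.tif", out_dir / "f0_mask.tif"]

        manifest = {
            "version": __version__,
            "config": _config_echo(config),
            "n_frames": F.n_frames,
            "f0_mask_threshold": baseline.threshold_used,
            "n_pixels_fitted": baseline.n_fitted,
            "n_rois_detected": (roi_map.n_rois + n_removed) if roi_map is not None
                               else len(archive),
            "n_rois_removed": n_removed,
            "n_rois": n_rois,
            "n_transients": len(all_transients),
            "signal_composition": list(composition) if composition.size else [],
            "n_synchronous_periods": len(sync.periods) if sync else 0,
        }
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    except PipelineError:
        _cleanup()
        raise
    except Exception as exc:
        _cleanup()
        raise PipelineError(stage, exc) from exc

    return PipelineResult(stack=stack, baseline=baseline, roi_map=roi_map,
                          roi_archive=archive, traces=traces,
                          transients=all_transients, composition=composition,
                          sync=sync, n_removed=n_removed, manifest=manifest)


def read_transients_csv(path) -> list[Transient]:
    """Parse a ``transients.csv`` written by :func:`export_tables` back into
    Transient objects (for the stage-wise CLI)."""
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        out.append(Transient(
            roi_label=int(row["roi"]),
            t_start=float(row["t_start_s"]),
            t_peak=float(row["t_peak_s"]),
            t_end=float(row["t_end_s"]),
            amplitude=float(row["amplitude_dff"]),
            duration=float(row["duration_s"]),
            rise_time=float(row["rise_time_s"]),
            decay_time=float(row["decay_time_s"]),
            auc=float(row["auc"]),
            class_index=int(row["class_index"]),
            is_subtransient=bool(row["is_subtransient"]),
        ))
    return out
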