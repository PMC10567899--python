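"""Temporal pre-processing applied before baseline estimation.

The stack fed to baseline estimation (referred to as ``F`` downstream) is
the raw recording after optional denoising and a temporal median filter.
Edges are handled by shrinking the window rather than reflecting data, so
no values are invented at the recording boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .stack_io import FluorescenceStack

__all__ = ["PreprocessConfig", "temporal_median_filter", "preprocess"]


@dataclass
class PreprocessConfig:
    """Settings for the pre-processing stage.

    median_window: odd number of frames for the running temporal median
        (1 disables it).
    denoiser: "none" or "gaussian"; "gaussian" applies a temporal Gaussian
        of ``gaussian_sigma`` frames before the median filter.  A callable
        ``custom_denoiser(data) -> data`` may be supplied instead.
    """

    median_window: int = 3
    denoiser: str = "none"
    gaussian_sigma: float = 1.0
    custom_denoiser: Callable[[np.ndarray], np.ndarray] | None = None

    def validate(self, n_frames: int) -> None:
        if self.median_window < 1 or self.median_window % 2 == 0:
            raise ValueError("median_window must be odd and >= 1")
        if self.median_window > n_frames:
            raise ValueError("median_window exceeds the number of frames")
        if self.denoiser not in ("none", "gaussian"):
            raise ValueError(f"unknown denoiser {self.denoiser!r}")


def temporal_median_filter(stack: FluorescenceStack, window: int) -> FluorescenceStack:
    """Running median along time with a centered, edge-truncated window."""
    T = stack.n_frames
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and >= 1")
    if window > T:
        raise ValueError("window exceeds the number of frames")
    if window == 1:
        return stack.with_data(stack.data.copy())
    half = window // 2
    out = np.empty_like(stack.data)
    for t in range(T):
        lo, hi = max(0, t - half), min(T, t + half + 1)
        out[t] = np.median(stack.data[lo:hi], axis=0)
    return stack.with_data(out)


def preprocess(stack: FluorescenceStack, config: PreprocessConfig) -> FluorescenceStack:
    """Apply the configured denoiser, then the temporal median filter."""
    config.validate(stack.n_frames)
    data = stack.data
    if config.custom_denoiser is not None:
        data = np.asarray(config.custom_denoiser(data), dtype=np.float64)
        if data.shape != stack.data.shape:
            raise ValueError("custom denoiser changed the stack shape")
    elif config.denoiser == "gaussian":
        if config.gaussian_sigma > 0:
            data = gaussian_filter1d(data, config.gaussian_sigma, axis=0, mode="nearest")
    return temporal_median_filter(stack.with_data(data), config.median_window)
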