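"""PBasE: per-pixel polynomial estimation of basal fluorescence (F0).

For each pixel's time course the algorithm (1) excludes statistically large
samples (transients) with either a whole-trace mean/sigma rule or a sliding
Hampel filter, (2) simplifies the retained samples into a piecewise-constant
*guidance signal* on a dyadic scale space (scale k splits the time axis into
2**k equal sections; the finest scale feeds the fit), and (3) least-squares
fits a low-order polynomial to the guidance signal, yielding F0(t).  The
normalized movie is dff = (F - F0)/F0.

Low-activity pixels are excluded from fitting altogether by the *F0 mask*:
the temporal range of a provisional dff (per-pixel temporal-mean F0) is
thresholded -- by Otsu's method unless a value is given -- and sub-threshold
pixels keep their recorded time course as F0, so their dff is identically 0.
Masking both suppresses noise-amplified false transients in dark regions and
skips their (per-pixel, hence linear-cost) fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import polynomial as npoly
from skimage.filters import threshold_otsu

from .stack_io import FluorescenceStack

__all__ = [
    "PbaseConfig",
    "BaselineResult",
    "temporal_mean_cleanup",
    "hampel_cleanup",
    "guidance_signal",
    "guidance_scale_space",
    "fit_polynomial_baseline",
    "range_projection",
    "estimate_mask_threshold",
    "estimate_baseline",
]

MAD_SCALE = 1.4826  # consistency factor: scaled MAD estimates sigma for normal data


@dataclass
class PbaseConfig:
    """Parameters of the F0 estimation.

    cleanup: "temporal_mean" (exclude samples > mu + n_sigma*sigma of the
        whole trace) or "hampel" (sliding-window median/MAD rule).
    n_sigma: exclusion multiplier for the temporal-mean rule (unitless).
    hampel_window / hampel_n_sigma: window length (odd frames) and multiplier
        for the Hampel rule.
    max_scale: finest guidance scale m (the time axis is split into 2**m
        sections); ``None`` selects floor(log2(T)) - 2, clipped to >= 1.
    guidance_mode: per-section constant -- "minima", "maxima" or "min_error"
        (section mean, the L2-optimal constant).
    poly_degree: degree of the fitted baseline polynomial.
    mask_threshold: "otsu" or a fixed dff value applied to the provisional
        range projection; pixels below it are masked out of the fit.
    """

    cleanup: str = "temporal_mean"
    n_sigma: float = 2.0
    hampel_window: int = 11
    hampel_n_sigma: float = 3.0
    max_scale: int | None = None
    guidance_mode: str = "min_error"
    poly_degree: int = 4
    mask_threshold: float | str = "otsu"

    def resolved_scale(self, n_frames: int) -> int:
        if self.max_scale is None:
            m = int(np.floor(np.log2(n_frames))) - 2
        else:
            m = int(self.max_scale)
        m = max(1, m)
        if 2 ** m > n_frames:
            raise ValueError(f"2^max_scale ({2**m}) exceeds the {n_frames} frames")
        return m

    def validate(self, n_frames: int) -> None:
        if self.cleanup not in ("temporal_mean", "hampel"):
            raise ValueError(f"unknown cleanup mode {self.cleanup!r}")
        if self.guidance_mode not in ("minima", "maxima", "min_error"):
            raise ValueError(f"unknown guidance mode {self.guidance_mode!r}")
        if self.cleanup == "temporal_mean" and not self.n_sigma > 0:
            raise ValueError("n_sigma must be > 0")
        if self.poly_degree < 0:
            raise ValueError("poly_degree must be >= 0")
        m = self.resolved_scale(n_frames)
        if self.poly_degree + 1 > 2 ** m:
            raise ValueError("poly_degree + 1 exceeds the number of guidance sections")


@dataclass
class BaselineResult:
    """Output of :func:`estimate_baseline`.

    f0 and dff are (T, H, W); range_projection is the temporal max - min of
    the final dff; mask marks low-activity pixels (dff forced to 0 there);
    n_fitted counts the pixels that actually went through the per-pixel fit.
    """

    f0: np.ndarray
    dff: np.ndarray
    range_projection: np.ndarray
    mask: np.ndarray
    threshold_used: float
    n_fitted: int


# ---------------------------------------------------------------------------
# signal clean-up


def temporal_mean_cleanup(trace, n_sigma: float):
    """Flag samples exceeding mu + n_sigma*sigma of the entire trace.

    mu and sigma (population standard deviation) are computed once over all
    T samples.  Returns ``(trace_copy, excluded)``; retained values are
    never altered.  A constant trace (sigma = 0) excludes nothing.
    """
    trace = np.asarray(trace, dtype=np.float64)
    if trace.size < 2:
        raise ValueError("trace must have at least 2 samples")
    if not n_sigma > 0:
        raise ValueError("n_sigma must be > 0")
    excluded = _temporal_mean_excluded(trace[:, None], n_sigma)[:, 0]
    return trace.copy(), excluded


def _temporal_mean_excluded(F: np.ndarray, n_sigma: float) -> np.ndarray:
    mu = F.mean(axis=0)
    sigma = F.std(axis=0)  # population (1/T)
    return F > mu + n_sigma * sigma


def hampel_cleanup(trace, window: int, n_sigma: float):
    """Standard Hampel outlier rule on a centered, edge-truncated window.

    A sample is excluded when it deviates from the local median by more than
    ``n_sigma`` scaled MADs (MAD * 1.4826).  Returns ``(trace_copy,
    excluded)``.
    """
    trace = np.asarray(trace, dtype=np.float64)
    excluded = _hampel_excluded(trace[:, None], window, n_sigma)[:, 0]
    return trace.copy(), excluded


def _hampel_excluded(F: np.ndarray, window: int, n_sigma: float) -> np.ndarray:
    T = F.shape[0]
    if window % 2 == 0 or window < 3:
        raise ValueError("hampel window must be odd and >= 3")
    if window > T:
        raise ValueError("hampel window exceeds the number of frames")
    half = window // 2
    excluded = np.zeros(F.shape, dtype=bool)
    for t in range(T):
        lo, hi = max(0, t - half), min(T, t + half + 1)
        win = F[lo:hi]
        med = np.median(win, axis=0)
        mad = np.median(np.abs(win - med), axis=0)
        excluded[t] = np.abs(F[t] - med) > n_sigma * MAD_SCALE * mad
    return excluded


# ---------------------------------------------------------------------------
# guidance signal


def section_edges(n_frames: int, scale: int) -> np.ndarray:
    """Frame boundaries of the 2**scale equal sections of scale ``scale``.

    Section i (1-based) covers the half-open 0-based frame interval
    ``[edges[i-1], edges[i])``; boundaries are rounded to the nearest
    integer and always cover [0, T) exhaustively and disjointly.
    """
    n_sections = 2 ** scale
    if n_sections > n_frames:
        raise ValueError("coarsest sections would be empty (2^scale > T)")
    edges = np.rint(np.arange(n_sections + 1) * n_frames / n_sections).astype(int)
    edges[0], edges[-1] = 0, n_frames
    return edges


def _section_constants(values: np.ndarray, excluded: np.ndarray, scale: int,
                       mode: str):
    """Per-section constants (S, P) and retained-sample counts (S, P)."""
    T, P = values.shape
    edges = section_edges(T, scale)
    S = len(edges) - 1
    const = np.empty((S, P))
    count = np.empty((S, P), dtype=int)
    masked = np.where(excluded, np.nan, values)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN sections handled below
        for i in range(S):
            seg = masked[edges[i]:edges[i + 1]]
            count[i] = np.sum(~np.isnan(seg), axis=0)
            if mode == "minima":
                const[i] = np.nanmin(seg, axis=0)
            elif mode == "maxima":
                const[i] = np.nanmax(seg, axis=0)
            else:  # min_error: the constant minimizing squared error
                const[i] = np.nanmean(seg, axis=0)
    return const, count, edges


def _fill_empty_sections(const: np.ndarray, count: np.ndarray) -> np.ndarray:
    """Sections with no retained sample inherit the nearest non-empty
    section's value at the same scale (ties toward earlier sections)."""
    S, P = const.shape
    valid = count > 0
    if valid.all():
        return const
    if not valid.any(axis=0).all():
        bad = np.nonzero(~valid.any(axis=0))[0]
        raise ValueError(f"empty guidance section: trace {bad[0]} has no retained samples")
    idx = np.arange(S)[:, None]
    prev = np.maximum.accumulate(np.where(valid, idx, -1), axis=0)
    rev_prev = np.maximum.accumulate(np.where(valid[::-1], idx, -1), axis=0)[::-1]
    nxt = np.where(rev_prev >= 0, S - 1 - rev_prev, S)
    # distance to nearest valid on each side (large when absent)
    d_prev = np.where(prev >= 0, idx - prev, S + 1)
    d_next = np.where(nxt < S, nxt - idx, S + 1)
    pick = np.where(d_prev <= d_next, prev, nxt)  # tie -> earlier section
    filled = np.take_along_axis(const, pick, axis=0)
    return np.where(valid, const, filled)


def guidance_scale_space(trace, excluded=None, max_scale: int = 3,
                         mode: str = "min_error") -> list[np.ndarray]:
    """Piecewise-constant simplifications of a cleaned trace at scales
    1..max_scale, each evaluated at every frame."""
    trace = np.asarray(trace, dtype=np.float64)
    T = trace.size
    if excluded is None:
        excluded = np.zeros(T, dtype=bool)
    excluded = np.asarray(excluded, dtype=bool)
    out = []
    for k in range(1, max_scale + 1):
        const, count, edges = _section_constants(trace[:, None], excluded[:, None], k, mode)
        const = _fill_empty_sections(const, count)
        sig = np.repeat(const[:, 0], np.diff(edges))
        out.append(sig)
    return out


def guidance_signal(trace, excluded=None, max_scale: int = 3,
                    mode: str = "min_error") -> np.ndarray:
    """The finest-scale (k = max_scale) guidance signal of a cleaned trace."""
    return guidance_scale_space(trace, excluded, max_scale, mode)[-1]


def _guidance_batch(values: np.ndarray, excluded: np.ndarray, scale: int,
                    mode: str) -> np.ndarray:
    const, count, edges = _section_constants(values, excluded, scale, mode)
    const = _fill_empty_sections(const, count)
    return np.repeat(const, np.diff(edges), axis=0)


# ---------------------------------------------------------------------------
# polynomial fit


def _fit_axis(n_frames: int) -> np.ndarray:
    # map frame indices to [-1, 1] for conditioning
    return np.linspace(-1.0, 1.0, n_frames)


def fit_polynomial_baseline(guidance, degree: int) -> np.ndarray:
    """Least-squares polynomial of the given degree through the guidance
    signal, evaluated at every frame."""
    guidance = np.asarray(guidance, dtype=np.float64)
    T = guidance.shape[0]
    if degree + 1 > T:
        raise ValueError("degree + 1 exceeds the number of frames")
    V = npoly.polyvander(_fit_axis(T), degree)
    coef, *_ = np.linalg.lstsq(V, guidance, rcond=None)
    return V @ coef


# ---------------------------------------------------------------------------
# range projection and masking


def range_projection(dff: np.ndarray) -> np.ndarray:
    """Temporal max - min of dff per pixel; >= 0 everywhere."""
    dff = np.asarray(dff)
    return dff.max(axis=0) - dff.min(axis=0)


def estimate_mask_threshold(R: np.ndarray) -> float:
    """Otsu's between-class-variance-maximizing threshold on a 256-bin
    histogram of the range projection."""
    R = np.asarray(R)
    if np.ptp(R) == 0:
        raise ValueError("degenerate range image: all values equal")
    return float(threshold_otsu(R, nbins=256))


# ---------------------------------------------------------------------------
# full estimation


def estimate_baseline(stack: FluorescenceStack, config: PbaseConfig | None = None
                      ) -> BaselineResult:
    """Estimate F0, dff, the range projection and the activity mask.

    Pass 1 builds a provisional dff from a per-pixel temporal-mean F0 and
    thresholds its range projection into the F0 mask.  Pass 2 runs
    cleanup -> guidance -> polynomial fit on every unmasked pixel; masked
    pixels keep their recorded time course as F0 so their dff is exactly 0.
    The returned range projection is recomputed from the final dff (zero on
    masked pixels).
    """
    if config is None:
        config = PbaseConfig()
    T, H, W = stack.shape
    config.validate(T)
    m = config.resolved_scale(T)
    F = stack.data.reshape(T, H * W)

    # pass 1: provisional mean baseline -> mask
    f0_prov = F.mean(axis=0)
    if np.any(f0_prov <= 0):
        p = int(np.argmax(f0_prov <= 0))
        raise ValueError(
            f"non-positive provisional baseline at pixel (y={p // W}, x={p % W})")
    dff_prov = F / f0_prov - 1.0
    R_prov = dff_prov.max(axis=0) - dff_prov.min(axis=0)
    if config.mask_threshold == "otsu":
        threshold = estimate_mask_threshold(R_prov.reshape(H, W))
    else:
        threshold = float(config.mask_threshold)
    mask_flat = R_prov < threshold

    # pass 2: per-pixel fits on unmasked pixels only
    f0 = F.copy()  # masked pixels keep their recorded time course
    fit_cols = ~mask_flat
    n_fitted = int(fit_cols.sum())
    if n_fitted:
        sub = F[:, fit_cols]
        if config.cleanup == "temporal_mean":
            excluded = _temporal_mean_excluded(sub, config.n_sigma)
        else:
            excluded = _hampel_excluded(sub, config.hampel_window, config.hampel_n_sigma)
        guidance = _guidance_batch(sub, excluded, m, config.guidance_mode)
        fitted = fit_polynomial_baseline(guidance, config.poly_degree)
        if np.any(fitted <= 0):
            t, j = np.unravel_index(int(np.argmax(fitted <= 0)), fitted.shape)
            p = int(np.nonzero(fit_cols)[0][j])
            raise ValueError(
                f"fitted F0 <= 0 at frame {t}, pixel (y={p // W}, x={p % W}); "
                "cannot normalize")
        f0[:, fit_cols] = fitted

    dff = np.zeros_like(F)
    dff[:, fit_cols] = (F[:, fit_cols] - f0[:, fit_cols]) / f0[:, fit_cols]
    R = (dff.max(axis=0) - dff.min(axis=0)).reshape(H, W)

    return BaselineResult(
        f0=f0.reshape(T, H, W),
        dff=dff.reshape(T, H, W),
        range_projection=R,
        mask=mask_flat.reshape(H, W),
        threshold_used=threshold,
        n_fitted=n_fitted,
    )
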