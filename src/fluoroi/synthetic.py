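"""Ground-truth-annotated synthetic movies for exercising the pipeline.

The generative model mirrors the structure the analysis assumes: each pixel
carries a smooth low-order polynomial baseline F0(t) (per-pixel
coefficients), multiplicatively modulated by the summed transient activity
of the ROIs covering it, plus optional additive noise:

    movie[t, y, x] = F0(t, y, x) * (1 + dff_true[t, y, x]) + noise

dff_true is built from per-ROI transient schedules: unimodal kernels (an
alpha function, the standard calcium-transient shape, or a Gaussian) with
prescribed peak time, amplitude (dff units) and FWHM (seconds), weighted by
the ROI's spatial amplitude profile (flat or Gaussian).  An optional slow
global ramp emulates long-lasting drifts in basal fluorescence.  Every run
is reproducible from its seed, and the exact F0, dff, footprints and event
parameters are returned alongside the movie.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stack_io import FluorescenceStack

__all__ = [
    "TransientSpec",
    "SyntheticRoi",
    "SyntheticSpec",
    "GroundTruth",
    "alpha_kernel",
    "gaussian_kernel",
    "generate_movie",
    "disk_footprint",
    "generate_fig_dichotomy_fixture",
    "generate_two_event_fixture",
    "generate_population_fixture",
    "dichotomy_configs",
]

# x * exp(1 - x) = 1/2 has roots x1, x2; the alpha kernel's FWHM is
# tau * (x2 - x1), so tau = fwhm / ALPHA_FWHM_FACTOR.
ALPHA_FWHM_FACTOR = 2.4463860600063117
GAUSS_FWHM_FACTOR = 2.3548200450309493  # 2*sqrt(2*ln 2)


@dataclass
class TransientSpec:
    """One planted event: peak time (s), peak amplitude (dff), FWHM (s)."""

    t_peak: float
    amplitude: float
    fwhm: float
    kernel: str = "alpha"


@dataclass
class SyntheticRoi:
    """A spatial footprint with a shared transient schedule.

    profile "flat" gives every footprint pixel the full amplitude;
    "gaussian" scales it by exp(-d^2 / (2 sigma^2)) with d the distance to
    the footprint centroid (sigma in pixels).
    """

    footprint: frozenset
    schedule: list[TransientSpec] = field(default_factory=list)
    profile: str = "flat"
    profile_sigma: float = 3.0
    profile_center: tuple[float, float] | None = None  # default: footprint centroid


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic movie.

    baseline_coeffs: polynomial coefficients of F0 over normalized time
        x in [-1, 1]; shape (d+1,) shared by all pixels or (d+1, H, W)
        per pixel.  The resulting baseline must stay strictly positive.
    ramp: optional (start_s, height_dff) slow-rise component added to every
        pixel's dff; it grows as ((t - start)/(T_end - start))**ramp_power
        from the start time to the end of the recording.
    noise_sigma: additive Gaussian noise (intensity units); noise="poisson"
        draws photon-like noise instead, with gain 1.
    """

    shape: tuple[int, int, int]
    baseline_coeffs: np.ndarray
    rois: list[SyntheticRoi] = field(default_factory=list)
    noise_sigma: float = 0.0
    noise: str = "gaussian"
    ramp: tuple[float, float] | None = None
    ramp_power: float = 1.0
    frame_interval: float = 1.0
    pixel_size: float | None = None
    seed: int = 0


@dataclass
class GroundTruth:
    f0: np.ndarray                      # (T, H, W) noiseless baseline
    dff: np.ndarray                     # (T, H, W) true relative change
    footprints: list[np.ndarray]        # boolean (H, W) per ROI
    amplitude_maps: list[np.ndarray]    # per-ROI spatial weight (H, W)
    spec: SyntheticSpec


def alpha_kernel(times: np.ndarray, t_peak: float, fwhm: float) -> np.ndarray:
    """Unit-amplitude alpha function a(u) = (u/tau) exp(1 - u/tau), peaking
    at t_peak with the requested full width at half maximum."""
    if fwhm <= 0:
        raise ValueError("fwhm must be > 0")
    tau = fwhm / ALPHA_FWHM_FACTOR
    u = np.asarray(times, dtype=np.float64) - (t_peak - tau)
    out = np.zeros_like(u)
    pos = u > 0
    out[pos] = (u[pos] / tau) * np.exp(1.0 - u[pos] / tau)
    return out


def gaussian_kernel(times: np.ndarray, t_peak: float, fwhm: float) -> np.ndarray:
    """Unit-amplitude Gaussian bump with the requested FWHM."""
    if fwhm <= 0:
        raise ValueError("fwhm must be > 0")
    sigma = fwhm / GAUSS_FWHM_FACTOR
    t = np.asarray(times, dtype=np.float64)
    return np.exp(-0.5 * ((t - t_peak) / sigma) ** 2)


_KERNELS = {"alpha": alpha_kernel, "gaussian": gaussian_kernel}


def _roi_amplitude_map(roi: SyntheticRoi, height: int, width: int) -> np.ndarray:
    w = np.zeros((height, width))
    ys, xs = zip(*roi.footprint)
    ys, xs = np.asarray(ys), np.asarray(xs)
    if np.any(ys < 0) or np.any(ys >= height) or np.any(xs < 0) or np.any(xs >= width):
        raise ValueError("ROI footprint outside the canvas")
    if roi.profile == "flat":
        w[ys, xs] = 1.0
    elif roi.profile == "gaussian":
        cy, cx = roi.profile_center if roi.profile_center is not None \
            else (ys.mean(), xs.mean())
        d2 = (ys - cy) ** 2 + (xs - cx) ** 2
        w[ys, xs] = np.exp(-0.5 * d2 / roi.profile_sigma ** 2)
    else:
        raise ValueError(f"unknown ROI profile {roi.profile!r}")
    return w


def generate_movie(spec: SyntheticSpec) -> tuple[FluorescenceStack, GroundTruth]:
    """Render the movie and its exact ground truth; reproducible from seed."""
    T, H, W = spec.shape
    times = np.arange(T) * spec.frame_interval
    x = np.linspace(-1.0, 1.0, T)

    coeffs = np.asarray(spec.baseline_coeffs, dtype=np.float64)
    if coeffs.ndim == 1:
        f0 = np.polynomial.polynomial.polyval(x, coeffs)[:, None, None] \
            * np.ones((1, H, W))
    elif coeffs.shape[1:] == (H, W):
        powers = x[:, None] ** np.arange(coeffs.shape[0])[None, :]  # (T, d+1)
        f0 = np.tensordot(powers, coeffs, axes=(1, 0))
    else:
        raise ValueError("baseline_coeffs must be (d+1,) or (d+1, H, W)")
    if np.any(f0 <= 0):
        raise ValueError("baseline must be strictly positive")

    dff = np.zeros((T, H, W))
    footprints, amp_maps = [], []
    for roi in spec.rois:
        wmap = _roi_amplitude_map(roi, H, W)
        course = np.zeros(T)
        for ev in roi.schedule:
            if ev.amplitude < 0:
                raise ValueError("transient amplitudes must be >= 0")
            course += ev.amplitude * _KERNELS[ev.kernel](times, ev.t_peak, ev.fwhm)
        dff += course[:, None, None] * wmap[None, :, :]
        footprints.append(wmap > 0)
        amp_maps.append(wmap)

    if spec.ramp is not None:
        start_s, height = spec.ramp
        t_end = times[-1]
        if t_end <= start_s:
            raise ValueError("ramp start must lie inside the recording")
        u = np.clip((times - start_s) / (t_end - start_s), 0.0, None)
        dff += (height * u ** spec.ramp_power)[:, None, None]

    movie = f0 * (1.0 + dff)
    rng = np.random.default_rng(spec.seed)
    if spec.noise == "poisson":
        movie = rng.poisson(np.maximum(movie, 0.0)).astype(np.float64)
    elif spec.noise_sigma > 0:
        movie = movie + rng.normal(0.0, spec.noise_sigma, size=movie.shape)

    stack = FluorescenceStack(data=movie, pixel_size=spec.pixel_size,
                              frame_interval=spec.frame_interval,
                              name="synthetic")
    truth = GroundTruth(f0=f0, dff=dff, footprints=footprints,
                        amplitude_maps=amp_maps, spec=spec)
    return stack, truth


def disk_footprint(cy: int, cx: int, radius: float) -> frozenset:
    """Pixel set of a rasterized disk (centers within ``radius``)."""
    r = int(np.ceil(radius))
    pts = []
    for y in range(cy - r, cy + r + 1):
        for x in range(cx - r, cx + r + 1):
            if (y - cy) ** 2 + (x - cx) ** 2 <= radius ** 2:
                pts.append((y, x))
    return frozenset(pts)


def generate_fig_dichotomy_fixture(
    n_frames: int = 360,
    frame_interval: float = 1.0 / 3.0,
    ramp_height: float = 0.5,
    with_ramp: bool = True,
    seed: int = 0,
) -> tuple[FluorescenceStack, GroundTruth]:
    """The slow-ramp-plus-fast-transients regime that separates the two
    clean-up filters.

    Every pixel of a small flat-baseline canvas carries three fast alpha
    transients plus (optionally) a slow accelerating rise spanning the
    second half of the recording and reaching ``ramp_height`` dff at the
    end.  A whole-trace mean/sigma clean-up excludes the elevated tail and
    keeps the baseline flat (the rise survives in dff); a sliding Hampel
    clean-up tracks the rise locally, so the fit absorbs it into F0.
    """
    T = n_frames
    dur = T * frame_interval
    rois = [SyntheticRoi(
        footprint=frozenset((y, x) for y in range(4) for x in range(4)),
        schedule=[
            TransientSpec(t_peak=0.15 * dur, amplitude=0.5, fwhm=2 * frame_interval),
            TransientSpec(t_peak=0.30 * dur, amplitude=0.5, fwhm=2 * frame_interval),
            TransientSpec(t_peak=0.55 * dur, amplitude=0.5, fwhm=2 * frame_interval),
        ],
    )]
    spec = SyntheticSpec(
        shape=(T, 4, 4),
        baseline_coeffs=np.array([100.0]),
        rois=rois,
        noise_sigma=0.0,
        ramp=(0.45 * dur, ramp_height) if with_ramp else None,
        ramp_power=5.0,
        frame_interval=frame_interval,
        seed=seed,
    )
    return generate_movie(spec)


def generate_two_event_fixture(seed: int = 0, amp_bright: float = 2.0,
                               amp_dim: float = 1.2, noise_sigma: float = 1.5
                               ) -> tuple[FluorescenceStack, GroundTruth, dict]:
    """A bright event abutting a dimmer one, with disjoint transient times.

    Two flat-profile disks touch along a short contact zone; each carries
    its own transient schedule, disjoint in time, so pixel time courses on
    the two sides of the contact are uncorrelated.  This is the regime
    where the correlation constraint matters: growth from the bright seed
    is stopped at the temporal-identity interface, whereas a watershed of
    the range projection floods the brighter plateau first and annexes the
    dim event's contact edge.  The third return value maps ROI name ->
    ground-truth footprint pixel set.
    """
    dur = 40.0
    fi = 1.0 / 3.0
    T = int(round(dur / fi))
    fp_bright = disk_footprint(17, 12, 6.0)
    fp_dim = disk_footprint(17, 24, 6.0)
    # a diffuse halo of independent activity drapes the bright event's far
    # side: its range rises monotonically toward the event, so it has no
    # local maximum of its own and a watershed drains it into the bright
    # basin, while its time course shares nothing with the event
    halo = frozenset(
        (y, x) for y in range(36) for x in range(18)
        if 6.0 < np.hypot(y - 17, x - 12) <= 10.0)
    rois = [
        SyntheticRoi(footprint=fp_bright,
                     schedule=[TransientSpec(8.0, amp_bright, 2.0),
                               TransientSpec(25.0, amp_bright, 2.0)],
                     profile="gaussian", profile_sigma=6.0),
        SyntheticRoi(footprint=fp_dim,
                     schedule=[TransientSpec(15.0, amp_dim, 2.0),
                               TransientSpec(33.0, amp_dim, 2.0)],
                     profile="gaussian", profile_sigma=6.0),
        SyntheticRoi(footprint=halo,
                     schedule=[TransientSpec(20.0, 1.62, 2.0)],
                     profile="gaussian", profile_sigma=6.0,
                     profile_center=(17.0, 12.0)),
    ]
    spec = SyntheticSpec(shape=(T, 36, 36), baseline_coeffs=np.array([100.0]),
                         rois=rois, noise_sigma=noise_sigma,
                         frame_interval=fi, seed=seed)
    stack, truth = generate_movie(spec)
    footprints = {"bright": fp_bright, "dim": fp_dim}
    return stack, truth, footprints


def generate_population_fixture(seed: int = 0, n_active: int = 5,
                                n_weak: int = 3, noise_sigma: float = 1.5,
                                n_frames: int = 240,
                                synchronous: bool = False
                                ) -> tuple[FluorescenceStack, GroundTruth]:
    """A field of compact flat-profile ROIs on a quiet background.

    ``n_active`` ROIs carry clear transients (amplitudes >= 0.8 dff) and
    ``n_weak`` ROIs only sub-classification activity (0.3 dff) -- the
    false-positive regime.  ROI pixels cover roughly a tenth of the canvas,
    so most pixels are transient-free.  With ``synchronous`` every active
    ROI additionally fires within one short window, staggered by ROI index
    (a planted activation wave).
    """
    fi = 0.5
    rng = np.random.default_rng(seed)
    H = W = 40
    centers = [(6 + 9 * (i // 4), 6 + 9 * (i % 4)) for i in range(n_active + n_weak)]
    rois = []
    for i, (cy, cx) in enumerate(centers):
        if i < n_active:
            amp = 0.8 + 0.3 * (i % 3)
            t1 = 8.0 + 13.0 * i
            schedule = [TransientSpec(t1, amp, 2.0),
                        TransientSpec(t1 + 22.0, amp, 2.0)]
            if synchronous:
                schedule.append(TransientSpec(100.0 + 0.5 * i, 1.0, 6.0))
        else:
            schedule = [TransientSpec(15.0 + 8.0 * i, 0.3, 2.0)]
        # gently peaked profile: a single interior range maximum per ROI
        rois.append(SyntheticRoi(footprint=disk_footprint(cy, cx, 2.5),
                                 schedule=schedule,
                                 profile="gaussian", profile_sigma=3.0))
    spec = SyntheticSpec(shape=(n_frames, H, W),
                         baseline_coeffs=np.array([100.0, 5.0]),
                         rois=rois, noise_sigma=noise_sigma,
                         frame_interval=fi, seed=int(rng.integers(2**31)))
    return generate_movie(spec)


def dichotomy_configs():
    """The paired baseline configs that expose the clean-up dichotomy on
    :func:`generate_fig_dichotomy_fixture`.

    Both use min_error guidance at scale 3 and a degree-4 fit; they differ
    only in the clean-up filter.  The mean/sigma branch uses an aggressive
    exclusion multiplier (n = 0.5) so the slow rise falls above the
    whole-trace threshold and is dropped from the fit; the Hampel branch
    uses the conventional 3-scaled-MAD rule, whose sliding median tracks
    the rise, so the fit absorbs it.
    """
    from .pbase import PbaseConfig

    mean_cfg = PbaseConfig(cleanup="temporal_mean", n_sigma=0.5,
                           guidance_mode="min_error", poly_degree=4,
                           max_scale=3, mask_threshold=0.0)
    hampel_cfg = PbaseConfig(cleanup="hampel", hampel_window=11,
                             hampel_n_sigma=3.0, guidance_mode="min_error",
                             poly_degree=4, max_scale=3, mask_threshold=0.0)
    return mean_cfg, hampel_cfg
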