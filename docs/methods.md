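# Methods

`fluoroi` analyzes single-channel time-lapse fluorescence recordings
(calcium or sodium indicators, two-photon or wide-field) in which discrete
transients ride on a slowly drifting basal fluorescence level.  The
pipeline has five stages: pre-processing, per-pixel baseline (F0)
estimation, correlation-constrained ROI detection, transient extraction
and classification, and population synchronicity analysis.  This note
records the model behind each stage, the parameters that matter, the
numerical choices, and what the synthetic fixtures do and do not
demonstrate.

## Signal model

A pixel's recorded intensity is modeled as

    F(t) = F0(t) * (1 + dff(t)) + noise(t)

with `F0(t)` a smooth, low-order trend (bleaching, slow drifts in basal
indicator concentration) and `dff(t) = (F - F0)/F0` the transient activity
of interest.  All downstream analysis — detection thresholds, amplitude
classes, synchronicity — operates on dff, so the quality of the F0
estimate bounds the quality of everything else.

## Pre-processing

An optional temporal denoiser (built-in Gaussian smoother, or any
user-supplied callable) followed by a running temporal median
(default window 3 frames).  Edge windows shrink rather than reflect, so no
values are invented at the recording boundaries, where the polynomial fit
is most fragile.  The median is the only default step: it removes
single-frame outliers without biasing transient peaks wider than half the
window.

## F0 estimation (per pixel)

Three steps per pixel, all along the time axis only:

1. **Clean-up** — exclude statistically large samples (transients) from
   the fit.
   * *Whole-trace rule* (`temporal_mean`): exclude samples above
     `mu + n_sigma * sigma`, with mu and the population sigma computed once
     over the full trace.  Default `n_sigma = 2`.
   * *Hampel rule* (`hampel`): exclude samples deviating from their
     centered-window median by more than `hampel_n_sigma` scaled MADs
     (MAD × 1.4826).  Defaults: window 11 frames, 3 MADs.

   The two rules differ in what counts as background.  A slow, long-lasting
   elevation is *preserved as signal* by the whole-trace rule (it exceeds a
   global threshold) but *absorbed into F0* by the Hampel rule (the local
   median tracks it).  Which is correct depends on the biology; both are
   exposed.

2. **Guidance signal** — to prevent high-frequency oscillation of the fit,
   the retained samples are simplified into a piecewise-constant signal on
   a dyadic scale space: scale k splits the time axis into 2^k equal
   sections (boundaries rounded to integers, covering [0, T) disjointly).
   Each section's constant is its retained minimum, maximum, or mean
   (`min_error`, the L2-optimal constant, is the default).  The finest
   scale `max_scale` (default `floor(log2 T) - 2`, at least 1) feeds the
   fit; coarser scales are available for diagnostics.  A section whose
   samples were all excluded inherits the nearest non-empty section's
   value at the same scale (ties toward earlier sections); a trace with no
   retained samples at all is an error.

3. **Polynomial fit** — a least-squares polynomial of `poly_degree`
   (default 4) through the guidance signal, with the frame axis mapped to
   [-1, 1] for conditioning, evaluated at every frame.

With single-frame sections (`max_scale = log2 T`) and no exclusions, the
guidance signal is the trace itself and a degree-d polynomial input is
recovered to machine precision — the identity limit the baseline-recovery
test pins down.  At the default scale, section constants are a controlled
smoothing and recovery is approximate by design.

### F0 masking

Computing dff in dark, inactive regions amplifies noise (F0 near zero) and
manufactures false transients.  Before fitting, a provisional F0 (the
per-pixel temporal mean) gives a provisional dff whose temporal range
`R = max - min` is thresholded — by Otsu's method on a 256-bin histogram
by default, or a user value.  Pixels below threshold are *masked*: they
keep their recorded time course as F0, so their dff is identically zero
and they are zero in the final range projection.  Because fitting is
per-pixel, skipping masked pixels yields a speedup linear in the masked
fraction; the implementation counts fitted pixels so this is testable.
The range projection reported downstream is recomputed from the final dff.

A masking threshold is a detection-sensitivity decision: Otsu is a
starting point that separates a clearly bimodal range image well, but on
fields dominated by background it can swallow weak events, and a manual
threshold is then the right tool (several fixtures here use one for
exactly that reason).

## ROI detection (CoRoDe) and the watershed baseline

Seeds are the local maxima of the final range projection R at or above the
range threshold `t_R` (default 0.6 dff, following the validation setting).
A plateau of equal values that dominates its border yields one seed, the
member nearest the plateau centroid.  All seeds grow simultaneously
through one global priority queue of (candidate, claiming region) pairs
ordered by descending R of the candidate (ties by ascending y, then x,
making growth deterministic).  A candidate joins iff it is unassigned, its
R clears `t_R`, and the Pearson correlation between its dff trace and that
of the *adjacent already-assigned pixel through which it was claimed*
reaches `corr_threshold` (`t_corr`, default 0.25).  Negative correlations
fail any positive threshold; zero-variance (masked) pixels correlate at 0.
A pixel adjacent to two or more distinct regions when its claim is
processed becomes a boundary pixel, joins no region, and is excluded from
trace integration.  Regions below `min_roi_area` (default 4 px) are
discarded.

The local-pairwise correlation partner makes the `t_corr = 0` limit exact:
growth degenerates to range-threshold flooding.  The flip side is that the
constraint acts at *temporal-identity interfaces* — where the dominant
time course changes between neighbors — and not along gradual mixtures,
whose step-to-step correlation stays high.

Two caveats worth knowing:

* **Monotonicity holds up to contact pixels.**  Raising `t_corr` shrinks
  regions, except that a contact pixel between two regions is marked
  boundary only if both competitors have reached it when its claim is
  processed; at a higher `t_corr` the competitor may never arrive, and the
  pixel is then assigned rather than marked.  The test suite asserts
  shrinkage modulo the lower-threshold boundary set.
* **Projection seeding is noise-sensitive.**  Noise in R creates spurious
  local maxima; each becomes a seed, and seed spam fragments regions via
  boundary marking.  This afflicts any projection-seeded detector
  (the watershed comparison equally); masking exists to suppress it in
  background, but near-flat activity plateaus remain susceptible.

`watershed_baseline` runs a marker-based watershed on -R with the same
seeds, restricted to `R >= t_R` — the classic alternative the detector is
compared against.  `validate_rois` matches detected to ground-truth ROIs
by maximal pixel overlap and reports signed/absolute/relative area
differences plus trace SNR, defined with the lowest classification edge as
the noise floor: samples of the ROI-mean dff trace at or above the floor
are signal, the rest noise, SNR = 10·log10(ratio of mean squares).

## Transient analysis

ROI traces are the plain mean of dff over the ROI's pixels (boundary
pixels excluded by construction).  Candidate peaks are local maxima with
amplitude at or above the lowest class edge and prominence at least
`min_prominence` (default: half the lowest edge, so noise ripples on a
tall plateau do not register); plateau peaks take their center frame.  The
event's extent is delimited where the trace crosses
`duration_level% × amplitude` (50 = FWHM; 25/10 give fuller extents),
with crossing times linearly interpolated between frames for sub-frame
resolution at low frame rates.  Duration, rise time, decay time, and the
trapezoidal area under the positive trace between the crossings (baseline
0, since dff is already baseline-referenced) follow.

A *sub-transient* is a non-maximal peak whose peak time falls within a
stronger peak's [start, end] span — a secondary bump on the rise or decay
of a larger event.  (Requiring the full crossing span to nest inside the
stronger peak's would make the flag nearly vacuous: a smaller peak's
crossing level is proportionally lower, so its span is wider than or
disjoint from the stronger one's.)  Sub-transients are excluded by default
before classification.

Classification uses half-open amplitude intervals closed on the left,
default [0.5, 1.0), [1.0, 1.5), [1.5, inf) dff; the per-class relative
frequencies are the *signal composition*.  ROIs with no retained transient
never exceeded the lowest edge and are removed as false positives (labels
compacted).  The per-ROI frequency is `(count - 1) / (last start - first
start)` Hz, defined only for ROIs with at least two transients — a rate
over the active span, not the recording, so sparse late activity is not
diluted.

Amplitudes are read directly off the dff trace at the peak frame, with no
local re-baselining: the classification edges are absolute dff values, so
re-baselining would silently change their meaning.

## Synchronicity

A ROI is active while some retained transient of it spans the timepoint
(`t_start <= t <= t_end`; overlapping windows union).  The index at frame
t is the active count divided by the total number of retained ROIs —
constant denominator, so the index is comparable across time.  Maximal
runs of index ≥ threshold (default 0.5, the at-least-half rule) are
synchronous periods; each reports its peak frame (first on ties) and
value.  The activation sequence of a period lists the ROIs with a
transient *peaking* inside it, ordered by that transient's *start* time
(earliest per ROI, ties by label) — membership by peak, order by onset.
Note the earliest activator of a wave can peak before the index crosses
threshold and then drops out of the period's sequence; at the default
threshold this needs the stagger between onsets to approach the rise time.

## Synthetic data: what it emulates, and what it does not

`fluoroi.synthetic` renders movies by the same generative model the
analysis assumes: per-pixel polynomial baselines, ROI footprints with flat
or Gaussian amplitude profiles sharing alpha-function
(`a(u) = (u/tau) e^(1-u/tau)`, the standard asymmetric indicator-transient
shape; FWHM = 2.44639·tau in closed form) or Gaussian kernels, an optional
slow ramp, and Gaussian (optionally Poisson) noise.  Exact F0, dff,
footprints, and event parameters are returned with every movie, and
everything is reproducible from a seed.

Three packaged fixtures define the standard study conditions:

* **Slow-ramp dichotomy** (`generate_fig_dichotomy_fixture`): 360 frames
  at 3 Hz, flat baseline 100, three fast transients (0.5 dff, FWHM 2
  frames), and an accelerating rise (power 5, starting at 45% of the
  recording, +0.5 dff at the end).  Analyzed with the paired configs of
  `dichotomy_configs()` (min_error guidance, degree 4, scale 3;
  mean/sigma clean-up at n = 0.5 versus Hampel 11/3), the mean/sigma
  branch keeps ≥ 80% of the rise in dff while the Hampel branch absorbs
  ≥ 80%.  The contrast is real but regime-dependent: a one-sided
  mu + n·sigma rule can only exclude an elevation whose mass is a minority
  of the trace, so the demonstration uses a rise concentrated late in the
  recording and an aggressive n; with a linear ramp occupying most of the
  recording and n = 2, both filters absorb most of it.
* **Two adjacent events + halo** (`generate_two_event_fixture`): a bright
  and a dim truncated-Gaussian event abutting each other with disjoint
  transient times, plus a diffuse halo arc of independent activity whose
  range rises monotonically toward the bright event — so it has no local
  maximum of its own, drains into the bright watershed basin, and is
  rejected by the correlation constraint.  Across seeds, the
  correlation-constrained detector attains lower mean relative area error
  (≈ 5–30% vs ≈ 40–60%) and higher trace SNR (≈ +1.2 dB) than the
  watershed.
* **Population field** (`generate_population_fixture`): 8 compact ROIs
  (5 with genuine transients, 3 never reaching 0.5 dff) covering < 10% of
  a 40×40 canvas, 240 frames at 2 Hz, with an optional staggered
  activation wave for synchronicity tests.

What the fixtures do **not** emulate: realistic astrocyte morphology,
motion artifacts, photon-limited (Poisson-dominated) noise statistics,
spatially correlated optical blur, and overlapping events at the same
location.  Passing on them shows the algorithms implement their
definitions and reproduce the claimed qualitative contrasts at desk
scale — not field performance on in vivo recordings.

## Numerical choices and conventions

* Coordinates are 0-based `(t, y, x)`; ImageJ ROI geometry is rasterized
  by testing pixel centers `(x + 0.5, y + 0.5)`.
* Times in seconds (frame × `frame_interval`), areas in um²
  (pixels × `pixel_size`²); without calibration, frames and pixels are the
  units and the CSV headers say so.
* The clean-up sigma is the population (1/T) standard deviation; the
  Hampel scale factor is the conventional 1.4826.
* Polynomial fits use a Vandermonde least squares on [-1, 1]; the suite
  checks them against explicit normal equations.
* Otsu runs on a 256-bin histogram; near-empty bins produce exact variance
  ties, so equivalence tests compare attained between-class variance, not
  the raw threshold.
* A fitted F0 ≤ 0 anywhere aborts with the offending pixel named, rather
  than silently producing infinite dff.
* All tie-breaks (seed ordering, growth order, plateau centers, period
  peaks) are fixed, making every stage deterministic; two runs on the same
  input produce byte-identical CSVs and label maps.
* For ratiometric inputs (e.g. sodium-dye ratio stacks) the pipeline can
  analyze the additive residual `F - F0` instead of dff
  (`additive_detrend: true`), since a ratio is already normalized.

## Known limitations

* The correlation constraint does not stop growth along gradual amplitude
  mixtures (see above); it separates events with distinct time courses,
  not concentric intensity zones of one event.
* Events overlapping in time *and* space are not resolved — a limitation
  of any temporal-projection-based detector.
* The Otsu initialization of the mask assumes a roughly bimodal range
  image.
* Sub-frame interpolation assumes the trace is locally linear between
  frames; at very low frame rates relative to transient kinetics,
  durations of short events are resolution-limited.
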