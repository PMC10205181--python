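# Methods

`sparkmap` implements a correlative analysis that maps spontaneous Ca²⁺
sparks, recorded as 2D TIRF time series, onto the nanoscale organization of
RyR2 channels imaged by DNA-PAINT in the same cell. This note describes the
models, the numerical choices and what the synthetic benchmark does and does
not establish.

## Coordinate conventions

All positions are nanometres with the origin at the field corner, x to the
right and y down. Images use half-open pixel indexing with position
`(index + 0.5) · pixel size`. Camera pixels default to 100 nm; rendered
super-resolution images to 5 nm/px.

## Ca²⁺ spark analysis (`sparks`)

A spark is modelled as a symmetric 2D Gaussian in normalized fluorescence
dF/F₀, transient over one to a few frames at a 10 Hz frame rate.

* **Baseline F₀** — per-pixel temporal percentile, default the median
  (50th): unbiased under symmetric noise and robust to sparks, which occupy
  only a few frames per pixel. A rolling window (`window`) tracks slow drift
  such as photobleaching. A low percentile (e.g. 20th) suits spark-dense
  data but acquires a noise-dependent downward bias of ≈0.84 σ, which
  inflates dF/F₀ globally; the median was therefore preferred as default.
* **Detection** — dF/F₀ is restricted to the cell footprint (dividing by a
  dim extracellular baseline only amplifies noise), smoothed ~2 px with a
  normalized (mask-aware) Gaussian so the cell boundary does not bleed
  zeros inward, and thresholded at `detection_sigma` (default 5) times the
  robust (MAD) noise scale, with an absolute floor of 0.05 dF/F₀ so
  noise-free input keeps a finite contrast threshold. 3D-connected
  components yield one candidate each at their peak voxel; candidates within
  1 µm and 2 frames merge, keeping the brightest.
* **Fitting** — least-squares symmetric 2D Gaussian with constant offset on
  the candidate's peak-frame dF/F₀, over a patch of ~3 × the initial FWHM,
  using only in-cell pixels. The frame is pre-smoothed (default 2 px) to
  stabilise the fit at realistic noise; because a Gaussian convolved with a
  Gaussian stays Gaussian, the fitted width is corrected in quadrature and
  the peak by the area ratio, which is exact for the model class.
  Amplitude is reported as F/F₀ of the corrected fitted peak. Fits that do
  not converge, or whose width collapses below the smoothing kernel, are
  flagged invalid and excluded downstream.
* **Filtering** — 1.0 µm ≤ FWHM ≤ 6.0 µm, bounds inclusive (in-focus
  selection), and an R² criterion with configurable direction. The default
  keeps R² ≥ 0.5: the criterion selects fits with sufficient signal-to-noise,
  so high R² is the retained side. R² is computed on the smoothed patch.
* **Spark mass** — `1.206 × amplitude × FWHM³` (FWHM in µm), the standard
  conversion between a fitted Gaussian peak and the integrated release
  signal; spark frequency is reported per second per 100 µm².

## DNA-PAINT branch (`paint`)

* **Localization** — per-frame local maxima above threshold fitted with a
  2D Gaussian for sub-pixel centroids; saturated frames are flagged.
* **Rendering** — Gaussian-kernel density rendering at 5 nm/px, kernel
  σ = per-event precision with a 5 nm floor. This replaces the
  Delaunay-triangularization renderer used in earlier work deliberately:
  for punctum detection and intensity-fraction thresholding the two are
  equivalent, and kernel rendering is simpler to verify. A `hist` mode bins
  events without smoothing and is used when the rendered point spread
  itself is the measurand (resolution estimation), since any kernel would
  inflate it. Rendered images are float densities integrating to the event
  count; a separate writer scales to 16-bit for TIFF export.
* **Punctum detection** — local maxima that survive suppression within a
  disk of half the minimum separation (default 30 nm ≈ one RyR2 footprint),
  refined by intensity-weighted centroids. The half-separation radius means
  two channels exactly one footprint apart are both retained.
* **Cluster segmentation** — a global threshold chosen so that the pixels
  above it integrate to 80% of the total above-background intensity
  (background = modal pixel value). The threshold operates on a copy of the
  rendering smoothed to the RyR2-footprint scale (30 nm) so that the ~38 nm
  punctum lattice of one cluster forms a connected labelled area instead of
  isolated spot cores. Components holding fewer than `min_cluster_size`
  puncta (default 4; 5 is the other conventional preset) are unclustered
  (id 0). Masks are nested in the labelling fraction by construction.

## Registration (`align`)

About 10 consecutive Ca²⁺ frames are averaged into a low-noise reference,
upscaled bilinearly to the rendering grid, and registered to the
(PSF-matched, i.e. diffraction-blurred) rendering by cross-correlation. The
correlation score at every candidate lag is the Pearson correlation over the
actual overlap rectangle, computed with one FFT cross-sum plus integral
images. This windowed normalization matters: with global normalization the
shrinking overlap biases broad correlation peaks toward zero lag, which is
fatal when the shared structure is the smooth cell outline. The integer
peak is refined by separable quadratic interpolation; a peak below the score
floor (default 0.1) raises an alignment-failure error, which on uncorrelated
inputs fires reliably (the noise ceiling of the windowed score is ≪ 0.1 for
the image sizes used). The manual coarse-alignment step of the experimental
protocol is replaced by an `initial_shift` argument restricting the search
window. The scale factor between modalities is taken from pixel-size
metadata, not estimated.

The **alignment-error simulation** renders a scene's channel map, blurs it
with a Gaussian PSF (default FWHM 250 nm), downsamples to camera pixels,
applies a known random sub-pixel shift, adds noise so that the in-cell
contrast over the background noise s.d. equals the target SNR (default 17,
the definition used for an averaged reference image), upscales and
re-registers. The reference is the same degraded rendering (matched
filtering); correlating the 5 nm-sharp rendering directly also works but
with a weaker peak. Errors are reported per iteration in nm.

The **resolution-ratio simulation** images isolated emitters (>1 µm apart)
both ways: histogram-rendered localizations whose Gaussian localization
spread has FWHM 10 nm (σ ≈ 4.25 nm — the conventional statement of ~10 nm
localization-microscopy resolution as the FWHM of the rendered point
profile), and convolution with a 250 nm FWHM PSF. Fitted point-profile
FWHMs give the fold improvement, ≈24× with the 5 nm pixel quantization
included.

## Footprint sampling (`footprint`)

Each spark samples a circular window of diameter equal to its own fitted
FWHM (a fixed global diameter is available as an option), boundary
inclusive, after transforming its centroid into the map frame. `ryr_count`
counts all puncta inside; `cluster_count` counts distinct qualifying
clusters (≥ `min_cluster_size` puncta map-wide) with at least one punctum
inside (a centroid-inside rule is available). NND and 3ND are means of
each included qualifying punctum's one or three nearest-neighbour distances
within the included qualifying set; 3ND requires at least four such puncta
and is otherwise reported absent rather than padded. Mass ratio is spark
mass over `ryr_count`, absent at zero count. The mass-vs-count relation is
fitted as `mass = a·count² + b` on linear axes by default (the log₁₀ axes
of the conventional scattergrams are treated as display); a log-log variant
of the same form is exposed. Group comparisons use Mann–Whitney U
(distributions are not normal) and Bartlett's test with conventional
d.f. = k − 1. The per-cluster spark-mass map colours each cluster component
by the mean mass of sparks whose footprint disc intersects it.

## Recurring spark sites (`sites`)

Spark centroids within a 15 s window are segmented by a quadtree on the
field's bounding square: nodes split while they hold more than
`max_leaf_points` (default 3) and their children stay ≥ `min_leaf_size`
(default 100 nm). Leaves tile the square exactly (half-open rectangles).
Leaves whose density exceeds `density_factor` (default 4) × the global mean
density are hot; 8-connected hot leaves merge into sites, so sites can
bridge adjacent leaves. The density criterion is per-leaf counts; defaults
are recorded in the output metadata. Site–cluster overlap is the pixel
fraction of a site's area inside the cluster mask.

## Null models (`nullmodels`)

Uniform randomization within the cell-footprint mask (points cannot exist
outside the cell), preserving point counts and all non-positional
attributes. Randomizing RyR2 destroys clustering, so segmentation is re-run
on the randomized set and clusters may dissolve; randomizing sparks
destroys recurring sites. Comparisons report percentage histograms on
shared bins, median differences, IQRs and two-sample KS distances for
`ryr_count`, NND and 3ND.

## Synthetic scenes (`synthetic`)

The generator emulates the study system rather than any particular dataset:

* **Cell footprint** — an irregular smooth blob inside the inset field
  (band-limited noise thresholded to ~80% fill, largest component,
  hole-filled). The unique outline is what makes a real myocyte registrable
  between modalities; a rectangular cell would leave the registration
  under-constrained along its edges.
* **RyR2 map** — elliptical clusters (aspect 1–2, roughly row-aligned) along
  sarcomeric rows 1.8 µm apart, ~6 clusters per row, negative-binomial
  channel counts (mean 14), channels on a jittered triangular lattice.
  Positional jitter (σ 4 nm) shrinks the *minimum* over ~6 lattice
  neighbours, so the lattice constant is widened by a first-order correction
  (1.32 × jitter, vanishing at zero jitter) to keep the empirical mean
  intra-cluster NND at the nominal 38.23 nm. A `fragmentation_fraction`
  splits clusters into 2–3 angular sectors displaced 50–200 nm with 1.25×
  loosened packing — the dispersed disease phenotype.
* **DNA-PAINT table** — each channel retained with probability 0.90
  (labelling efficiency), emitting 1 + Poisson(14) events with isotropic
  7 nm localization error on random frames.
* **Spark movie** — 10 Hz, 100 nm camera pixels, baseline 100 counts in-cell
  over a 10-count background. The in-cell baseline carries diffraction-
  limited texture (channel density seen through the 250 nm TIRF PSF,
  ±25% amplitude): real averaged Ca²⁺ images are textured by cell
  structure, and this is the intensity landscape intensity-based fine
  alignment locks onto. Sparks are 2D Gaussians in dF/F₀ scaled by the
  local baseline, with FWHM 1.5–3.5 µm, amplitude F/F₀ 1.5–2.5 (the
  amplitude distribution is not constrained by prior measurements and is a
  free parameter), durations 30–100 ms. At 10 Hz a spark is sub-frame, so
  the per-frame weight is the maximum of the rise/decay profile within the
  exposure (full nominal amplitude in the peak frame, exponential decay
  with τ = duration/2 after). White noise is calibrated so that the
  10-frame-averaged image reaches SNR = (in-cell mean − background mean) /
  background s.d. = 17, i.e. per-frame σ = contrast·√10/17. Spark rate is
  2 s⁻¹ per cell footprint (ctrl preset); the disease preset doubles it and
  fragments half the clusters.

**What the synthetic benchmark does not show.** The generator has no
photophysics (imager binding kinetics, blinking statistics), no drift, no
3D geometry or t-tubules, no out-of-focus spark contamination beyond the
FWHM filter's reach, and Gaussian noise rather than a full camera model.
Passing tests demonstrate that the estimators recover known ground truth
under the stated imaging regime; they do not certify performance on real
recordings with un-modelled artefacts, and the real-data group differences
(healthy vs failing myocytes) are expressly out of scope — the pipeline
computes the identical statistics, but their values on synthetic scenes are
properties of the generator.

## Problem sizes and numerical tolerances

Test scenes are 15 × 15 µm (≈500–650 channels, ≈40 clusters) with 100–150
frame movies; the alignment-error simulation runs 50 iterations on the full
scene and ≈3000² px FFTs. Brute-force oracles check footprint statistics
exactly on ≤10³-point instances. Quadratic-interpolation sub-pixel shifts
are clipped to ±0.5 px; Bartlett is flagged rather than computed at zero
group variance; the intensity-fraction threshold raises a degenerate-input
error on uniform images.
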