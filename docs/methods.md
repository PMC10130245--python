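# Methods

`stentbench` emulates, end to end and entirely in software, a head-to-head
comparison of two CT detector technologies — a silicon photon-counting
prototype (Si-PCCT) and a conventional energy-integrating scanner (EIDCT)
— on the task of imaging metal vascular stents. This note records the
model, its assumptions, the tunable parameters, and what the synthetic
setting can and cannot say about real scanners.

## Phantom model

The physical object is a 200-mm cylinder of 2% agar-water (soft-tissue
surrogate) containing a contrast-filled artery on its axis, with one stent
(carotid d = 5.5 mm, iliac d = 8.5 mm) or two overlapping stents (femoral,
d1 = 7 mm outer and d2 = 5.8 mm inner). Each stent is reduced to a thin
annulus of metal: in every axial slice within the stent's axial range,
material within `strut_thickness_mm / 2` (default 0.15 mm) of the
centerline radius `d/2` is metal. The woven-mesh structure and the
radiolucent polymer cover of a covered stent are not modelled: all three
metrics operate on the ring cross-section, for which a continuous annulus
is the appropriate idealization.

HU assignments (the source quantities are concentrations, not HU):

| material | HU | rationale |
| --- | --- | --- |
| 2% agar background | 10 | near water |
| iodine lumen, 15 mg/mL | 390 | ~26 HU per mg/mL at 120 kVp |
| vessel wall | 50 | soft tissue |
| steel strut | 8000 | only needs to dominate; partial volume does the rest |

The femoral pair overlaps axially over a central 2.52-mm band, with the
inner stent offset 0.25 mm in-plane so the ring gap varies around the
circumference. Per-stent diameter and blooming are measured on each
stent's *exclusive* axial band (where only that ring is present, so the
outermost-peak rule is unambiguous); inter-stent distinction is measured
in the overlap band, along the direction where the gap is widest
(centerline separation there is 0.85 mm).

Rasterization is nearest-material on a grid of at most 0.02 mm in-plane
(several voxels across the thinnest strut); all partial-volume behaviour
emerges downstream from blurring and binning, as in a real reconstruction.

## System model

A reconstruction is modelled as a linear degradation chain:

1. in-plane convolution with an isotropic Gaussian PSF of FWHM
   `psf_fwhm_mm`,
2. axial averaging over the slice thickness (contiguous slices),
3. area-average binning onto the detector pixel grid (`FOV / matrix`),
4. additive white Gaussian noise in HU.

There is no beam hardening, no photon starvation, no streaks and no
spiral/cone geometry: the three stent metrics are resolution-driven, and
both real systems were operated at matched dose with the same kernel, so a
shared linear blur + noise model isolates exactly the variable under study
(spatial resolution).

Preset parameters (two systems x two reconstruction FOVs):

| preset | FOV (mm) | matrix | pixel (mm) | slice (mm) | PSF FWHM (mm) | CTDI_vol (mGy) |
| --- | --- | --- | --- | --- | --- | --- |
| `si_pcct_150` | 150 | 1024 | 0.146 | 0.42 | 0.292 | 8.9 |
| `si_pcct_50` | 50 | 1024 | 0.049 | 0.42 | 0.292 | 8.9 |
| `eidct_150` | 150 | 512 | 0.293 | 0.63 | 0.586 | 9.0 |
| `eidct_50` | 50 | 512 | 0.098 | 0.63 | 0.586 | 9.0 |

Neither scanner's MTF is public, so the PSF widths are free model
parameters (config-overridable). They are set to twice each detector's
native 150-mm-FOV pixel size and held fixed across reconstruction FOV:
the PSF is a property of the detector and focal spot, while a smaller
reconstruction FOV only samples the same signal more finely. This
reproduces the qualitative pattern that moving from 150-mm to 50-mm FOV
helps modestly, while switching detector technology helps a lot.

Noise defaults to 25 HU (1 SD) at the 9-mGy reference dose for both
systems — the study design matched dose across systems, and modelling a
detector-specific noise advantage is out of scope — and scales as
1/sqrt(CTDI_vol) if the dose is changed. `noise_sd_hu = 0` selects the
noiseless idealization used in resolution sweeps.

The ground-truth grid must oversample the detector grid by an integer
factor of at least 4 (at least 3 is enforced) so that binning is an exact
area average; the pipeline chooses the factor per preset (4-16) so the
rasterization stays at or below 0.02 mm.

## Measurement operators

All operators work on raw HU (display windowing plays no role) and use
only relative thresholds, making every metric invariant under positive
affine HU rescaling (`a*HU + b`, `a > 0`); this invariance is tested.

**Center estimation.** Intensity-weighted centroid of voxels above the
midpoint between the local background (window median) and the window
maximum, iterated twice.

**Diameter (peak-to-peak).** On each of `n_angles` (default 8) equally
spaced diametral lines through the centroid, HU is sampled by bilinear
interpolation at a step of `pixel/4`; local maxima above a prominence of
0.2 x (max - median) are refined by a parabola through the three samples
around each discrete peak; the diameter is the distance between the two
outermost opposing peaks. A symmetric PSF does not shift an isolated
symmetric ridge, so the estimator is unbiased to first order; the residual
inward bias of a blurred *curved* ridge is O(sigma^2 / d), well below a
pixel for all presets. Lines with fewer than two opposing peaks are
dropped; more than 50% dropped lines is a measurement failure.

**Blooming.** On radial rays from the centroid, the strut peak's inner
and outer half-maximum crossing radii are found, each relative to the
local background on that side (median HU in radius windows 0.25-0.6 and
1.6-2.4 times the peak radius, i.e. contrast lumen inside and agar
outside). Mean crossing radii over rays define apparent areas
`A_in = pi r_in^2`, `A_out = pi r_out^2`, and

    blooming % = (A_out - A_in) / A_out * 100.

The externally referenced area-measurement protocol behind this metric is
not reproducible from its description, so the half-maximum edge — the
standard surrogate for apparent strut width — defines the areas, and the
outer area is the denominator, which keeps the metric in [0, 100].

**Inter-stent distinction.** A ray from the midpoint between the two
stent axes, cast toward the wide side of the gap, crosses one strut of
each stent. With `peak` the mean height of the two strut peaks, `trough`
the HU minimum between them and `minimum` the background reference (median
HU at radii at least 2.2 x the outer stent radius, in the agar),

    distinction % = (peak - trough) / (peak - minimum) * 100,

clamped to [0, 100]. If the two struts are not resolvable (fewer than two
peaks), the location scores 0 and is flagged. Averaging the two peak
heights treats the stents symmetrically when their apparent heights
differ.

**Replication.** Every metric is measured at exactly 3 axial locations
per stent (interpreting the replicate "locations" as axial slices) and
reported as mean +/- SD; the same replicate ordinals pair the two systems
in the paired tests.

## Reader-score model

Ordinal 1-5 ratings (stent appearance, blooming severity, inter-stent
visibility) are simulated with a cumulative-threshold model: latent item
quality + fixed reader bias + Gaussian rating noise, cut at four ascending
thresholds (defaults 1.5, 2.5, 3.5, 4.5 on the score scale). Latent
quality is a linear function of the item's *measured* metrics (e.g.
appearance latent = 5.1 - 0.095 x blooming% - 2.0 x error_mm), with
coefficients chosen once so that a sharp system at ~15-20% blooming maps
near score 4 and a blurred one at ~30% blooming near score 2, matching the
range a 5-point scale is designed to cover. Two readers (second reader
biased -0.3) rate every item in two sessions; items are the four stents
(visibility: the one pair) per FOV and system.

## Statistics

* Continuous metrics: paired Student t (pairs = stent x location).
* Ordinal scores: Wilcoxon signed-rank, zero differences dropped,
  mid-ranks for ties, exact sign-assignment distribution for n <= 15
  without ties (computed by the standard signed-rank count recursion),
  otherwise a normal approximation with tie correction and continuity
  correction. Pairs are (item, reader), sessions averaged.
* Reliability: two-way mixed consistency ICC for the mean of 2 raters,
  ICC(C,2) = (MS_items - MS_err) / MS_items, pooled across all
  evaluations; a per-metric-then-averaged pooling mode is also exposed
  because the pooling convention is genuinely ambiguous. Inter-reader uses
  session 1 of both readers; intra-reader uses both sessions within each
  reader, readers stacked as items.
* Normality screening: Shapiro-Wilk via scipy.
* Two-tailed alpha = 0.05 throughout; no multiple-testing correction (by
  design, matching the emulated analysis).

Quantile convention for the reported IQRs: linear interpolation
(`numpy.percentile` default), e.g. scores {4,4,4,4,5,4,4,2} give median 4,
IQR 4-4.

## Numerical choices

* Gaussian blur uses `scipy.ndimage.gaussian_filter`, edge mode
  `nearest`; the field of view is cropped to a 24-mm box around the
  vessel whose border is uniform agar, so the volume mean is conserved to
  well under 0.5 HU (tested).
* Sub-pixel peak refinement clamps the parabolic offset to half a sample
  and falls back to the sample position when the three-point curvature is
  non-negative.
* Binning requires exact integer spacing ratios; anything else raises a
  resolution error rather than silently resampling.
* Seeds: one master seed expands through `numpy.random.SeedSequence` into
  31-bit per-volume and per-score-simulation seeds; all outputs are
  byte-identical for identical configurations.
* Problem sizes: volumes are cropped to 24 mm in-plane around the vessel
  (the largest background window needed is 2.4-3.0 stent radii) and to
  2.52 mm axially for single stents / 8.82 mm for the femoral pair —
  exactly whole numbers of slices for both slice thicknesses, giving the
  three replicate slices per measurement band with no partial slabs.

## What passing tests do and do not show

The synthetic phantoms have exact circular cross-sections, uniform
materials, no motion, and a degradation model that is linear and
shift-invariant. Under these conditions the pipeline reproduces the
*directional* findings of the emulated comparison robustly: the
photon-counting presets yield lower diameter error, roughly half the
blooming (about 18-20% vs 33-36% at these defaults), and far higher
inter-stent distinction, with the paired tests significant for the
quantitative metrics and the simulated reader scores, and non-significant
for inter-stent visibility where only one specimen contributes items.
Absolute diameter-error magnitudes, by contrast, are an order of magnitude
smaller than on a real scanner: real errors are dominated by
reconstruction-kernel overshoot, calliper placement and specimen geometry,
none of which the desk-scale model contains. Blooming and distinction
percentages land in the physically expected range because they are ratios
of blur-driven lengths, but they should be read as model outputs, not
scanner measurements. The reader-score layer is a fixture for the
statistics, not a model of radiologists: its coefficients tie scores to
measured image quality so that agreement statistics have realistic
structure, nothing more.

## Known limitations

* No spectral/material-decomposition modelling; single-energy HU only.
* No helical/cone-beam geometry, bowtie filtration or rotation physics;
  those acquisition parameters are carried as metadata.
* The PSF FWHM values are plausible surrogates, not measured MTFs;
  absolute blur magnitudes (hence absolute blooming) move with them.
* The intertwined pair is represented by one inner and one outer annulus;
  true strut interleaving in 3-D is not modelled.
* DICOM input is supported read-only; export is NIfTI.
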