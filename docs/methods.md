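# Methods

## Optical model

A DMD (rows × cols binary mirrors) is imaged onto the sample through a
microscope objective. The projected pixel size is measured directly where
possible (FOV width / DMD columns) and otherwise scaled between objectives
by the magnification ratio: px(target) = px(ref) · mag(ref) / mag(target).
The bundled default instrument carries a measured 20× reference of
0.702 μm/px (561.6 μm projected width over 800 columns); all other
objectives scale from it. At two-decimal rounding this reference also
reproduces the instrument table exactly (4×: 3.51, 40×: 0.35,
100×: 0.14 μm/px), which the rounded 0.70 value would not (0.70·20/4 =
3.50). A coarser field measurement of 560 μm/800 px ≈ 0.7 μm/px is
equally valid at its own precision; both are representable through
`measured_pixel_size_um` and the package does not arbitrate between them.

Depth of focus uses the standard scalar approximation Δz = nλ/NA², with
n the immersion index (1.0 air, 1.515 oil) and λ the exposure wavelength
(0.395 μm default). This is an order-of-magnitude guide for layer-height
planning, not a wave-optics PSF model; in practice usable layer thickness
exceeds Δz considerably.

### Dosimetry

Power is affine in two controls: the LED setting (P = fraction · P_max,
assumed linear over the full range — linearity below ~10% output is an
extrapolation) and the DMD ON-pixel fraction (P = slope·f + intercept,
default slope 2.71 mW per unit fraction, intercept −0.02 mW). The fitted
intercept is slightly negative, so the ON-fraction model clamps at 0 mW:
physical power cannot be negative and the affine fit is an approximation
near the all-OFF end. Energy is E = P·t/1000 (mJ), dose D = E/A
(mJ/mm²) over the projected field area. No intermediate is ever rounded;
printed-precision comparisons round only the final value (round-half-even
at the printed decimal count) — required, e.g., to obtain 0.478 rather
than 0.477 mJ/mm² at the 46% setting. `exposure_time_for_dose` is the
algebraic inverse of the chain and round-trips to 1e−9 relative.

Units are fixed package-wide: lengths μm, areas mm² (dose only), power
mW, time ms, energy mJ, dose mJ/mm². Conversions live inside operations.

## Spin-coat calibration

Film thickness follows h(RPM) = a/√RPM + h₀. Substituting x = RPM^(−1/2)
makes the model linear in (a, h₀), so the fit is closed-form ordinary
least squares (numpy lstsq) — no iterative optimiser and no convergence
tolerance. With `with_offset=False` the intercept column is dropped and
h₀ forced to 0. R² = 1 − SS_res/SS_tot with SS_tot about the sample mean
of h. Noiseless model-generated data is recovered to machine precision;
under Gaussian measurement noise of 2 μm at n = 10 points spanning
200–3200 RPM, a 1000-replicate Monte-Carlo places the relative error of
â under 10% in well over 95% of replicates, which is the tolerance the
noisy-fit tests assert.

The multilayer consistency statistic uses the layer constant c = h·√RPM,
which is invariant under the h ∝ RPM^(−1/2) law when h₀ is negligible.
Two constants are compared by the symmetric relative difference
100·|c₁−c₂| / mean(c₁, c₂). The denominator was verified by brute force
against the candidates {c₁, c₂, mean}: only the mean reproduces the
4.93% obtained from the reference measurements (43.93 μm at 120 RPM
single-layer; 69.77 μm / 2 = 34.885 μm per layer at 210 RPM); the
asymmetric choices give 5.05% and 4.81%.

## Tiling

One coordinate convention everywhere: x rightward, y downward (raster row
order), design origin at its top-left corner, half-open pixel intervals,
row-major frames. Tiles abut exactly by default — the tile count per axis
is ceil(design extent / field extent) — with an optional overlap that
steps the stage by (field − overlap); ON pixels in overlaps are simply
exposed by both frames. Frames are resampled by nearest neighbour (a DMD
pixel is ON iff its centre falls in an ON design pixel): the DMD is
binary, so anti-aliasing would be meaningless. All-OFF frames are dropped
from the plan (counted in `skipped_empty`) to save stage moves. Tiles are
visited in serpentine order, which attains the minimum axis-aligned
travel of n_rows·n_cols − 1 single steps. When the design pitch equals
the projected pixel size and the extents divide evenly, rasterising the
plan back onto the design grid is exactly the identity — the coverage
oracle used in tests.

Fiducial alignment is normalised cross-correlation template matching
(scikit-image `match_template`); the offset is reported in μm relative to
a reference placement (default: template centred), at integer-pixel
resolution. A flat template, or a peak correlation below an optional
threshold, raises instead of silently aligning to noise.

## Virtual printer

Each exposure deposits t·P/A_field uniformly on the substrate cells whose
centres land on ON frame pixels; exposures add; the summed map is
convolved once with a Gaussian PSF (zero-padded borders); curing is a
hard threshold dose ≥ D_c. Defaults: substrate pitch = half the projected
pixel (Nyquist w.r.t. the frame raster); PSF σ = 0.21·λ/NA (Gaussian
approximation of the diffraction-limited spot — configurable because real
prints resolve ~5 μm at 20×, well above the diffraction limit, due to DMD
edge artifacts); stage jitter = independent Gaussian offsets per exposure
with default SD 1 μm (motivated by the <2 μm pitch SD a well-tuned stage
achieves); cure threshold 0.5 mJ/mm², the setting reported to work across
layer heights — resin-brand dependent and not calibrated here. Blur
conserves total energy to <0.1% away from borders (checks exclude a 3σ
margin). The model ignores resist kinetics, oxygen inhibition and the
z-profile of curing; cured maps are 2-D.

## Synthetic QC grids

`synth_grid_image` renders dark horizontal and vertical lines on a bright
background: nominal pitch, per-line Gaussian positional jitter, global
rotation about the image centre (applied analytically to the sampling
coordinates, so there is no resampling error), additive Gaussian pixel
noise, fixed-seed deterministic. It returns the exact post-jitter line
positions, which is what makes the QC pipeline testable: fixtures carry
their own truth. It emulates the geometry and contrast of a stitched-grid
micrograph, not its optics — no uneven illumination, defocus, debris or
edge diffraction — so passing tests demonstrate correctness of the
analysis chain, not robustness to every real-world artifact.

## Grid QC pipeline

Upscale (bicubic, default 4×) → Otsu binarise (dark-lines polarity
configurable) → skeletonise → probabilistic Hough (defaults: 10 votes,
minimum length 25% of the shorter side, maximum gap 5 px, all
post-upscale; seeded, since the transform samples randomly) → classify
segments horizontal iff |angle| ≤ 45° → single-linkage grouping of
midpoint coordinates along the dominant axis (gap > tolerance starts a
new group; tolerance defaults to half the expected pitch when given, else
10 post-upscale px) → per group, pool endpoints and take the maximally
distant pair as the merged line. Orientation is reported as signed
deviation from the assigned axis so both axes share one misalignment
scale; pitch is the spacing of consecutive sorted merged-line positions
converted to μm (÷ upscale factor). SDs are sample standard deviations;
axes with fewer than two lines report pitch as undefined. Upscaling
gives quarter-pixel position resolution at the default factor; on clean
fixtures the recovered pitch is exact to the detection pixel. One known
interaction: skeletons of a *rotated* grid break at line crossings, so
tilted grids need a larger Hough `max_gap_px` (~20) to be traced across
intersections; the parameter is exposed.

## Jobs and the driver contract

A job (design + objective + exposure time or target dose) talks to a
three-call driver contract — move_stage, project_frame, capture_image —
so the simulated driver and any future hardware driver are
interchangeable; only the simulated driver ships. Exposure time given a
target dose is derived through the LED power model before any driver
call, as are all configuration errors. Artifacts (plan JSON + frame TIFF,
stage CSV, dose/cure TIFFs, structured log) are byte-reproducible for a
fixed seed; the log records stage position, ON-pixel fraction, time and
computed dose per exposure.

## Problem sizes

Tests run designs up to 8000×8000 design pixels (tile counting only),
simulator grids of order 10⁵ cells, and QC images of ~300×300 px
(upscaled 4×), with 10–20 lines per axis — sizes chosen so the full suite
and the acceptance script complete in seconds while every code path,
including multi-tile plans and jittered fixtures, is exercised.

## Known limitations

- Pixel-level (not sub-pixel) fiducial correlation; no rotation/scale
  registration.
- Dose model has no reciprocity failure, no resin depth attenuation, no
  sidewall profile.
- The QC pipeline assumes an axis-aligned-ish orthogonal grid; curved or
  strongly rotated patterns are out of scope.
- LED linearity is extrapolated below ~10% output.
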