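# Methods

This note records the models, conventions and numerical choices behind
`polarmic`, and what the synthetic validation does and does not demonstrate.

## Angle conventions

All dipole-related angles live on the 180°-periodic axis of a transition
dipole (dyad symmetry).  Counter-clockwise is defined in the display
orientation (y up); image arrays index rows downward, so every conversion
from a pixel displacement to an angle goes through one helper
(`angles.axis_angle_deg`), preventing silent handedness flips between
modules.  Circular statistics on axis data (means, standard deviations,
distances) operate on doubled angles.

## Emission anisotropy (two-channel mode)

Anisotropy is r = (I∥ − I⊥)/(I∥ + 2 I⊥); the perpendicular intensity counts
twice because emission has two planes perpendicular to the parallel one.
Range: [−0.5, 1] for nonnegative inputs.  The processing chain is:

1. **Background model.**  A Gaussian is fitted to the left shoulder of the
   intensity histogram (bins at or below the peak), so bright foreground in
   the right tail does not bias μ or σ.  The histogram is bracketed at
   μ̃ ± 8·(1.4826·MAD) around the median, which assumes background occupies
   the majority of pixels; images dominated by cell area violate this
   assumption.  Constant images return σ = 0 rather than failing, because the
   noiseless fixtures exercise exactly that case.  Background masks use
   μ + 3σ; per-frame, per-channel mean background over the mask is
   subtracted.
2. **G factor.**  From an isotropic dye pair, G = mean(I∥)/mean(I⊥); the
   correction multiplies I⊥ so the dye's corrected anisotropy is zero.
3. **Prefilter.**  A 3×3 intensity-weighted average with weights equal to
   total intensity (I∥ + 2 I⊥).  With these weights the filtered anisotropy
   equals the anisotropy of the summed channels, which is how it is
   implemented (two uniform filters and one division).
4. **Gating.**  Pixels with total intensity ≤ 4 background standard
   deviations are invalid (r = 0, flagged; never NaN).  Regions with
   SNR = μ<sub>⊥,region</sub>/σ<sub>bg</sub> below 5 are excluded; SNR
   exactly 5 is kept.  σ<sub>bg</sub> = 0 yields SNR = +∞.

## Orientation map

Pixel orientation relative to the cell outline comes from the mask alone:
closure (radius 3 px), Euclidean distance transform, Gaussian smoothing of
the distance field (σ = 2 px, see below), central-difference gradient, folded
axis angle.  On a circular cell the map is the radial azimuth folded to
0–180°, aligned with the polarization axis.

**Why the smoothing:** the discrete EDT is a union of cones to individual
boundary lattice pixels; near axis-aligned boundary runs its gradient locks
onto the local staircase flat and deviates from the analytic normal by up to
~12°.  Smoothing the distance field with σ = 2 px reduces the worst-case
deviation on a radius-50 disk to < 3° while remaining fully deterministic.
Generation and analysis share this one function, so the ideal-image
validation is unaffected by the choice.

## cos² angular-dependence fit

Orientations are snapped to the nearest 10° (or 15°) multiple; the model
r = C + A cos²(γ − θd) is reparameterized as a linear model in
(1, cos 2γ, sin 2γ) and solved by least squares — the exact global optimum,
with A ≥ 0 by construction and θd the phase of maximal r.  The fit runs on
all pixels with binned orientation labels by default, or on per-bin means.
Preconditions: ≥ 3 occupied bins spanning ≥ 90° of orientation (circular
extent).  Degenerate outcomes carry status codes: constant data →
`degenerate` (R² undefined); A < 10⁻⁴ → `low_amplitude` (θd undefined).

The Fourier cross-check builds the running average of r over a 1° orientation
grid (10° circular boxcar; gaps filled by circular interpolation and
flagged), removes the mean, and reports the first-harmonic magnitude, which
equals A/2 for a cos² law (cos²x = ½ + ½cos 2x over the 180° period).

## Four-channel inversion and ROI dipoles

With analyzer channels at 0/45/90/135°, I0 − I90 and I45 − I135 are the
quadrature components of the dipole's cos 2θ modulation, giving
θ = ½ atan2(I45 − I135, I0 − I90) and
p = √((I0−I90)² + (I45−I135)²)/(0.5 ΣI).  The inversion is exact for the
forward model at all p ∈ [0, 1], θ ∈ [0, 180); p > 1 (possible under noise)
is reported with a flag, not clipped.  Calibration divides each quadrant by
its throughput factor, warps it onto the reference quadrant, and subtracts
the per-channel mean of a 4×4 ROI at the cell center.

Membrane ROIs are 1000 × 500 nm rectangles tiled without overlap along the
boundary contour, tangent from the principal axis of boundary points within
±500 nm of arc length, outward normal fixed away from the centroid; the
leftover arc shorter than one ROI is dropped, and tiling starts at the
protrusion centroid when one exists.  Cell-body ROIs reuse the same long-axis
angles ≥ 1000 nm inside the membrane (default inset 1500 nm) so segmentation
orientation cannot bias the edge/body comparison.  Per-ROI θd is the folded
difference between the recovered dipole axis and the ROI normal.  Residual
disagreement between the contour-PCA normal and the distance-map normal
leaves per-ROI errors of up to ~2.5° on a 160-px disk (median < 1°);
cell-level intensity-weighted summaries are accurate to well under 2°.

Radial histograms bin θd at 15° with intensity-weighted mean p per bin; the
circular-Gaussian summary is the intensity-weighted circular mean and the
wrapped-normal standard deviation √(−2 ln R)/2 on doubled angles.  The
histogram is reflected for display only.

## Segmentation chain

Threshold segmentation (default; active contour behind a flag via
morphological Chan–Vese) seeds from the background mask, dilates seeds by
5 px, then applies closure (radius 1), small-object removal (< 64 px) and
hole filling.  Movies keep only cells segmented in ≥ 5 frames
(spatiotemporal connected components, 8-connectivity in space, 1-frame
adjacency in time).  Edge band = cell minus a 10-px erosion (cells thinner
than 20 px degenerate to the whole cell, flagged).  Protrusions are positive
frame-to-frame differences connected spatiotemporally and kept when their
spatial footprint is ≥ 2000 px and they span ≥ 5 frames; the leading edge is
the edge band intersected with protruding regions.

## Actin flow

Optical flow uses the iterative Lucas–Kanade solver (window 15 px, 10 warps)
on frame pairs normalized to zero mean and unit variance — speed is
therefore invariant to global intensity scaling.  A confidence mask requires
the smallest structure-tensor eigenvalue of the normalized frame to exceed
10⁻⁴; textureless movies come back fully masked rather than zero-valued.
Per-ROI flow is the vector mean (not a mean of angles, which would be biased
by wraparound); the angle to the membrane tangent is the folded difference.
Direction histograms use 15° bins with a least-squares Gaussian fit of bin
counts; SEM = fitted sd/√n.

Kymograph velocity scans candidate streak slopes v (±5 px/frame, 0.05-px
steps with parabolic refinement): rows are shifted by −v·t, summed, and the
variance of the aligned profile is maximized over a fixed evaluation window
(a line-integral/Radon-style angular maximization parameterized directly in
px/frame).  Streak coherence — best aligned-profile variance over mean
single-row variance — is ≈ 1 for clean streaks and ≈ 1/T for uncorrelated
noise; below 0.2 the estimator refuses with a diagnostic.

## Molecular reference frame

The frame is built from three anchor Cα positions: ligand point at the
origin, α-junction on +x, β-junction in the xz half-plane (z > 0); rows of
the rotation are the frame axes, so any rigid motion of the input structure
cancels exactly.  For LFA-1 the documented anchors are the internal-ligand
Glu, Arg-588 (αL) and Pro-104 (β2).  The GFP transition dipole is either the
published slope (−0.026, 0.871, 0.439) in the 1w7s chain-B frame
(normalized: (−0.02665, 0.89267, 0.44992)) or the line from the Val-112 N
atom to the Asn-146 C / Ser-147 O midpoint; sign fixed to positive y.

Orientation states (θ, φ) have reference θ = 0°, φ = 90°.  The φ tilt is a
rotation about y by (90° − φ) — chosen because it keeps the α-junction in
the xz plane exactly, which is the stated geometric constraint of tilting
under cytoskeletal force — followed by the θ rotation about z.  Ensemble
dipoles are computed by simulating four-analyzer intensities: each member
contributes |in-plane projection|²·cos²(α − member angle); the channel sums
go through the same four-channel inversion as the imaging data.  Selection
keeps the lowest 40% of members by energy (stable ties).  Equal weights are
used within the selected set.  The tilt scan evaluates (θ_ens, p_ens) at
θ = 0 over φ ∈ {11.25, 22.5, 45, 67.5}° by default and flags φ values whose
θ_ens lies within the measured θd ± 1 s.d. band (circular distance, period
180°).

## Synthetic scenes

The generators emulate the study conditions, not the instrument physics:

- **EA scenes** render r(γ) = C + A cos²(γ − θd) with γ from the shared
  orientation map, inverted to channels at constant total intensity
  (default 1000 counts ≈ 100× the default background σ of 10, so no pixel
  trips the intensity gate in noiseless tests; background mean 100).  The
  ideal-image validation protocol additionally snaps γ to the analysis bin
  grid (`orientation_bin_width`), because a perfect (R² = 1.00) binned fit
  exists only when generation and fit share the binned geometry; without
  snapping, pixel-mode fits on a continuous-γ disk give R² ≈ 0.986 from
  within-bin cos² variance.
- **Quad scenes** set a per-pixel dipole axis θ = γ + θd (optional wrapped-
  normal jitter) and render I(α) = (I_tot/4)(1 + p cos 2(α − θ)); separate
  p values for the 10-px edge band and the interior, plus optional uniform-
  random interior axes, produce the ordered-edge/disordered-body fixture.
- **Flow movies** translate a Gaussian-band-limited periodic texture by
  exact FFT phase shifts (rigid) or advect it radially inward
  (map_coordinates, cubic).  Default fixture speeds correspond to 0.5–2
  px/frame, the regime the estimators target.
- **Ensembles** are von Mises–Fisher draws about a mean axis with
  pseudo-energies increasing with angular distance from the mean (plus
  seeded noise), so the 40% energy cut is exercisable.

Cell geometry is a disk (default radius 0.3 × image size) optionally growing
a half-disk protrusion to full size over the movie.  All generators are
bit-for-bit reproducible from the seed; `noise_model='none'` is fully
deterministic.

What passing tests show: the analysis chain inverts its own forward models
exactly, the estimators are unbiased at realistic SNR, and the geometric
conventions are self-consistent under rotation and rigid motion.  What they
do not show: robustness to real-microscope effects absent from the
generators — high-NA depolarization mixing, photobleaching, camera gain
structure, evanescent-field depth variation, irregular cell morphology — nor
the study's biological values (e.g. θd = 95.4° ± 10.1°), which require the
original movies and structural ensembles.

## Problem sizes

Test fixtures use 128–192 px frames, 8–12 frame movies, and ensembles of
10²–4·10³ members; the in-silico validation runs five 128-px scenes.  These
sizes were chosen as the smallest at which boundary discretization effects
stop dominating the estimators under test.

## Known limitations

- The background estimator assumes background-majority images.
- Per-ROI θd carries up to ~2.5° of boundary-discretization error on small
  cells; use cell-level weighted summaries for quantitative comparisons.
- Registration's `auto` method estimates translation only; use bead images
  for rotation/scale.
- The quad central-ROI background subtraction removes the cell's own base
  intensity along with camera background (by design, matching the
  calibration protocol); absolute p values are therefore comparable only
  within an experiment.
- The twofold dipole ambiguity means all reported orientations are modulo
  180°; tilt-scan consistency cannot distinguish θ = 0° from θ = 180°.
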