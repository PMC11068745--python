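# Methods

This note documents the models, conventions and numerical choices
behind `migrochip`, and what the synthetic-data validation does and
does not establish about real microscopy data.

## Coordinate and unit conventions

All physical coordinates are continuous, in micrometres, with the
origin at the channel entrance (microchannels) or the arena corner
(micropillar chambers).  Times are minutes.  Images use 0-based pixel
indices; a position maps to pixels as `x_px = x_um / pixel_size`, a
position being the center of its pixel.  The default pixel size of
0.65 µm/px is typical for a 10× objective on a CCD camera but is a
placeholder: calibration of the actual optics should always replace
it, and the frame interval is always read from image metadata rather
than assumed, since acquisition cadence varies between experiments.

## Motion model (synthetic cohorts)

The 2-D simulator is a discrete-time persistent random walk: per step,
the heading receives a Gaussian increment of standard deviation
`angular_noise_sd` (radians/step, a rotational-diffusion surrogate) and
the cell advances by `speed · frame_interval`, with per-step speeds
drawn from N(`mean_speed`, `speed_sd`) truncated at zero.  The
truncation biases the realized mean upward when `speed_sd` is large
relative to `mean_speed`; cohort parameter-recovery checks therefore
run at `speed_sd = 0`, where the draw is exact.  This is the simplest
model with independently tunable persistence and speed variability;
the assays it feeds measure only per-step geometry, so no inertia or
speed–persistence coupling is modeled.

Closed-form limits used in testing: heading increments N(0, σ) give
E[cos α] = exp(−σ²/2) for the turning angle α; σ = 0 gives straight
lines (0% confined); `angular_noise_sd = inf` is implemented as a
uniformly redrawn heading per step, making α exactly uniform on
[0°, 180°] so the expected percent of motile time confined is
100·(150/180) = 83.3%.

Pillar and arena-wall collisions are resolved by specular reflection
(up to 32 bounces per step), which preserves walked path length and
keeps the zero-noise limit deterministic; redrawing the heading on
contact would not.  Note that measured trajectory length sums sampled
frame-to-frame displacements (chords), so reflections within a step
shorten the measured length relative to the distance walked — the same
truncation a microscope's frame cadence imposes on real cells.

The 1-D channel simulator pins the lateral coordinate to the channel
centerline; waiting cells sit at axial positions in
[−entry_margin, 0) and begin moving with a per-frame Bernoulli entry
probability, so the number of ground-truth entries is controllable and
recorded per track.  An optional `speed_profile(t)` override lets
cohorts change mean speed over the run (e.g. fast-then-slow).

Determinism: every generator draws all randomness from one
`numpy.random.default_rng(seed)`, so identical config + seed reproduce
tracks, movies, stacks and Ct tables bit-for-bit.

## Rendering and detection

Nuclei are rendered as isotropic Gaussian blobs (default σ = 1.6 µm,
FWHM ≈ 3.8 µm — a nucleus under a 10× objective) on a constant
background with additive Gaussian read noise.  No photobleaching,
drift, shape deformation or cell division/death is modeled, so
end-to-end tracking results bound performance under ideal illumination
only; on real movies the detector's threshold and the linker's gate
need adjusting to the data.

Detection: Gaussian smoothing (σ = 1 px), Otsu threshold on the
smoothed frame (a fixed absolute threshold is available), connected
components with a minimum area, intensity-weighted centroid on the raw
frame.  A constant frame yields no detections; NaN pixels are an input
error.  Touching nuclei are not split (no watershed); at device cell
densities merges are rare and transient, and appear as short track
splits rather than position errors.

Linking: greedy mutual-nearest-neighbor between consecutive frames —
pairs that are each other's nearest unmatched neighbor are linked,
closest first, under a hard displacement gate; ties break toward the
smaller displacement, then the smaller track index.  Unmatched
detections seed new tracks; gap closing is opt-in (`max_gap`, default
0, since at a 2–3 min cadence detection gaps are rare).  In the
intended regime — inter-cell separation well above the per-frame
displacement — the greedy matching coincides with exhaustive
minimum-total-displacement assignment (tested against a brute-force
oracle); global assignment optimization is deliberately out of scope.

## Channel statistics

Channel motion is treated as one-dimensional: speeds use the axial
projection of the displacement, since the 4 µm channel width confines
lateral motion to sub-cell scale.  A cell *enters* when its axial
coordinate crosses the entrance from below and subsequently reaches
`entry_margin` (default 10 µm, about one cell length) — the margin
makes the count robust to detection jitter for cells grazing the
entrance.  *Speed fluctuation* is the per-track sample standard
deviation (n−1) of instantaneous speeds, in µm/min; because this
statistic's normalization is a convention rather than a law, a
coefficient-of-variation variant is available behind
`statistic="cv"`.  The density profile bins each entered cell's
furthest axial distance into half-open [k·w, (k+1)·w) bins, so counts
conserve the entered-cell total; `fraction_within` reports the share
of entered cells whose furthest distance is below a cutoff (default
200 µm).  With no entered cells, the fraction is reported missing
(NaN), never zero.

## Pillar statistics

The turning angle at an interior track point is the angle between the
displacement vectors over three consecutive timepoints, in [0°, 180°];
it is undefined (NaN) when either displacement is zero, and consecutive
frames only are used — a missing detection breaks the triple rather
than interpolating.  A step is *motile* when its displacement exceeds
`motile_min_disp` (default 0.65 µm, one pixel-equivalent per step;
"motile time" has no standard definition so the threshold is exposed).
Among motile steps with a defined angle, α < 30° is persistent and
α ≥ 30° confined; the defining inequalities are strict on both sides,
leaving exactly 30° unassigned, so the boundary is a convention — it is
assigned to confined (conservative toward confinement).  Percent of
motile time confined = 100 × confined / (confined + persistent), NaN
when the denominator is empty.  Trajectory length is the sum of step
displacements (path length, not net displacement); top-N selection
sorts by that length with ties broken by track id.

## Morphometry

Cells are segmented in 3-D from the phalloidin (cortical actin)
channel: Otsu threshold, connected components, hole-filling so the
membrane shell's interior belongs to the mask, minimum-volume filter,
and border-touching cells flagged (excluded from tables by default).

*Projected inner surface* is the area of the z-axis maximum projection
of the filled mask, in µm².  The z-projection convention matches how
these stacks are presented and measured — for a ~7 µm lymphocyte it
yields tens of µm² — and is the primary output; the 3-D marching-cubes
mesh area is exposed separately as `surface_mesh_um2` because the two
differ by ~4× for a sphere and must never be conflated.

*Spikes* are detected on the projected outline: the projection is
morphologically opened with a disk (default radius 0.8 µm), which
removes protrusions thinner than the disk and leaves a smooth reference
body (opening, not closing, is the operation that removes thin
protrusions — closing would fill concavities and leave spikes in the
reference).  Residue components attached to the body whose maximal
Euclidean distance from the body exceeds `min_spike_length` (default
1 µm) count as spikes, with that distance reported as the spike length.
Detection is 2-D by design; spikes pointing steeply out of plane
foreshorten on the projection and can fall below the length threshold.

*Organelle content*: the organelle channel is thresholded (Otsu within
the cell's bounding box) and intersected with the cell mask, so the
organelle volume can never exceed the cell volume and the percent
occupied is hard-bounded to [0, 100].

The synthetic 3-D cells provide exact ground truth (analytic ellipsoid
area/volume, spike count and length, exact organelle voxel count) but
are idealized: sharp shells, in-plane rod spikes, isotropic noise.
Passing these oracles establishes correctness of the measurement
geometry, not robustness to real staining variability, anisotropic PSFs
or touching cells.

## TSDR demethylation

`demethylation_percent` computes `100 / (1 + 2^(Ct_meth − Ct_demeth))`
exactly as assay protocols print it (`as_printed`).  The sign is worth
pausing on: a fully demethylated template amplifies earlier in the
demethylation-specific reaction, making ΔCt = Ct_meth − Ct_demeth
large and *positive* and the printed expression small — protocols
disagree on which Ct is subtracted from which, so a `flipped`
convention (exponent negated) is provided and the convention used is
recorded in every output row rather than silently corrected.  The
function is strictly decreasing in ΔCt under `as_printed`, maps ΔCt = 0
to exactly 50%, and satisfies value(ΔCt) + value(−ΔCt) = 100.  The
synthetic generator inverts the formula (ΔCt = log₂(100/f − 1)), so the
zero-noise round-trip is exact; fractions of exactly 0 or 100 would
require infinite ΔCt and are rejected.  No amplification-efficiency
correction is applied.

## Problem sizes and tolerances in the validation suite

The test and acceptance runs use sizes at which each check's
statistical resolution comfortably exceeds its tolerance: 10,000 random
triples for the turning-angle oracle (agreement to 1e−9°); 500 tracks ×
100 steps for the uniform-heading confinement law (within 3 Monte-Carlo
SEs of 83.3%); 5 noise levels × 200 tracks for monotonicity; one
rendered movie of 50 cells × 100 frames at SNR 100 in a 650 µm field
for tracking recovery (≥ 95% of positions within 1 px, cohort mean
speed within 5%); 300 simulated cells for channel entry (exact match to
ground truth) and 10,000 uniform draws for the density-fraction law
(within 3 binomial SEs of 200/900); 0.2 µm voxels for the sphere
oracles (area and volume within 5% of analytic values) and stars with
k ∈ {3, 5, 7, 11} spikes (exact recovery); 1,000 Ct pairs at 0.2-cycle
noise for the TSDR round-trip (within 1 percentage point).  Monte-Carlo
assertions use law-derived expectations with data-estimated standard
errors, never tuned constants.

## Known limitations

- No drift correction, photobleaching model, or nucleus-shape change;
  the renderer is a testing instrument, not an optics simulator.
- The linker is greedy; adversarial equidistant configurations can
  link suboptimally (they do not arise at assay densities).
- Spike detection is 2-D (projection-based) and reports radial extent
  beyond the smoothed body, not arc length along a curved protrusion.
- The channel simulator moves entered cells monotonically forward;
  direction reversals inside channels are not modeled, so
  reversal-sensitive statistics exercise real data paths only through
  the detector, not the generator.
- Speed-fluctuation values depend on frame interval (finite-difference
  speeds); comparisons across datasets require matched cadence.
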