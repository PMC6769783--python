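# Methods

`sxtmorph` models the quantitative arc of a cryo soft X-ray tomography
(cryo-SXT) morphometry study of mitochondria, from a known digital specimen
to two-group statistics. This note records the model, its assumptions, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Forward model and units

Transmission imaging follows the Beer–Lambert law: a parallel beam at tilt
angle θ produces a frame

    T(x, y) = I(x, y) / I0(x, y) = exp( −∫ µ(r) dt ),

where µ is the linear absorption coefficient (LAC). Path lengths are
carried in µm so LAC stays in µm⁻¹, the unit water-window measurements are
reported in; all lengths elsewhere are nm, with the working pixel size
defaulting to 11.8 nm. The absorbance conversion is `A = −ln T` after
flat-field normalization (`apply_flatfield` divides by I0 and removes any
multiplicative incident-intensity pattern exactly in the noiseless case).

Geometry: a single tilt axis (`y` in the (z, y, x) voxel convention, 0-based
indices, voxel centers at integer coordinates), beam along `z` at zero tilt.
The line integral is computed by rotating the volume in the (z, x) plane
(linear interpolation by default; the order is a knob) and summing along
`z`. The default tilt scheme covers 140° in 1° steps — 141 projections and
a 40° missing wedge, which elongates reconstructed objects along the beam
axis; the test suite measures that bias explicitly (a sphere reconstructed
from 140° data has higher shape anisotropy than from 180° data).

Photon noise is Poisson at a configurable incident dose per pixel (study
default 5000 photons, giving ≲1% transmission noise). Zero-count pixels are
clamped to half a count so the logarithm stays finite; noisy pixels with
T > 1 produce small negative absorbances that are deliberately kept —
clipping them would bias reconstructed LAC downward.

## ART reconstruction

The solver is block-Kaczmarz ART: per projection, the residual between
measured and reprojected absorbance is backprojected along the rays, scaled
by the relaxation factor and the inverse ray weight; projections are
visited sequentially in angle (the access order is a knob because ART
output depends on it). Defaults are 15 sweeps at relaxation 0.01 — standard
practice for cryo-SXT tilt series — with a nonnegativity projection after
each sweep (LAC is physical; disabling it recovers plain linear ART, which
the linearity test exercises).

One numerical subtlety: the Kaczmarz row norm ‖a_i‖². With linear
interpolation a ray splits each plane's weight dt into (w, 1−w); averaging
w² + (1−w)² over fractional offsets gives 2/3, so the row norm is
(2/3)·nz·dt², not the binary-footprint estimate nz·dt². Using the corrected
norm keeps the effective relaxation at its nominal value; the cruder
estimate silently under-relaxes by a third and leaves the reconstruction
visibly under-converged at 15 sweeps.

At these settings a centred sphere (radius 16 voxels, 64³ grid, µ = 0.45
µm⁻¹) reconstructs with a reprojection residual below 5% and an in-mask
mean LAC within 15% of truth despite the missing wedge; with ~180° coverage
the voxel RMSE to truth decreases monotonically over all 15 sweeps.
Convergence diagnostics (per-sweep relative residual, a divergence flag set
when the residual grows three sweeps running) are recorded in the
reconstruction's provenance rather than raised.

No fiducial-based alignment is implemented: synthetic geometry is exactly
known, so the manual alignment step of a beamline workflow is replaced by
the identity. This is a stated limitation — alignment error is one source
of real-data variance the phantoms do not model.

## Digital-cell phantoms

A phantom is a spherical cytoplasm region (default LAC 0.2 µm⁻¹) containing
one nucleus (0.25), N ellipsoidal mitochondria, and gold fiducial beads
(200 nm, LAC 8.0 µm⁻¹, matching the bead nominal used for calibration).
Two regimes emulate the biology of interest: "S-like" cells carry
elongated, dense-matrix organelles (axis ratio 4:1:1, µ = 0.45 —
condensed-matrix phenotype) and "R-like" cells near-spherical, lucent ones
(1.2:1:1, µ = 0.35 — orthodox phenotype). Organelle size is parameterized
by the equivalent-sphere radius, so arms with the same radius distribution
are volume-matched by construction regardless of shape — which is what
makes the "no volume difference" null test meaningful.

Placement is rejection sampling with an orientation-aware overlap test on a
margin-enlarged ellipsoid (default clearance 2–3 voxels: organelles have
membranes and must stay separable downstream). Fiducials sit on the support
film, modelled as a thin y-slab at the base of the cell. This placement is
not cosmetic: with a single `y` tilt axis each y-slice reconstructs
independently, so bead streak artefacts — severe, because gold is ~20×
denser in LAC than any organelle — stay confined to rows no organelle
occupies. The pipeline zeroes those rows before segmentation and the
organelle field is artefact-clean, while the beads remain available for
calibration.

Randomness comes from named substreams of one master seed (per cell, per
arm, per noise realization); a crowded placement draw is retried with the
next seed from the same substream (bounded), so a population is a pure
function of its master seed. What the phantoms do not model: cristae
substructure, tubular networks with branching, ice-thickness gradients,
detector MTF, and alignment error. Passing tests therefore demonstrate
method correctness and statistical power at the injected effect sizes, not
performance on real tomograms.

## Segmentation

Beads are detected as compact components above half the robust bead peak
(floored at 1 µm⁻¹) whose equivalent-sphere diameter is within ±40% of the
nominal 200 nm.

Organelles are segmented by a two-pass half-maximum scheme
(`segment_organelles_halfmax`). A single global threshold would place the
boundary at different heights on the blurred edge of bright (S-like) and
faint (R-like) organelles, inflating dense volumes and eroding lucent ones
— a shape- and contrast-dependent bias that would masquerade as a
biological volume difference. Instead, conservative cores above a global
core threshold (study default 0.29 µm⁻¹, above nucleus and cytoplasm
levels) are grown to their own half level, midway between the tomogram
background (median of sub-core cellular voxels) and the core plateau (upper
quartile of core values, which resists the blur shoulder). Components
smaller than `min_voxels` (speckle) or larger than `max_voxels` (the
nucleus) are rejected. Labels are assigned in decreasing size order with
centroid tie-breaks so outputs are byte-stable; a plain single-threshold
segmentation is also provided, and every metric also accepts ground-truth
labels so morphometry is testable independently of segmentation.

## Morphometry

- **Volume**: voxel count × voxel volume, exact and additive.
- **LAC**: mean and population SD under the mask. The bead calibration
  divides by the mean LAC measured inside eroded bead cores (erosion drops
  the partial-volume shell); the reported `lac_normalized` is therefore
  dimensionless and invariant under any global multiplicative gain a
  tomogram picked up — the entire purpose of carrying fiducials into the
  quantification.
- **Shape**: eigenvalues λ₁ ≥ λ₂ ≥ λ₃ of the second central moment tensor
  of mask voxel coordinates (equivalent-ellipsoid convention, matching 3D
  region-properties tools). For a continuous ellipsoid with semi-axes
  (a, b, c) these are (a², b², c²)/5, which the tests use as an oracle.
- **Fractional anisotropy**, in percent:

      FA = 100 · √(3/2) · √[(λ₁−λ̄)² + (λ₂−λ̄)² + (λ₃−λ̄)²] / √(λ₁²+λ₂²+λ₃²)

  the standard eigenvalue (Basser–Pierpaoli) form. A transcription of this
  formula that drops the squares in the numerator is identically zero;
  only the form above satisfies the defining limits — 0 for an isotropic
  body, 100 for a fully one-dimensional one — and the [0, 100] range, and
  those limits are what the tests pin down. FA is scale- and
  permutation-invariant; degenerate masks (< 4 voxels or rank-deficient)
  are flagged, not raised.
- **2D area**: pixel count × pixel area on labelled slices, the
  micrograph-style analogue measure.

## Group statistics

Welch's t test is the default (arms of unequal size and variance; the
pooled-variance Student form is available by flag), with mean ± SEM,
medians, and stars at p < 0.05 / 0.01 / 0.001. Aggregation follows the
reporting conventions of organelle studies: FA is compared on the pooled
per-mitochondrion table (~100+ organelles per arm), while normalized LAC
(per-cell means) and total mitochondrial volume (per-cell sums) are
compared per cell (7 vs 7).

The respirometry helpers implement oxygraph bookkeeping: ROX (residual
oxygen consumption after rotenone + antimycin A) is subtracted from each
steady state, flooring at zero with a warning; coupling efficiency is
(routine − leak)/routine on corrected fluxes, invariant under flux
rescaling; spare respiratory capacity is maximal minus basal respiration.
A seeded Gaussian trace generator provides test data at stated state means.

## Problem sizes and runtime choices

The end-to-end study runs 7 + 7 cells with 15–20 mitochondria each on 56³
grids at a 40 nm voxel. The coarser-than-beamline voxel is what makes a
whole two-arm study (14 ART reconstructions × 141 projections × 15 sweeps)
run in minutes on one core while every object — organelle minor axis,
bead diameter — still spans ≥ 3 voxels. The ART validation fixture uses a
64³ grid with a radius-16 sphere so the partial-volume shell is a small
fraction of the mask. Statistical conclusions (direction of FA and LAC
contrasts, null volume result) are scale-free; absolute nm³ volumes simply
scale with the voxel choice.

## Known limitations

- Parallel-beam, single-axis geometry; no zone-plate optics or depth of
  focus.
- Ellipsoidal organelles cannot express the interconnected-network
  morphology of elongated mitochondria; FA captures elongation, not
  connectivity.
- The half-max segmentation assumes locally flat background around each
  organelle; steep background gradients would shift boundaries.
- Bead calibration corrects only global multiplicative gain, not spatially
  varying artefacts.
- The missing-wedge FA bias is measured, not corrected: round objects
  reconstruct with FA well above zero (~15–30 at these settings), so
  absolute FA values are comparable only within one acquisition geometry.
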