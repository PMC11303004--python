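# Methods

This note records the model behind each stage, the parameters that
matter, the design choices made where the design was genuinely open, and
what the synthetic benchmarks do and do not demonstrate.

## Conventions

Images are indexed `img[y, x]` with the center at `((n−1)/2, (n−1)/2)`;
x runs along columns, y along rows. Shifts are the translation that moves
the tube onto the image center, expressed in the rotated (axis-vertical)
frame; the along-axis shift is identically zero because a straight tube is
translationally invariant along its axis. Euler angles are ZYZ: φ about
the volume z axis (azimuth around the tube), θ about y (polarity, 90° or
270°), ψ in plane. The in-plane angle ψ of a tube is measured from the
image y axis such that the axis direction is `(sin ψ, cos ψ)`; rotating an
image by −ψ verticalizes its tube, and the projection orientation matrix
carries a fixed 90° offset so that at θ=90°, ψ=0° the volume z axis
(tube axis) lands on image y with the same sign convention. Volumes are
cubic, `vol[z, y, x]`, tube axis along z.

## Synthetic decorated tubes

The bilayer is a body of revolution with radial density
`g(r) = A·[exp(−(r−r_out)²/2σ²) + exp(−(r−r_in)²/2σ²)]`,
`r_in = r_out − d`. Defaults follow the experimental system: outer radius
137.5 Å (the observed 25–30 nm width range, taken at its middle),
leaflet separation d = 35 Å (typical bilayer phosphate spacing), shell
width σ = 7 Å. Noiseless tube images are rendered *analytically*: the
projection perpendicular to the axis is the Abel transform
`P(x) = 2∫ g(√(x²+s²)) ds`, evaluated by quadrature and mapped through
each pixel's perpendicular distance to the axis — exact at any in-plane
angle, no interpolation. Particles are small non-negative density grids
(default: a Gaussian blob of σ = 45 Å, matching a ~465 kDa globular
protein at the simulated pixel size; a two-lobe dumbbell is available as
an asymmetric test shape) placed at radius `r_out + attachment gap`
(default gap 20 Å — the tether length varies in reality; this is a fixed
representative value), at random axial/azimuthal positions with a minimum
axial spacing, and rendered by rotating and ray-summing the grid. Azimuth
0° points toward the viewer (projects onto the axis line); 90° projects
at the full decoration radius to +x. Noise is additive white Gaussian.

**SNR definition.** `snr` follows the conventional simulation definition:
signal variance over the signal's own support divided by noise variance.
For decorated segments the signal of interest is the particle layer (the
tube is subtracted before picking, so scaling noise to the tube's
variance would tie "SNR" to an object that is removed); for particle-free
segments (alignment benchmarks) it is the tube projection itself.

The simulator also emulates a parent micrograph: one straight tube across
a large rectangular field, decorated, cut into overlapping square
segments at a fixed stride with the segment origin recorded — the same
physical particle then appears in several segments, which is the input
duplicate elimination needs. Not modelled: tube curvature (straight tubes
dominate the real preparations; curved ones are meant to fail alignment
QC), ice gradients, beam-induced motion, detector transfer functions,
aberrant "ghost"/"dark" tube classes. A standard CTF (optional) is
available for realism; CTF estimation/correction is out of scope, and
subtraction operates in the possibly CTF-affected image domain — valid
because the projected average and the data share the same CTF to first
order.

## Tube alignment

ψ estimation is two-stage. The coarse stage scores every candidate angle
(default 1° grid over [0°, 180°)) by the variance of the
chord-length-normalized Radon profile of the circularly masked segment;
the variance peaks when the rays run along the tube, and the
peak-to-median anisotropy of the curve is the detection score (default
floor 2.0; pure-noise images score ≈0.3–0.5, tubes at SNR 0.2 score >3).
The refinement stage is differential: rotate to near-vertical, measure
the tube's perpendicular position in the top and bottom halves by 1D
profile correlation (per-column medians along the axis, robust to bright
decorations), and update ψ by the arctangent of the differential shift
over the lever arm; 2–3 iterations converge below 0.1°. An earlier
candidate — scoring rotations of the 2D autocorrelation by column-sum
variance — was implemented and rejected: it carries an irreducible ~1°
bias toward grid-aligned angles from its square support window, visible
even noiselessly. The two-stage estimator is unbiased (noiseless error
~0.002°) and reaches ~0.1° RMS at SNR 0.2 on 256 px segments; precision
scales as (box size)^{3/2} through the lever arm.

Centering: the y-averaged, lightly smoothed (σ = 2 px) profile is scanned
for local maxima (prominence ≥ 10% of the span); the outermost pair is
taken as the tube edges, with a plausibility window on their separation,
and the shift is the distance from their midpoint to the image center,
sub-pixel refined parabolically. For a two-shell tube whose leaflet
tangent peaks merge under the projection, the outermost *resolved* maxima
are used — the midpoint, which is what the shift needs, is unaffected by
which shell pair survives smoothing. φ is drawn uniform on [0°, 360°) and
θ from {90°, 270°} with equal probability: azimuth and polarity of a
near-featureless tube are unobservable in a single projection, and
randomizing them is precisely what makes the subsequent reconstruction an
azimuthal average.

## Azimuthal average

Reconstruction is direct Fourier inversion: each aligned segment is
inserted as a central slice at (φ, θ, 0) with trilinear weighting on a
2× oversampled grid and per-voxel weight normalization (Wiener constant,
default 10⁻³ of the peak weight); a cosine taper on the image edges
limits wrap ringing. `smooth_z` replaces every slice by the mean over the
central fraction (default 0.8, excluding wrap-around edge slices), making
the volume z-invariant.

Two QC metrics: `cylindricity` = 1 − (off-rotational-average power)/(total
power) inside the inscribed cylinder, where the rotational average is a
least-squares cubic-spline model of density vs radius (histogram binning
of a sharply shelled profile leaks bin-interpolation error into the
apparent asymmetry; the spline does not). With 360 uniform azimuths the
reconstruction scores >0.999; with ~20 random azimuths, angular sampling
gaps dominate and the score drops — that is a real property of sparse
random-φ direct inversion, and the pipeline reports it per run. The
second check is inverse-Abel consistency: the volume's radial profile
must match the inverse Abel transform of the mean aligned projection
(computed with a singularity-free substitution and spline derivatives).

For the *subtraction model* the pipeline uses `ring_average=True`: the
accumulated Fourier samples are normalized per ring of constant
(k⊥, k_z) instead of per voxel. The Fourier transform of a body of
revolution is constant on such rings, so ring averaging is the natural
estimator when the target is the azimuthal average itself; it fills the
angular gaps of a few dozen random azimuths and removes the sparse-view
radial ringing they otherwise cause (model-profile error ~3× smaller at
20 segments). The per-voxel mode remains the default of `reconstruct`
(and is what cylindricity is computed on), since it makes no symmetry
assumption.

Projection of a z-smoothed average uses an exact fast path: the volume is
fully described by one slice, so the projection is a 1D ray-sum profile
of that slice mapped through each pixel's perpendicular-distance
coordinate — valid at any output size (a 128-voxel average can be
projected into a larger segment frame without lateral truncation) and
~100× faster than volume resampling. General orientations fall back to
trilinear/spline volume resampling with the axial coordinate clamped
(axial extension) and lateral out-of-bounds set to zero.

`refine_against_average` re-optimizes ψ and the perpendicular shift per
segment against the projected average using the same differential
half-profile scheme as the aligner (grid-scan approaches proved biased:
rotation interpolation slightly smooths the image, which can raise the
correlation away from the true optimum). The align→average loop stops
when mean |Δψ| < 0.2° and mean |Δshift| < 0.25 px, or after 5 iterations.

## Subtraction

Per segment: project the average at the segment's angles/shifts, fit
`α = argmin‖I − α·P‖²` over the tube mask (|P| > 10% of its maximum — so
off-tube background does not bias the scale), subtract `α·P` from the
whole frame. The α fit is robust by default (two reweighting passes
clipping residuals beyond 2.5 RMS) so on-tube particles do not inflate
it. Per-segment scaling is used rather than a global scale because ice
thickness and dose vary segment to segment.

The pipeline enables two further passes, both the package's own design:
a local re-optimization of ψ/shift against the projected average (grid
±0.75°/±1 px, minimizing the masked residual — the reference-based final
alignment round the method calls for before subtracting), and removal of
the axially invariant residual (the per-column median of the subtracted
segment in the aligned frame, mapped back through the distance
coordinate). Anything invariant along the axis is tube-like by
definition — in particular the faint ring that dispersed decorations
leave in the average — while localized particles are untouched because a
median along the axis ignores them. Under dense decoration (several
particles per segment) the axial median does absorb a modest fraction of
particle flux (~10% at the benchmark's four particles per 192 px
segment); the template-picking threshold default is calibrated for this
chain, and template-free classification benefits strongly from the
cleaner boxes, so the cleanup is on by default in the pipeline. Residual-based automatic segment
rejection is *not* performed; the per-segment residual RMS is reported in
the metadata for downstream triage.

## Particle recovery

**Template picking** is a greedy matched filter: normalized
cross-correlation against (rotations of) the template, accept the
strongest peak above threshold, subtract the least-squares-scaled
template at that site, recompute, repeat. The explained-signal
subtraction stops a bright particle's correlation tails from displacing
or masking neighbours (median localization error drops from ~2 px to
<1 px at the benchmark noise level). NCC is zeroed where the local window
variance vanishes (it is numerically meaningless there), and peaks within
half a template of the segment border are excluded — a clipped particle
cannot be localized, and with overlapping segments it is always interior
to a neighbour. Default threshold 0.25 (calibrated on simulation: true
particles at the benchmark SNR score ≳0.3, the noise background tops out
near 0.15).

**Picking-by-classification** tiles each segment into overlapping
sub-boxes (grid spacing must not exceed twice the alignment shift search,
or particles midway between box centers cannot be centered by any box —
at the benchmark geometry 6×6 boxes of 64 px on 192 px segments, ~50%
overlap), light low-pass filters the boxes (σ = 2 px, well below the
particle scale: lets references lock onto structure instead of noise),
and runs hard multi-reference alignment classification: random partition,
then iterate assignment (best correlation over classes × in-plane
rotations × a bounded FFT shift search) and reference re-averaging, with
references re-centered on their intensity centroid each iteration so
class membership translates into a *centered* pick; winning shifts are
parabolically sub-pixel refined at the end. Classification proceeds in
rounds: each round emits picks from classes whose references concentrate
their power centrally (fraction of reference power inside a central disc
of 0.2× box size ≥ 0.4 — genuine particle classes are compact central
blobs after re-centering), discards members of clearly incoherent
classes (< 0.15 — membrane residual is elongated, noise-alignment
artifacts spread power across the frame), and re-classifies the
ambiguous remainder, up to four rounds. The concentration heuristic
stands in for the operator who would normally pick classes by eye and
can be overridden from the CLI. A final rescue pass re-aligns every
never-emitted box against the most compact reference the classification
discovered and accepts boxes whose correlation reaches the lower
quartile of the emitted boxes' own scores — self-calibrating, still
template-free (the reference comes from the data), and it recovers
particles whose boxes first co-classified with partially visible
neighbours into rejected classes.

**Duplicate elimination**: two picks are duplicates iff their global
distance is below a gate (default 21 px, half the benchmark particle's
diameter) *and* the peak NCC of their boxed images over a ±4 px shift
search exceeds 0.8. Boxes are extracted from each pick's own segment — picks of
the same physical particle in overlapping segments see nearly identical
pixels (shared noise included) and correlate strongly; different
particles never do. The shift search covers the sum of two picks'
localization errors; the distance gate defaults to half the particle
diameter. Candidates are visited in score-sorted order with deterministic
tie-breaks, so the result is order-independent and idempotent, and the
highest-scoring member of each duplicate group survives.

## Benchmarks: what they show

All study geometries use a 4.32 Å/px pixel (3×-binned 1.44 Å detector
pixel — subtraction-stage processing is routinely run binned):

* ψ/shift recovery: 20 particle-free tubes, 256 px boxes, SNR 0.2.
* Average fidelity: 360 noiseless uniform-φ views of a reduced tube
  (outer radius 60 Å) reconstructed at 64³ — the full-size tube does not
  fit a 64-voxel box, and the small profile exercises identical code.
* Subtraction: 30 noiseless bare tubes (shell residual), 20 noiseless
  single-particle segments (particle-layer NCC), full-size profile.
* Picking: 50 segments of 192 px, 4 particles each, SNR 0.3;
  recall/precision scored at a 5 px match radius (an eighth of the
  particle diameter) plus the median centering error.
* Dedup: a 3-fold-overlap micrograph, 5 particles, SNR 0.5.
* Determinism: the full pipeline twice at one seed, byte-identical picks.

Passing these shows the algorithms are correct and well-calibrated on
ideal straight tubes with known ground truth. It does not demonstrate
robustness to curved or aggregated tubes, incompletely subtracted
"ghost" membranes, CTF mismatch between segments, or crowded/overlapping
decorations — on real data those are handled by the surrounding 2D
classification triage, which is standard-tool territory.

## Numerical notes and limitations

* Reconstruction values are arbitrary-linear in scale; subtraction's α
  absorbs this.
* The spline rotational average restricts its fit to the inscribed
  circle (cube corners are too sparse for stable knots) and clamps
  evaluation beyond it.
* Tie-breaks: duplicate elimination sorts by (score, x, y, segment);
  classification resolves equal correlations by class order under a
  fixed seed.
* Degenerate inputs fail loudly: empty stacks, all-noise stacks (no tube
  detected), zero projections, non-cubic volumes, k > n classes.
* The edge detector requires two resolved profile peaks; very low
  contrast or merged-peak profiles outside the width window are flagged
  and excluded rather than guessed.
* At desk-scale segment counts the cylindricity of the per-voxel
  reconstruction mostly reflects azimuthal sampling gaps, not alignment
  quality; judge alignment by the refine-loop's Δψ/Δshift report
  instead.
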