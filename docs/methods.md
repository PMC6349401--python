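# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of `punctaloc`.

## Scope and conventions

All pixel coordinates are 0-based `(z, y, x)`; exported tables carry this
convention in a header comment.  Physical calibration (µm/pixel laterally,
µm/layer axially) is read from TIFF metadata (ImageJ or OME) or supplied via
config, but the algorithm operates in pixel units throughout: its fixed
length scales (the 20/40 px edge-attenuation distances) are defined in
pixels, and the axial sampling of confocal stacks is too coarse and too
anisotropic for physical 3D distances to be meaningful at the pixel level.
The cell mask is computed from one designated *segmentation channel*
(default `green`) and reused for both channels.

## Cell segmentation

Per-layer Otsu thresholding (256-bin histogram; pixels strictly above
threshold are foreground) is followed by a sum projection of the binary
layers.  Disjoint islands of the projection are labelled with
**4-connectivity** — the conservative choice that never bridges diagonally
touching objects — and the island with the largest projected *pixel sum* is
selected.  Summing layer counts rather than footprint area makes the
criterion a 3D volume proxy: an object present in many layers beats a
larger object present in one.

Each layer mask is then cleaned by morphological **closing then opening**
with a disk of radius 3 px (configurable `struct_radius`); closing first
fills pinholes before opening removes specks.  A second Otsu round over the
layer's in-mask intensities identifies dark intracellular vacuoles, with two
safeguards the basic recipe lacks:

* **Minority rule.**  A vacuole split must label fewer than half the in-mask
  pixels dark.  When the strongest histogram split instead separates a
  bright minority (cell rim, puncta) from the bulk, the search recurses into
  the lower class (up to 3 levels) to look for a darker minority there.
  Without this, a bright cell rim makes Otsu discard the entire cell body.
* **Compactness rule.**  The dark class is morphologically opened with the
  same structuring element before removal, so noise speckle straddling a
  unimodal histogram split is not carved out of the cell body; only compact
  dark regions at least the size of the structuring element are treated as
  vacuoles.

Degenerate inputs are fail-safe: a constant layer thresholds to an empty
mask in round one and removes nothing in the vacuole round.  Cells whose
vacuoles exceed half a cross-section violate the minority rule and are not
removed — a known limitation.

## Fluorescent foreground

Per layer and channel, the diffuse cytoplasmic background is estimated by a
median filter (disk, default radius 15 px — chosen to exceed the radius of
the largest expected focus so foci survive subtraction; configurable) and
subtracted; negative values are clipped to zero, making the foreground an
enrichment map.  Before filtering, out-of-mask pixels are replaced by the
layer's in-mask median so the cell boundary does not leak zeros into the
estimate; this also makes the foreground exactly zero for any constant
in-mask image and invariant to constant offsets.  Integer-valued layers use
the fast histogram-based rank median; float layers the exact scipy filter.
Grayscale opening then closing with a 1-px disk removes shot-noise spikes.

Edge attenuation multiplies each in-mask pixel by `f(d) = min(d/40, 1)`
where `d` is the **2D** Euclidean distance (per layer) to the nearest
out-of-mask pixel: 0 at the edge, 0.5 at 20 px, 1 at and beyond 40 px.  The
distance is per-layer because axial and lateral sampling are incommensurate;
a 3D pixel distance would mix units.

## Focus detection, segmentation, collation

Detection is a per-layer multiscale Laplacian of Gaussian.  Defaults:
σ ∈ [2, 8] px over 5 scales, covering foci of roughly 1–3 µm diameter at
the 0.05–0.15 µm/px sampling of high-NA confocal imaging (a Gaussian-profiled
focus of width σ_b elicits its strongest scale-normalized response near
σ ≈ σ_b).  The response threshold is **relative**: 0.1 × the strongest
response anywhere in the cell (all scales, all layers).  Overlapping
detections are resolved by non-maximum suppression.  A relative threshold
adapts to exposure but implies that a cell containing *no* genuine foci will
report its brightest noise fluctuations; detection counts from featureless
cells should be interpreted with the background rate, never alone.

Each seed markers a watershed on the negated foreground restricted to the
support `{foreground > 0}`, so basins never contain background pixels —
flooding the whole plane would assign cytoplasm to foci and corrupt both
intensity and overlap metrics.  Seeds falling on zero foreground are dropped
with a warning.  Focus intensity is the summed foreground over the basin.

2D basins are collated into 3D objects by connecting any two basins in
adjacent layers (|Δz| = 1) that share an (y, x) pixel, and taking connected
components of that graph; the pairwise adjacency relation is closed
transitively, so a basin overlapping two disjoint basins in the next layer
fuses all three.  Collation conserves voxels by construction.

## Overlap metric and randomized null

A focus's overlap fraction is the number of its voxels lying inside the
union of the other channel's basins, divided by its total voxel count, with
both counts summed over all layers (a volume-based metric).  The per-cell
summary is the unweighted mean of per-focus fractions; a volume-weighted
mean (total overlapped / total volume) is emitted as a secondary column.
No threshold declaring a focus "colocalized" is imposed.

The null model re-places each focus rigidly — identical per-layer shapes,
the same (dy, dx) in every layer plus an integer z-shift keeping all slices
in the stack — at uniformly random positions, rejecting placements that
leave the cell mask or collide with an already-placed focus of the same
channel.  Collision checking is within-channel only: cross-channel overlap
is the signal being measured.  Placement proceeds in decreasing volume
order (large foci first makes packing far more likely to succeed) with a
default limit of 1000 attempts per focus, after which a `PlacementLimitError`
identifies the offending focus.  Ten synthetic replicates per cell are
generated by default; each replicate and channel derives its own random
substream from the global seed (`default_rng([seed, replicate, channel])`),
so any replicate is individually reproducible.  The *exceedance count*
(replicates whose mean overlap ≥ observed) is reported as a descriptive
statistic, not a calibrated p-value — ten replicates cannot resolve one.

The pixel-based Pearson coefficient over in-cell voxels is reported
alongside; it is NaN (with a warning) if a channel is constant in the mask.

## FRAP analysis

Normalization: `F(t) = R(t) / mean_pre(R)` with
`R = (bleach − bg) / (ref − bg)`.  Division by the background-subtracted
reference corrects acquisition photobleaching (which hits both ROIs alike);
division by the pre-bleach mean of the corrected ratio pins the pre-bleach
level to exactly 1.  With a noiseless reference this is identical to the
familiar two-factor double normalization
`(bleach/ref)·mean_pre(ref)/mean_pre(bleach)`; the ratio form was preferred
because it makes "pre-bleach mean = 1" exact rather than approximate under
reference noise.  A non-positive background-subtracted reference at any
frame is an error.

The recovery model is a single exponential,
`F(t) = f0 + (f_inf − f0)(1 − e^{−(t − t_bleach)/τ})`, the standard
empirical model when one exchange process dominates; the model name is
recorded in every output row so results remain interpretable.  Time zero is
the first post-bleach frame.  Initialization is data-driven: `f0` from the
first post-bleach value, `f_inf` from the mean of the last 10 % of frames,
τ from the time to reach halfway between them.  Fitting is least squares
(`scipy.optimize.curve_fit`, τ bounded positive).  The mobile fraction
`100·(f_inf − f0)/(1 − f0)` is clamped to [0, 100] with a warning if the
fit strays outside.  At least 10 post-bleach frames are required, and the
first post-bleach value must lie below the pre-bleach level.  Half-bleach
traces run through the same model; the mode flag only annotates output.
Batch runs report per-trace fits plus group mean ± sd and N; per-trace
failures are recorded in the table, not fatal.  ROI extraction from movies
is out of scope: traces enter as CSV of ROI means.

## Synthetic data

The stack generator emulates the target imaging situation: one bright,
irregularly shaped cell (radius perturbed by low-order Fourier modes,
cross-section tapering toward the top and bottom layers), dark ellipsoidal
vacuoles, a 3-px bright rim at the cell edge, and foci rendered as
thresholded anisotropic Gaussians (support = the 2σ ellipsoid) with random
in-plane elongation and rotation — irregular enough to exercise watershed
and collation beyond spheres.  Defaults: 20 layers of 256×256 px at
0.1 µm/px and 0.5 µm/layer, cell radius 105 px (~21 µm), background 12 /
cell 100 / rim +80 / focus amplitude 150 counts, 8 foci per channel of
1–3 µm diameter, coincidence fraction 0.5.  A fraction `c` of red foci
reuses a green focus's support exactly (true overlap 1); the rest are placed
with supports separated by ≥ `min_separation` (8 px in-plane, one layer in
z) from all other foci (true overlap 0) — planted scenes contain resolvable,
distinct organelles, so ground truth is unambiguous.  Foci are kept
≥ 30 px (plus their own radius) from the 2D cell edge: the pipeline
deliberately suppresses edge signal, and planting foci inside the attenuated
band would test the attenuation rule, not detection.  A 1-px Gaussian blur
stands in for the PSF (no optics-accurate model), then Poisson noise on the
signal plus Gaussian read noise (σ = 2).  Everything is deterministic per
seed.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: overlapping/touching organelles and fission
intermediates, depth-dependent attenuation and scattering, a realistic
anisotropic PSF, chromatic shift between channels, neighbouring cells in
the field, and motion during acquisition.

The FRAP generator produces the single-exponential recovery with known
mobile fraction and τ at the emulated acquisition cadence (300 frames at
0.2 s, 10 pre-bleach), multiplicative per-frame acquisition bleaching
applied to bleach and reference alike, additive background, and relative
Gaussian noise (default 2 %).

## Numerical choices and tie-breaks

* Otsu uses 256 histogram bins; ties in between-class variance resolve to
  the lowest bin (first argmax).
* Watershed floods the *negated* foreground; plateau/tie assignment follows
  the scikit-image implementation's deterministic ordering.
* Focus ids are assigned deterministically by first-slice position, so
  repeated runs produce byte-identical tables.
* Randomization offsets are drawn uniformly over positions where the
  focus's bounding box stays inside the image; mask membership and
  collisions are then tested voxel-exactly.
* Degenerate inputs: empty foreground → no seeds; a seed on zero foreground
  is dropped with a warning; constant channels → NaN Pearson with warning.

## Problem sizes used in validation

The validation suite runs on default 256×256×20 synthetic stacks (five
coincidence fractions for the monotonicity check), 50-replicate
randomization contracts on 48×48×6 masks, and a 4×3 grid of mobile
fractions × time constants with 20 simulated traces per cell — sizes chosen
so the whole suite completes in about a minute on a single core while still
exercising every stage at realistic scale.

## Known limitations

* Single cell per field: the largest projected object wins; no multi-cell
  support, no tracking over time-lapse movies.
* The relative LoG threshold guarantees detections in any cell with nonzero
  foreground; interpret counts jointly with the background rate.
* The vacuole rule cannot remove vacuoles covering more than half a
  cross-section, and vacuoles smaller than the structuring element survive.
* Ten randomization replicates give a background rate, not a p-value.
* The FRAP model ignores diffusion during bleach and reaction–diffusion
  kinetics; no diffusion coefficients are estimated.
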