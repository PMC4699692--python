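# Methods

This note documents the models and procedures implemented in `volseg`,
the parameter choices that matter, what the synthetic phantoms do and do
not emulate, and the numerical decisions taken where the design was open.

## Data model and geometry

A dataset is four congruent grids — image, selection, mask, model — over
one `VolumeGeometry` (voxel size `(dx, dy, dz)` in a named length unit,
plus the physical coordinate of the volume origin). Conventions:

* 0-based voxel indices, half-open ranges; the physical centre of voxel
  `i` along an axis is `bbox_min + (i + 0.5) * voxel_size`.
* Arrays are stored `(z, y, x[, c])`; geometry fields are semantic
  X, Y, Z order. All voxel-coordinate arguments in the API are `(z, y, x)`.
* Crop shifts `bbox_min`; resize rescales `voxel_size` so the physical
  extent is preserved (annotation layers are resampled nearest-neighbour
  only); rotate90/transpose permute voxel sizes and origin.
* Time-series data are treated as independent per-frame 3-D volumes; no
  joint 5-D segmentation is attempted.

**Undo** stores whole-slice (2-D scope) or whole-layer (3-D scope)
snapshots in bounded per-scope stacks — simplicity over memory, acceptable
in a headless setting. A consequence documented in the tests: undoing a
scope restores that snapshot verbatim, so a later edit of the *other*
scope on the same voxels is rolled back with it; true diff-based
interleaving was deliberately not implemented.

**Chop/reassemble** tiles the volume into near-equal blocks (optionally
expanded by an overlap margin, clipped at the border) with offset
geometry per block. On reassembly the later block in plan order wins in
overlap regions; material tables are reconciled by name. An unedited
round trip is bit-exact, which the suite asserts for several grids.

## I/O

Multipage TIFF carries the in-plane voxel size in resolution tags
(pixels per centimetre); Z spacing does not fit in baseline TIFF and is
restored from the bundle sidecar when present. NRRD (raw and gzip
encodings) carries `spacings`, `units` and `axis mins`; the reader and
writer are implemented in `volseg.imgio` and support exactly the 3-D
single-block dialect the writer emits (detached headers are rejected).
PNG series carry no physical metadata, so the bundle sidecar is mandatory
there. AmiraMesh export is the ASCII uniform-lattice dialect with a
material section, write-only. Binary layers are written 0/255; models are
8-bit (≤255 materials).

**Stitching** is translation-only: the shift is either taken from the
declared bounding boxes (plus a manual offset) or estimated by phase
cross-correlation of the two image volumes; voxel sizes must match
exactly — no implicit resampling — and the fixed dataset wins in
overlaps. Richer (rotational/elastic) alignment is out of scope.

## Filters

* **Normalisation** rescales each slice linearly so its mean/std (over the
  whole slice, or over masked voxels only) matches the dataset-wide
  statistics. The dataset-wide target (not the first slice) keeps the
  operation order-independent.
* **Anisotropic diffusion** is the explicit Perona–Malik scheme,
  exponential conductance by default, step size λ ≤ 0.25 (2-D stability
  bound), run per slice by default and in 3-D on request. `kappa` is in
  intensity units: gradients above it are treated as edges and preserved.
* **Morphology** uses disk (2-D, per slice) or ball (3-D) elements;
  bottom-hat = closing − image highlights dark detail smaller than the
  element.
* **Frangi vesselness** wraps the multiscale Hessian filter with
  α = β = 0.5 and c = half the maximum Hessian norm unless overridden,
  dark-structure polarity by default (EM staining). The
  `sequential-planes` mode computes 2-D vesselness in the XY planes and
  again in the ZX planes and combines by voxel-wise **maximum**: a tube of
  any orientation is line-like in at least one of the two plane families,
  while a sphere is blob-like in both, so the maximum accumulates tubular
  evidence without admitting blobs. A radius-r tube responds maximally
  near σ ≈ r/√2, which the suite checks on bar phantoms.
* **ROI restriction** runs the filter on a crop padded by the filter
  support and hard-replaces the voxels inside the ROI; no edge blending.
  Voxels outside the ROI are bit-identical to the input.

## Semiautomatic engines

**SLIC supervoxels.** Images are normalised to [0, 1]; compactness
defaults to 0.05 of that range; anisotropic grids cluster in physical
coordinates. Per-region statistics (mean, min, max, decile cuts) and a
face-adjacency graph are computed once and shared by the superpixel
brush, graph-cut and the supervoxel classifier. When connectivity
enforcement merges away more than half of the requested regions the
clustering is re-seeded proportionally, keeping the delivered region
count within a factor two of `volume / target_size`.

**Graph-cut.** N-link capacity `exp(−|μ_i − μ_j| / σ)` makes cuts cheap
across large intensity differences; σ defaults to 10 % of the
region-mean range. Seeded regions get terminal links with capacity
exceeding the total n-link weight, so they can never end on the wrong
side; a supervoxel seeded with both classes is a hard error. The min cut
is solved with an augmenting-path max-flow on the symmetric digraph and
the object side is taken as residual-graph reachability from the source
**with a float tolerance** — exact comparisons misread the ~1e−19
arithmetic residue on saturated edges as spare capacity (this produced
inconsistent partitions with both the preflow-push solver and the stock
partition extraction, hence the explicit implementation). Correctness is
pinned by a brute-force oracle: on ≤12-supervoxel instances the engine's
cut cost must equal exhaustive enumeration over all 2-colourings.

**Marker-controlled watershed** floods the image (or its spacing-aware
gradient magnitude) from the object/background scribbles; the oracle is a
textbook priority-flood implemented independently with a heap, compared
exactly on smoothed unique-valued reliefs, where flood order is
unambiguous.

**Object separation** computes the Euclidean distance transform of the
foreground — in physical units when `anisotropy_aware` — suppresses
maxima shallower than `min_depth` (default 2 physical units) and floods
the negated transform from the surviving maxima. Components that lose
every marker to the suppression keep one marker at their distance
maximum, so disconnected inputs are never merged or dropped. The
anisotropic acceptance case fuses spheres along the *coarse* axis: there
the voxel-space transform has no saddle at the neck and only the
physical-units transform separates the pair.

**Classifiers.** The membrane detector works per 2-D slice on a feature
stack of Gaussian-smoothed intensity, gradient magnitude and both Hessian
eigenvalues per scale, difference-of-Gaussians between consecutive
scales, and rotation-pooled ring context (mean/min/max of the intensity
sampled on two rings, 16 angles) — an orientation-invariant simplification
of published rotated-patch context features, recorded as such in the
feature schema id. The supervoxel classifier uses each region's intensity
statistics plus the mean of those statistics over its adjacent regions (a
neighbour-context block; an isolated region falls back to its own
values). Both are random forests (default 100 trees, unlimited depth)
trained on labelled voxels/regions only; a fixed seed makes the forest
and all predictions reproducible, and prediction refuses a feature stack
whose schema id differs from the training schema. Supervoxels seeded with
both classes are resolved by majority vote for classifier *training*
(soft constraint), in contrast to the graph-cut error (hard constraint).

## Manual tools

Points of note beyond the obvious definitions: the 3-D ball paints the
ellipsoid whose *physical* shape is a sphere of the requested radius;
brush strokes rasterize the polyline 8-connected and dilate to the brush
radius, so the footprint is gap-free for any click spacing; the membrane
tracker routes through a corridor around each click chord on a cost field
of smoothed intensity plus a 1e−4·distance-to-chord tie-break, so a
featureless field yields the discrete straight segment; the 3-D line
tracker interpolates anchors linearly in physical coordinates and places
one node per intersected slice. Shape interpolation blends per-object
signed distance fields with integer weights `(b−k, k−a)` — equivalent to
the usual `(1−t, t)` up to positive scaling but bit-symmetric under slice
reversal; objects are matched across key slices by centroid proximity and
unmatched objects are copied unchanged with a warning rather than faded
against an empty field. Thresholding is inclusive at both window ends.

## The 13-step mitotic-cell workflow

The built-in recipe segments six organelle classes from one grayscale
EM-style volume by peeling them off in contrast order, replacing each
segmented class with the median background intensity ("degrading" the
image) so the next, lower-contrast class becomes separable:

1. anisotropic diffusion;
2. per-slice bottom-hat (flattens large objects, keeps small dark detail);
3. dual-plane (XY + ZX) vesselness of the bottom-hat response → **ER**;
4. degrade ER;
5. global dark threshold;
6. 3-D opening **by reconstruction** and volume classification →
   **peroxisomes / lysosomes / lipid droplets**;
7. degrade the singular organelles;
8. threshold restricted to the user-supplied central-area mask
   (chromosome contrast is too close to mitochondria for a global
   threshold);
9. opening → **chromosomes**;
10. degrade chromosomes + second diffusion pass;
11. threshold + opening;
12. smoothing and small-object filtering → **mitochondria**;
13. assemble the final model (earlier classes keep conflicted voxels).

Two additions proved necessary in step 3 to keep the ER model from
swallowing the organelles later steps need: a strict blob-suppression
weight (β = 0.3; spheres are blob-like in both plane families and are
rejected by the dual-plane maximum, tubes survive) and exclusion of a
3-voxel neighbourhood of very dark cores (≤ 45 grey levels — singular
organelle interiors, well below the stained ER lumen). Step 6's geodesic
reconstruction lets the erosion kill specks and texture webs outright
while surviving organelles regain their full thresholded extent — a plain
opening truncates the smallest class (r ≈ 3 voxels) below usable size.

Every numeric step parameter is exposed in the recipe and is a
phantom-tuned default, *not* a canonical value; the workflow structure is
the canonical part. The central-area mask is user-supplied (brush +
shape interpolation in interactive use); the test path derives it from
phantom ground truth dilated by 3 voxels and the workflow raises a
descriptive error when it is missing.

## Phantoms: what they emulate, and what they do not

Phantoms are rendered as ideal label volumes mapped to class mean
intensities, softened by a 0.7-voxel Gaussian (partial-volume edges) and
corrupted with Gaussian noise, σ = 5 % of the dynamic range by default.
Ground truth is the pre-blur label volume. EM polarity (dark structures
on a bright background) is the default.

The mitotic phantom (144³ by default for the workflow benchmark — full
13 steps in ~15 s on one CPU; the generator accepts any shape) contains
an ER tube network (lumen 60), three size classes of very dark singular
organelles (lipid droplets r=8 / lysosomes r=5.5 / peroxisomes r=3.2,
means 25/30/35), a central irregular chromosome mass (mean 104) with dark
speckle texture, and mitochondria (mean 112). The speckle makes a global
dark threshold leak into the chromosome mass — reproducing the reason the
chromosome step needs a local mask. Class volumes are well separated so
the size classification in step 6 is clean; real data would need the
cutoffs re-tuned.

What passing these benchmarks does **not** show: robustness to the
structured noise, charging/curtaining artifacts, staining gradients and
anisotropic PSFs of real EM; performance when organelle size classes
overlap; or classifier generalisation across imaging sessions. The
phantoms isolate the algorithmic contracts (correct cuts, floods,
distances, bookkeeping), not instrument physics.

## Benchmark scenarios and their conditions

* *Graph-cut blob* (48³, one r≈10 blob, mean 200 on 50): 8 iterations of
  3-D diffusion before SLIC (target 16 voxels, compactness 0.1) — on the
  raw noisy volume supervoxel boundaries are too jagged for a Dice-0.95
  recovery; denoising before clustering is standard practice.
* *Nucleus watershed* (64×96×96): object and background scribbles on the
  single central slice; gradient relief.
* *Network classifier* (24×96×96 bright tube network): four fully
  annotated frames, light diffusion, fine per-slice superpixels
  (target 8, compactness 0.1, min-size factor 0.02). The partition itself
  caps attainable Dice near 0.92 on radius-2.2 tubes; the painting
  contract (output constant per superpixel) is the limiting factor, not
  the forest.
* *Membrane classifier* (5×96×96, ~2-px dark curves): two annotated
  slices; feature scales (0.7, 1, 2, 4) so the finest ridge filter
  resolves the membrane width.
* *Separation*: isotropic r=10/d=14 pair and anisotropic (2,2,10) nm
  r=20/d=28 pair fused along z.
* *Alignment*: 20 random shifts of a 2-D blob phantom at 5 % noise
  (contrast-to-noise ≈ 12), phase correlation, ±1 voxel tolerance.

## Known limitations

* NRRD support is deliberately minimal (own dialect + common readers'
  output); no detached headers, no non-axis-aligned space directions.
* The membrane tracker's corridor width and cost field are not calibrated
  against any published tracker — they are this package's choices.
* `separate_objects` assumes near-convex objects; elongated interdigitated
  shapes will oversplit at the default depth.
* Classifier features are intensity-based only; no texture filterbanks.
* Undo snapshots cost full-slice/full-layer memory per step.
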