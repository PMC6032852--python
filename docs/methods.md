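# Methods

## Problem setting

In-resin fluorescence (IRF) preserves fluorophore signal in
resin-embedded ultrathin sections (~100–200 nm), so a widefield
fluorescence image of a section can be taken before electron imaging of
the same section, with near-perfect alignment when both microscopes
share one stage. Detecting the fluorescent cells in the light image
makes it possible to restrict electron acquisition to regions of
interest. The detection problem is hard: sectioning leaves highly
variable per-cell intensity (dim cells, glancing cuts through cell
edges), and illumination adds a smooth bell-shaped background.

`irf_cellfinder` detects cells in such images as axis-aligned bounding
boxes — the unit that defines an electron-imaging field of view — and
evaluates detections against ground-truth boxes with a Dice-based
scheme. Because no annotated IRF data ship with the package, a
synthetic-section simulator reproduces the relevant image statistics
and provides exact ground truth.

## Detection pipeline

1. **Denoising (optional, off by default).** BM3D when the optional
   `bm3d` package is installed, given a user-supplied noise sigma
   (the method assumes a good noise-level estimate rather than
   estimating one). When BM3D is unavailable the stage falls back to
   mild Gaussian smoothing (sigma 2 px) and logs the substitution.
2. **Background leveling.** Rolling-ball subtraction: the background is
   the envelope of a ball of radius 50 px rolled under the intensity
   surface, i.e. grayscale opening with a ball structuring element.
   skimage's `rolling_ball` returns only the ball-apex surface (an
   erosion plus the radius); we complete the opening with a grayscale
   dilation by the same ball profile. The default radius (50 px ≈ 9 µm
   at 178 nm/px) exceeds the typical cell radius so cells are not
   flattened, while the illumination bell (spatial scale of order the
   image size) is tracked and removed.
3. **Contrast enhancement.** CLAHE with clip limit 0.01 on an 8×8 tile
   grid, after min–max rescaling to [0, 1]. This lifts dim cells into
   the working range of the feature detector. A constant image maps to
   zeros (zero dynamic range has nothing to equalize).
4. **LoG feature.** Negated, scale-normalized Laplacian of Gaussian at
   sigma = 7 px, so the bright rings/disks of sectioned cells give a
   high positive response at their intrinsic scale.
5. **Cell markers.** The pixels at or above the 0.92 empirical quantile
   of the feature (the 8% brightest); ties at the threshold are
   included.
6. **Background markers.** The ridge skeleton (medial axis) of the
   distance transform of the marker complement: a thin set of pixels
   maximally distant from all candidate cells. The medial axis is the
   same ridge set a watershed of the distance transform traces between
   marker blobs, but it remains defined when there is only one blob
   (a plain watershed of a single basin has no lines at all).
7. **Watershed.** Marker-controlled watershed of the feature's Sobel
   gradient magnitude (normalized so a unit ramp gives magnitude 1).
   Each connected cell-marker component seeds one basin; the whole
   background skeleton seeds a single background basin, which is
   discarded.
8. **Box postprocessing.** Basin bounding boxes are cleaned in three
   steps: (a) boxes larger than `max_area_px` (20 000 px) are dropped —
   an oversized box is a background basin, never a cell, and must go
   first or merging would let it absorb every detection it encloses
   (in a noise-free image the feature is exactly zero over the leveled
   background, the quantile threshold lands on that plateau, and the
   plateau becomes one near-image-sized basin); (b) boxes whose
   intersection-over-minimum-area is ≥ `merge_overlap` (0.5) are
   replaced by their union, iterated to a fixed point, repairing
   watershed oversegmentation of single cells; (c) boxes below
   `min_area_px` are dropped.

The pipeline is fully deterministic: identical inputs and configuration
give byte-identical outputs.

### Size-filter bounds

`min_area_px` defaults to 500 px and `max_area_px` to 20 000 px, which
at 178 nm/px correspond to cell cross-sections roughly 4–25 µm across.
The lower bound is matched to the modelled cell population (radius
6 ± 1.5 µm): the smallest plausible cross-section of such cells is a
few micrometres across, while noise-driven spurious watershed basins
measure a few hundred pixels. On synthetic sections, spurious basins
concentrated at 120–600 px whereas true cross-section boxes were
almost always ≥ ~550 px, so 500 px separates the two populations; the
cost is that glancing cuts with footprints below ~4 µm are lost, which
is the dominant contributor to the recall gap from 100%. Both bounds
are configuration-exposed and should be rescaled for other pixel sizes
or cell types.

## Evaluation scheme

Dice between two boxes is `2|A∩B| / (|A|+|B|)` on half-open integer
boxes (exact integer-area arithmetic). For a detection set and a
ground-truth set, the Dice matrix D_ij feeds two asymmetric averages:
the mean over rows of the row maximum (how good the found detections
are) and the mean over columns of the column maximum (how well the
ground truth is covered). Detections are matched to ground truth
one-to-one, greedily by descending Dice, accepting only pairs with
D strictly greater than the threshold (0.5 by default); matched pairs
are true positives, unmatched ground-truth objects false negatives,
unmatched detections false positives, giving recall = TP/(TP+FN) and
precision = TP/(TP+FP). Greedy matching can in principle differ from
optimal assignment; tests verify it recovers the optimal TP count on
hundreds of random scenes (scipy's Hungarian solver as oracle). Empty
sets yield rate 0 with a warning flag instead of an exception so batch
runs never abort.

The annotator agreement table applies the same machinery pairwise to
several ground-truth sets: entry (k, l) treats annotator k as
detections and annotator l as ground truth and reports the
ground-truth-side average; the table is generally asymmetric.

## Synthetic sections

The simulator models a resin block of spherical cells with cytoplasmic
staining:

| parameter | default | meaning |
|---|---|---|
| volume | 80 × 512 × 512 | slabs of 100 nm; pixels of 178 nm |
| n_cells | 15 | spheres per volume |
| radius | 6 ± 1.5 µm (Gaussian, > 0) | cell radius |
| nucleus_fraction | 0.6 | empty core radius / cell radius |
| brightness | 120 ± 30 (Gaussian, > 0) | cytoplasm intensity, 8-bit scale |
| A_bg | 80 | bell-background amplitude |
| bell scale | image diagonal / 4 | background spatial scale |
| noise sigma | 20 / 40 / 60 | additive Gaussian noise |

Cells are placed uniformly in the volume, rejection-sampled to be
non-overlapping. A section is the plane through the center of one
100 nm slab: a cell at axial distance d from the plane contributes its
brightness on pixels whose center lies inside the cross-section disk of
radius sqrt(R² − d²) and outside the nucleus cross-section — an annulus
through the equator, a small filled disk for a glancing cut.
Ground-truth boxes are tight boxes of each cell's rendered footprint,
computed strictly before background and noise are added. Geometry and
noise use separate seeded random streams, so one volume yields
identical ground truth across noise levels.

Defaults were calibrated once to scene statistics, not to scores: the
8 µm-deep volume with 15 cells gives 13–15 cells visible per 512²
section, matching the ~14 cells per section that expert annotators
find in real IRF images, and keeps the per-section cell coverage
stable (in deeper volumes the visible count fluctuates strongly, and
in sparse scenes the fixed 8% marker budget necessarily spills onto
background noise). The per-image brightness scale and the 8-bit
clipping match the sigma = 20–60 noise range.

What the simulator does **not** model: optical PSF blur, Poisson shot
noise, non-spherical or touching cells, nuclear/punctate fluorophore
patterns, intensity falloff within a cell, and section-to-section
correlation. Passing the synthetic experiment therefore demonstrates
noise robustness and correctness of the pipeline mechanics under the
modelled statistics, not performance on real IRF data, where reported
scores are much lower for both algorithms and human experts.

## Noise-robustness experiment

The standard experiment (`irf-cellfinder fig7`, also the acceptance
script) uses 5 replicate volumes (seeds base..base+4); for each, the
central section is rendered once and corrupted at sigma = 20, 40, 60;
detection runs with all defaults; TP/FP/FN are pooled per noise level.
Five 512² sections per noise level keep the full run within a few
minutes on one CPU while the pooled counts (~70 ground-truth objects
per noise level) make the rates stable to a few percent.

## Numerical choices and degenerate inputs

- Quantile thresholds use linear interpolation (`numpy.quantile`
  default) and `>=` comparison; ties are included.
- A constant feature image has no meaningful quantile: `cell_markers`
  raises, but `detect_cells` maps a constant/blank image to zero
  detections.
- Rolling-ball borders: only the in-image part of the ball window
  participates (infinite padding), so the background estimate never
  undershoots near edges.
- Box coordinates are 0-based half-open (row, col); ImageJ ROIs
  (x, y, width, height and polygon vertices) are converted on import,
  and freehand outlines are reduced to their tight bounding boxes,
  since evaluation is defined on boxes.
- Truncated-Gaussian draws resample until positive; radius_sd = 0
  degenerates to constant radii.
- The merge step preserves the label of the surviving (first) fragment.

## Known limitations

- The Gaussian fallback denoiser is far weaker than BM3D; with heavy
  noise it blurs noise into cell-scale blobs, so the default pipeline
  leaves denoising off and relies on the LoG scale selection instead.
- Recall is bounded by glancing cuts whose footprint falls under the
  size filter; recovering them would require linking detections across
  adjacent serial sections, which is out of scope here.
- Very dim cells (brightness near the noise level) can fragment into
  several disjoint arc boxes around their ring; when the fragments'
  boxes do not overlap, the box-level merge cannot reunite them and
  the cell costs one false negative plus several false positives.
  Distinguishing such fragments from genuinely adjacent cells would
  need image evidence, not box geometry, so the merge rule leaves
  them.
- The greedy matcher is order-dependent in exact-tie configurations
  (it resolves ties by scan order, deterministically).
- Real IRF data vary in pixel size; all pixel-denominated defaults
  (LoG sigma, ball radius, area bounds) assume 178 nm/px and must be
  rescaled otherwise.
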