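# Methods

`ivmhisto` implements an in vivo 3D histomorphometry workflow for
multi-channel two-photon z-stacks of the mouse calvaria: automatic 3D
cell counting by seed detection, bone and suture volumetry from manually
segmented fluorochrome-labelled bone fronts, and the derived
cellular-dynamics metrics, together with a synthetic-scene generator
that provides exact ground truth for every stage.

## Imaging model and coordinate conventions

A stack is a `(z, y, x)` array of 8- or 16-bit intensities with
physical voxel size `(dz, dy, dx)` in µm; z increases with depth from
the skull surface and slices are acquired at 1 µm intervals.  The
lateral pixel size defaults to 400/512 ≈ 0.781 µm/px (a 400 × 400 µm
field of view rastered at 512 × 512); it is metadata only — every
algorithm operates in pixel units, so results are insensitive to this
default.  Channels carry a spectral role: SHG (collagen/bone matrix),
EGFP (Prx1+ skeletal stem cells), tdTomato (their lineage-traced
progeny), calcein blue (old bone front, Day 0) and tetracycline (new
bone front, Day 28).  All quantification is 3D; maximum-intensity
projections are display-only and not implemented here.

## Automatic 3D cell counting

Counting reduces each cell to a *seed*, the 3D point at the centre of
its fluorescence peak.  The stages, in order:

1. **Crosstalk subtraction** (optional): `target − coefficient × source`,
   clamped at zero, for calcein-blue leakage into the green detector.
   The leakage coefficient is instrument-specific and defaults to 1.0
   (straight subtraction) when enabled; the synthetic generator embeds
   a known coefficient so correction is testable.
2. **Moment-preserving segmentation** of cell areas: the threshold is
   chosen so the binarized stack preserves the first three moments of
   the pooled 3D intensity histogram (Tsai's construction: the
   two-point distribution matching m1–m3 is solved in closed form, and
   the threshold is the gray level whose cumulative fraction is closest
   to the distribution's low-level mass).  One threshold per stack.
3. **Standardized contrast enhancement**: a monotone linear rescale
   clipping a fixed fraction of voxels (default 1.2 %, split evenly
   between the tails) at the dynamic-range extremes.  This standardizes
   per-stack gain without hand tuning and lifts dim stacks (raw maxima
   of 20–25 on the 8-bit scale) to full range.
4. **3D mean filter** with a 1-px kernel (27-voxel average), then
   **anisotropic local maxima** over a neighbourhood of half-widths
   `(kx, ky, kz) = (6, 8, 10)` px sized to the expected cell extent.
   The narrow x half-width is what separates closely apposed cells.
5. **Tukey-fence filtering**: local-maxima clusters are labelled with
   26-connectivity; a cluster is kept as a cell only if its peak in the
   smoothed enhanced image exceeds

   `T = Q3 + 1.5 (Q3 − Q1)`,  with  `Q1 = x ln(4/3)`, `Q3 = x ln 4`,

   i.e. `T = x (ln 4 + 1.5 ln 3) ≈ 3.034 x`, the Tukey outlier fence
   under an exponential model of the cell-surrounding intensity with
   mean `x`.  The surround is the euclidean dilation (default radius
   3 px) of the segmented cell areas minus the cell areas; its mean is
   computed over voxels passing a *step background gate*: the cutoff is
   the raw stack's modal (background) intensity plus an offset that
   steps with the stack's signal level (default `(64→2, 128→4, 255→8)`
   on the 8-bit scale), mapped onto the enhanced scale through the same
   affine transform as the image.  The gate keeps heavily enhanced dim
   stacks from flooding the surround statistics with amplified noise.
6. **Seed extraction**: the intensity-weighted centroid of each
   surviving cluster, at fractional voxel coordinates.

Two deliberate design choices, made because the alternatives measurably
failed on synthetic data:

* The cluster's representative intensity for the fence test is its peak
  in the **smoothed** enhanced image — the image in which the maxima
  were found — not the unsmoothed voxel value.  A single-voxel
  exponential-background outlier can exceed `T` while carrying no
  cell-scale structure; the 27-voxel average suppresses exactly that
  false-positive mode (~2–9 % overcount on dim stacks otherwise).
* The fence is applied un-anchored, `T = 3.034 x`, with `x` the gated
  surround mean.  An anchored variant `T = c + 3.034 (x − c)` (exact
  for a cutoff-truncated exponential) was evaluated and rejected: on
  dim stacks the moment mask absorbs the bright background tail, the
  gated shell is squeezed against the moment threshold, and the
  anchored fence drops below the smoothed-noise peaks.

### Operating regime and a known limitation

The saturated fraction standardizes gain for stacks whose cells occupy
at least that fraction of voxels; the defaults assume the density of a
typical imaged region (our synthetic regions carry 150–400 cells in a
50 × 256 × 256 stack, matching a few hundred cells per field).  On much
sparser scenes the clip quantile falls inside the background, the
enhancement factor explodes, and because the step-gate cutoff scales
with it, `T` can exceed the dynamic range and detection collapses to
zero.  The remedy is the same standardization at the scene's density: a
proportionally smaller `saturated_fraction` (e.g. 0.002 for a 50-cell
validation stack).  All detection knobs live in `DetectionParams` /
the YAML config.

## Bone and suture volumetry

Bone fronts are manual segmentations supplied as per-slice polylines in
a documented JSON schema (automatic front extraction is out of scope:
tetracycline staining is discontinuous and SHG is confounded by bright
suture collagen fibres).  Per slice, the new-bone area of each bone is
the area of the simple polygon bound between the old and new front
(closed through the frame edges), in px² scaled by `dy·dx`; crossing
fronts are rejected.  Areas are summed over a standardized 50-slice
(50 µm) depth, multiplied by `dz`, and converted to mm³ (the µm³→mm³
factor of 1e−9 lives in exactly one function).  Suture volume uses the
closed suture-boundary outline per slice.  Volumes are additive over
z-blocks and exact for polygonal fronts, so generator prisms/wedges are
recovered to well under 1 %.

Osteocyte classification counts seeds inside the new-bone polygon of
their nearest slice, **boundary-inclusive** with a 0.5 px tolerance —
cells sitting right on the labelled front lines count, per the
inclusion rule of the underlying protocol — minus any seed inside an
optional exclusion mask (vessel walls, marrow cavities, old bone).

Derived metrics for a region: cell density = osteocytes / new-bone
volume (count/mm³); normalized incorporation = osteocytes as % of the
Day-0 cell count; and the fractional change
`ΔM = (M_D28 − M_D0)/M_D0 × 100` used for population expansion and
suture-volume change, which normalizes away baseline variability
between regions and animals.

## Statistics

Group comparisons use the two-tailed pooled-variance (equal-variance)
Student's t-test with `df = n_a + n_b − 2`, implemented in closed form
and cross-checked against an independent reference implementation to
1e−10; significance stars at p < 0.05 / 0.01 / 0.005 / 0.0005.
Counting accuracy is the absolute relative count error per region,
pooled as mean ± SD (sample SD).  Seed localization error is the mean
per-axis absolute deviation over greedy nearest-first matches within a
5 px radius.  Box-plot summaries use linear-interpolation quartiles
(deterministic across n; Q1 of 1…9 is 3) with points beyond 1.5 × IQR
flagged.  Regions are pooled across animals without hierarchical
modelling, mirroring the analysis this package reproduces.

## Synthetic scenes

`generate_cell_stack` renders cells as anisotropic Gaussian blobs
(lateral σ uniform in 1.6–2.6 px, axial σ = 0.75 σ_lat) at
jittered-grid centres — grid spacing (14, 14, 12) px in (z, y, x) with
±1.5 px jitter guarantees that any two cells are separated beyond the
local-max kernel in at least one axis, so ground-truth counts are
unambiguous.  Peak amplitudes are 20–25 (EGFP-like, the dim regime) or
120–240 (tdTomato-like) on the 8-bit scale; the background is
exponential noise (mean 2.0 dim / 4.0 bright), chosen so the fence's
exponential surround model holds exactly (a Gaussian background option
probes robustness).  Scenes are deterministic given `rng_seed` and
carry exact centroids, counts, analytic front geometries and
closed-form volumes.

What the generator does **not** emulate — hence what passing tests do
not show about real data: optical PSF structure beyond Gaussian blobs,
depth-dependent attenuation and scattering, cell-shape irregularity,
touching/overlapping cells, vessel walls and marrow cavities, or
motion/registration error between imaging sessions (stacks are assumed
pre-aligned by the restrainer-based repositioning of the acquisition
protocol).

`generate_bone_geometry` builds straight or linearly varying (wedge)
fronts with closed-form volumes.  `generate_paired_study` produces
paired Day-0/Day-28 regions realizing requested effects — bone growth,
population expansion, osteocyte incorporation, all in % with
region-level gaussian noise — in the ground truth; by default scenes
are unrendered (geometry + truth only), which keeps whole-study
simulations to milliseconds; `render=True` adds voxel data.

## Problem sizes used in the shipped checks

Counting validation uses 28 regions per channel profile at the default
(50, 256, 256) shape with 150–400 cells each; localization uses one
50-cell stack; the power demonstration uses 40 regions/group, 10 %
region noise and 200 replicates of a 41 % vs 0 % bone-growth contrast.
These desk-scale sizes keep the full suite within a few minutes on one
CPU core while matching the per-region densities described above.

## Numerical choices

* Histogram mode ties break toward the lower intensity; moment
  threshold ties toward the lower gray level.
* Filters are edge-clamped (`mode="nearest"`); the mean filter returns
  float32 so plateaus are not created by re-quantization.
* Local-maxima plateaus (e.g. from clipped cell cores) are marked whole
  and merged by 26-connectivity; centroids are intensity-weighted.
* 16-bit stacks are histogrammed at native resolution; thresholds are
  returned on the native scale.
* Degenerate inputs: constant stacks yield a warning (contrast), an
  error (moment threshold), or an empty seed set (detection); an
  all-background scene with zero detections is a valid result.
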