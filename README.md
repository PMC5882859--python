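# ivmhisto

**In vivo 3D histomorphometry for intravital two-photon microscopy.**

Classical bone histomorphometry measures bone structure and cellular
composition on thin post-mortem sections, losing the third dimension
and the time axis.  Intravital two-photon microscopy (IVM) of the mouse
calvaria images the same animal repeatedly in 3D: collagen/bone matrix
by second-harmonic generation, skeletal stem cells and their progeny by
genetically encoded fluorophores (EGFP, tdTomato lineage tracing), and
the old/new bone mineralization fronts by calcein-blue/tetracycline
double labelling.  `ivmhisto` turns such multi-channel z-stacks into
quantitative histomorphometry for researchers studying calvarial bone
formation and skeletal-progenitor dynamics:

* **automatic 3D cell counting** — every cell is reduced to a "seed"
  (the 3D centre of its fluorescence peak) by moment-preserving
  segmentation, standardized contrast enhancement, a 3D mean filter,
  anisotropic local-maximum detection, and an outlier threshold based
  on Tukey's fence, `T = Q3 + 1.5 (Q3 − Q1)`, with quartiles from an
  exponential model of the cell-surrounding background
  (`Q1 = x ln 4/3`, `Q3 = x ln 4`, so `T ≈ 3.034 x`);
* **3D bone and suture volumetry** — per-slice areas bound between the
  manually segmented old and new bone fronts, summed over a 50 µm
  layer and reported in mm³;
* **cellular dynamics** — osteocytes incorporated into new bone
  (boundary-inclusive point-in-polygon classification), cell density
  per mm³ of new bone, and the Day-0-normalized fractional change
  `ΔM = (M_D28 − M_D0)/M_D0 × 100`;
* **validation statistics** — counting accuracy vs ground truth,
  per-axis seed-localization error, pooled-variance two-tailed t-tests
  and box-plot summaries;
* a **synthetic-scene generator** with exact ground truth (centroids,
  counts, closed-form bone volumes), so the entire pipeline is testable
  without microscope data.

See `docs/methods.md` for the model, parameters and limitations.

## Worked example

Simulate a bright (tdTomato-like) region with 200 cells, count them,
validate against the generator's ground truth, and measure volumes:

```bash
ivmhisto simulate --preset tdtomato --seed 7 --n-cells 200 --out scene/
ivmhisto count --stack scene/stack.tif --channel tdtomato --out seeds.csv
ivmhisto validate --seeds seeds.csv --truth scene/truth.csv --out accuracy.json
ivmhisto morpho --geometry scene/geometry.json --seeds seeds.csv --out report.json
```

`accuracy.json`:

```json
{
  "auto_count": 200,
  "truth_count": 200,
  "counting_error_pct": 0.0,
  "centroid_deviation_px": {"z": 0.122, "y": 0.123, "x": 0.134},
  "n_matched": 200,
  "n_unmatched_seeds": 0,
  "n_unmatched_truth": 0
}
```

All 200 cells were found (0 % counting error) and each seed lies within
~0.13 px of the true cell centre on every axis.  `report.json`:

```json
{
  "new_bone_frontal_mm3": 7.8125e-05,
  "new_bone_parietal_mm3": 7.8125e-05,
  "new_bone_total_mm3": 0.00015625,
  "suture_volume_mm3": 0.0008359375,
  "n_slices": 50,
  "depth_um": 50.0,
  "osteocytes_in_new_bone": 22,
  "cell_density_per_mm3": 140800.0
}
```

The synthetic geometry is a 10-px prism of new bone on each side of the
suture over a 50 µm layer: 1.56e−4 mm³ of new bone in total, with 22 of
the 200 seeds falling inside it, i.e. 1.41e5 osteocytes/mm³.  (These
match the generator's analytic volumes in `scene/analytic_volumes.json`
exactly.)

Library use mirrors the CLI: `generate_cell_stack`, `detect_seeds`,
`measure_volumes`, `classify_osteocytes`, `fractional_change`,
`ttest_equal_var`, etc. are importable from `ivmhisto`.  An end-to-end
pipeline over many regions (counts at both timepoints, volumes,
fractional changes, manifest) runs via `ivmhisto run --config run.yaml`.

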