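# adiposcope

Quantitative histology and physiology pipelines for aging/adipose
innervation studies:

- **collagen_psr** — picrosirius-red collagen scoring from paired
  bright-field/polarized fields: total-collagen ratio (birefringent area /
  total stain area) and hue-binned thin vs thick fiber fractions
  (green 52–128 and yellow 39–51 = thin; orange 10–38 and red 0–9 ∪ 230–255
  = thick; brightness gated at 35–255 on the 0–255 hue scale).
- **neurovascular** — whole-depot nerve/vessel relative densities from tiled
  Z-max-projected mosaics, engineered channel masks from high-magnification
  stacks (Gaussian background subtraction σ=80, unsharp radius 1 / weight
  0.60 on the vessel channel, interval thresholds, dilation + hole filling +
  median cleanup), Mander's overlap coefficients, and point-annotation
  tallies.
- **ienf** — intraepidermal nerve-fiber density with per-image intermodes
  auto-thresholding against skin autofluorescence.
- **morphometry_nmj** — NMJ occupancy / terminal-Schwann-cell summaries from
  annotation CSVs, plus adipocyte area/perimeter from label masks.
- **physiology** — von Frey response curves with trapezoidal AUC, myography
  normalization (percent of KCl max / percent of pre-contraction), and 4PL
  EC50 fitting.
- **imaging_core** — shared raster types, RGB→HSB conversion, Z-projection,
  mosaic tiling, block-mean binning, polygon-ROI rasterization, interval
  thresholds, and the intermodes histogram threshold.
- **synthetic_data** — seeded generators for every input above, with exact
  machine-readable ground truth, so all pipelines are testable without any
  raw microscopy data.
- **reporting / cli** — run provenance, long-format result tables with
  hierarchical (field → tissue → animal → group) averaging, and the
  `adiposcope` command-line interface.

## CLI

```sh
# make a synthetic scene, then analyze it
adiposcope simulate ienf --seed 3 --out scene/
adiposcope ienf --image scene/section.tif --roi scene/epidermis.csv

adiposcope simulate psr --seed 1 --out scene/
adiposcope psr --brightfield scene/brightfield.tif --polarized scene/polarized.tif

adiposcope simulate depot --seed 2 --out scene/
adiposcope overlap --nerve-stack scene/nerve_stack.tif --vessel-stack scene/vessel_stack.tif
adiposcope depot --nerve mosaic_th.tif --vessel mosaic_ib4.tif --roi tissue.csv

adiposcope vonfrey --trials trials.csv
adiposcope myograph --trace trace.csv --mode contraction --reference 20.0
adiposcope nmj --annotations nmj.csv
```

Every command emits JSON (stdout or `--out`) with embedded provenance
(package version, config hash, seed).

## Conventions

- All intensities on the 8-bit-equivalent [0, 255] float scale (16-bit
  TIFFs divided by 257 on load); hue on a 0–255 wraparound scale.
- Pixel coordinates 0-based row/col; polygons implicitly closed, even–odd
  fill; threshold intervals inclusive at both ends.
- Deliverable formats are plain text or TIFF: masks as 8-bit 0/255 TIFFs,
  ROIs as CSV/JSON vertex lists, tables as CSV.
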