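# irf-cellfinder

Automated detection of fluorescent cells in widefield fluorescence
images of ultrathin **in-resin fluorescence (IRF)** sections, for
integrated light and electron microscopy workflows.

In integrated array tomography, serial ultrathin sections (~100–200 nm)
of resin-embedded cells are imaged first by fluorescence and then by
electron microscopy in the same instrument. The fluorescence image can
drive "smart tracking": electron images are acquired only where
fluorescent cells are, cutting acquisition time and data volume.
Detecting those cells automatically is hard — sectioning leaves dim
cells, ring-shaped cross-sections and glancing cuts, on top of a
bell-shaped illumination background. This package provides:

- a **marker-controlled watershed detector**: optional denoising,
  rolling-ball background subtraction, CLAHE, a scale-normalized
  Laplacian-of-Gaussian (LoG, σ = 7 px) feature, cell markers from the
  92% feature quantile, background markers from the distance-transform
  ridge skeleton, watershed of the feature gradient, and bounding-box
  merging/size filtering;
- a **bounding-box Dice evaluation** scheme: for detections *i* and
  ground-truth objects *j*, the Dice matrix
  *D*<sub>ij</sub> = 2|A<sub>i</sub>∩B<sub>j</sub>| / (|A<sub>i</sub>|+|B<sub>j</sub>|),
  the two asymmetric averages D̄<sub>det</sub> (row maxima) and
  D̄<sub>GT</sub> (column maxima), and recall r = TP/(TP+FN),
  precision p = TP/(TP+FP) after one-to-one matching at *D* > 0.5;
- a **synthetic section simulator**: spherical cells with Gaussian
  size/brightness, cytoplasmic staining with an empty nucleus,
  100 nm slicing at 178 nm/px, bell background of amplitude
  A<sub>bg</sub> = 80 and Gaussian noise σ ∈ {20, 40, 60}, with exact
  per-object ground-truth boxes computed before noise;
- readers/writers for TIFF images, ImageJ `.roi`/`.zip` ROI sets
  (reduced to tight bounding boxes on import) and CSV/JSON box tables,
  plus a CLI tying everything together.

See `docs/methods.md` for the model details and design choices.

## Worked example

Simulate sections, detect cells, and evaluate at the three noise
levels (seeded, reproducible):

```sh
irf-cellfinder fig7 --seed 0 --out results/fig7
```

which prints one row per noise level (counts pooled over 5 replicate
volumes, one 512² central section each):

```
 sigma  tp  fp  fn  n_gt  n_det  recall  precision  mean_dice_det  mean_dice_gt
20.000  69   0   5    74     69   0.932      1.000          0.977         0.911
40.000  68   0   6    74     68   0.919      1.000          0.978         0.899
60.000  69   2   5    74     71   0.932      0.972          0.958         0.911
```

Reading the σ = 60 row: of 74 simulated cells visible in the sections,
69 were detected with bounding-box Dice above 0.5 (recall 93%), and 69
of the 71 reported detections were correct (precision 97%). The misses
are glancing cuts and very dim cells — cross-sections that fall below
the detector's minimum plausible cell size or fragment in heavy noise.
Mean Dice ≈ 0.90–0.98 says the matched boxes overlap their ground
truth well. Detection quality degrades only mildly as the noise level
triples, which is the point of the experiment: the LoG-plus-watershed
pipeline is robust against noise.

Other entry points:

```sh
irf-cellfinder simulate --out data/ --seed 3 --sigmas 20,40,60
irf-cellfinder detect data/sigma_20/section_z0040.tif --out boxes.csv
irf-cellfinder eval --det boxes.csv --gt data/sigma_20/gt_z0040.csv --out report.json
irf-cellfinder agreement --gt expert1.zip --gt expert2.zip --out table.csv
```

or from Python:

```python
from irf_cellfinder import (DetectConfig, PreprocessConfig, SimConfig,
                            detect_cells, match_and_score, read_image)

dets = detect_cells(read_image("section.tif"), PreprocessConfig(), DetectConfig())
```

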