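# barrettometry

Automated measurement of Barrett's esophagus from endoscopic depth maps:
Prague C&M scores, island diameters and the Barrett's epithelium area (BEA),
together with a digital esophagus phantom simulator that provides exact
geometric ground truth for validating the whole pipeline without patient data.

## Who this is for

Barrett's esophagus (BE) is a precancerous replacement of esophageal squamous
epithelium by columnar epithelium extending above the gastric folds.  Its
extent is reported with the Prague classification — the circumferential
extent **C** and maximal extent **M**, in cm from the top of the gastric
folds — which is subjective and operator dependent, and it ignores islands
and the actual mucosal *area*.  Given a per-pixel depth map (mm from the
camera, as produced by a monocular depth estimator or here by an exact
simulator) plus segmentation masks of the Barrett's epithelium and the
gastroesophageal junction, this package computes those quantities objectively
in real-world units, and reconstructs the esophageal surface in 3D.  It is a
research tool for groups developing or validating quantitative endoscopy.

## The measurement principle

A pixel `(u, v)` with depth `d` back-projects through the pinhole model to
`((u−u0)·d/f, (v−v0)·d/f, d)` mm.  All pixels of the main Barrett's segment
are fitted with a convex hull; from the center of the gastric junction the
geodesic distance *along the imaged surface* (summed 3D steps under the
rasterized pixel line) is measured to every hull vertex:

* **C** = the smallest such distance — the extent of the circumferential
  Barrett's collar;
* **M** = the largest — the tip of the longest tongue;
* island diameters = maximal surface geodesic between island hull vertices,
  with paths constrained to the island's own surface;
* **A_b** = the 3D surface area integrated over every pixel enclosed by the
  hull, **A_fold** = the gastric-fold area, and
  **BEA = A_b − A_fold** when A_fold > 1 cm² (else A_b), islands reported
  separately.

The simulator renders a tubular esophagus phantom (18.75 cm × 2 cm internal
diameter) with painted Barrett's bands, tongues and islands by analytic
ray casting — depth maps are exact, so measurement error is purely geometric.

## Worked example

Measure the five length markers of a phantom painted with a 23.4 mm
circumferential collar, tongues reaching 70.0 and 65.7 mm, and islands of
diameter 20.3 and 14.3 mm, from five rendered frames:

```python
from barrettometry.experiments import run_length_experiment

res = run_length_experiment(seed=1)
print(res.summary())
```

```
marker              ground truth   automated  abs diff  rel err %
Ma                         70.00       70.39      0.39       0.56
Mb                         65.70       65.96      0.26       0.39
C                          23.40       22.98      0.42       1.80
Island 1                   20.30       20.51      0.21       1.05
Island 2                   14.30       14.51      0.21       1.49
overall                                           0.30       1.06
```

Each row compares the configured marker length with the mean of five
automated measurements: the collar is recovered to 0.4 mm, the tongues to
within 0.4 mm of their 65–70 mm extents, and the overall mean relative error
is about 1% — sub-millimeter accuracy from single 256×256 frames.  RMSE over
the five differences is 0.31 mm with perfect rank agreement
(Spearman r = 1.0).

### Command line

```bash
barrettometry simulate config.yaml out/dataset     # render RGB+depth+masks
barrettometry measure out/dataset out/meas.csv     # per-frame C/M/BEA
barrettometry evaluate out/meas.csv out/dataset/manifest.json out/report.csv
barrettometry reconstruct out/dataset out/fused.ply
```

`simulate` writes PNG images, 32-bit float TIFF depth maps (mm), mask PNGs
and a JSON manifest with poses and analytic ground truth; everything is
reproducible from the config's seed.

## Limitations

The simulator uses a straight constant-radius tube, flat paint colors and a
pinhole camera without lens distortion; real endoscopes are wide-angle with
fisheye distortion, and real mucosa adds texture, specularities and
deformation.  With ground-truth depth the results bound only the geometric
measurement error, not the error a learned depth estimator would add.  See
`docs/methods.md` for the model, parameter choices and numerical details.
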