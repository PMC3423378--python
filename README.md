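# fibrinet

Quantitative image analysis of fibrin clot microstructure from fluorescence
(multiphoton/confocal) images.

Fibrin networks — the structural mesh of blood clots — are characterized by
a handful of architectural parameters: fiber density, fiber diameter, the
balance of thin vs thick fibers, branch-point and crossing-fiber rates, and
the void (pore) fraction. Small molecules that perturb fibrin polymerization
shift these parameters and, at high perturbation, produce abnormal phenotypes
(dense "fibrin clusters" with thin radiating fibers, and isolated micron-scale
fibrin agglomerates when network formation fails entirely). `fibrinet`
implements the full measurement chain for 2D images and small z-stacks, plus a
synthetic network generator with complete ground truth so every operator is
testable without real microscope data.

## The measurements

* **Test-line fiber detection.** Equally spaced horizontal test lines (5 for a
  1024-row image, rows ≈ 171/341/512/682/853) sample the randomly oriented
  network; each peak of a line's intensity profile (local maximum of the
  smoothed profile above a 27 au cut) is one fiber crossing. Fiber density is
  *n*/100 µm of test line. A batch edit list (confirm/reject/add) audits the
  automatic pass and yields its positive predictive value,
  PPV(%) = 100·TP/(TP+FP).
* **Diameter.** Each fiber is measured at its local intensity maximum; the
  diameter is the full width at half maximum (FWHM) of the intensity profile
  perpendicular to the local fiber axis (structure-tensor orientation), with
  sub-pixel interpolation.
* **Thin/thick statistics.** Diameter samples are normality-tested
  (Shapiro–Wilk) and fitted by maximum likelihood to a normal or a
  two-component Gaussian mixture (EM); for bimodal samples the interior
  minimum of the fitted density splits thin from thick fibers (default
  threshold 761.9 nm), giving the thin-to-thick ratio TTR = n_thin/n_thick.
* **Topology.** A three-fiber meeting is a trifunctional branch junction when
  the widest width equals the sum of the other two (F1 = F2 + F3, within 15%).
  A two-fiber meeting is a physical contact when *both* fibers show a
  proportional intensity increase > 40% at the meeting point (fluorophore
  additivity); otherwise one fiber passes above or below the other.
* **Voids and structures.** Binarized images (fiber ≥ 27 au) give the void
  area per slice, the projected void of an OR-combined 3-slice stack, and the
  void volume (mean of slice void fractions). Cluster detection finds
  irregular high-intensity cores with > 8 thin radial protrusions; agglomerate
  morphometry (component long axis, 0.5–8 µm scale) engages automatically when
  no network spans the field.

## Worked example

```python
from fibrinet import synth, report

img, truth = synth.render_scene(synth.SceneSpec(seed=11, n_branches=5, n_crossings=6))
readout = report.analyze_image(img, label="control")
print(readout.to_json(indent=2))
```

prints (abridged):

```json
{
  "label": "control",
  "n_fibers": 89,
  "fiber_density_per_100um": 30.18,
  "fiber_intensity_au": 86.16,
  "diameter_nm": 646.62,
  "diameter_fit_kind": "bimodal",
  "void_area_percent": 65.85,
  "clusters_per_mm2": 0.0,
  "agglomerates_per_mm2": 0.0
}
```

The 89 detected fibers equal the generator's true fiber–test-line crossing
count for this seed; the density (30.2 fibers/100 µm) and void area (65.9%,
vs 65.9% true rendered footprint) are in the range typical of control plasma
clots; the diameter summary (647 nm median) sits near the generated 670 nm
mean. `synth.render_dose_series` produces a 7-dose virtual series whose
density falls monotonically, diameter peaks at an interior dose, clusters
appear before agglomerates, and the final dose contains agglomerates only.

The same operations are available from a CLI:

```bash
fibrinet synth --out scene.tif --truth truth.json --seed 11
fibrinet detect --image scene.tif --pixel-size-nm 57.6 --out fibers.csv
fibrinet measure --image scene.tif --fibers fibers.csv --out metrics.csv
fibrinet report --image scene.tif --out readout.json
```

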