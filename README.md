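# cartinirs

Combined optical coherence tomography (OCT) lesion scoring and near
infrared spectroscopy (NIRS) chemometrics for articular cartilage.

Arthroscopic grading of cartilage lesions is subjective and poorly
reproducible. Two quantitative probes complement each other: OCT images a
cross-section of the tissue at micrometre resolution, and NIRS measures
absorbance at 700–1100 nm, where CH/NH/OH overtone vibrations carry
information about collagen, proteoglycans (PG) and water. `cartinirs`
implements the full analysis chain used in equine-cartilage research of
this kind, plus a ground-truthed synthetic-data generator so every stage
is testable without access to study data:

* **`oct_scoring`** — automatic ICRS (International Cartilage Research
  Society) grading of OCT B-scans: the 0.9 mm imaging catheter is detected
  and used as the scaling factor, a 2 mm region of interest matching the
  NIRS probe is selected, the articular surface and the non-calcified /
  calcified cartilage interface are segmented with adaptive smoothing, and
  the OCT roughness index (ORI, the RMS deviation of the surface from its
  least-squares line), thickness loss and bone exposure are thresholded
  into grades 0–4 (ORI > 8 µm → 1, loss > 8 % → 2, defect > 50 % of
  thickness → 3, bone exposed → 4).
* **`spectral_preprocessing`** — repetition averaging, Savitzky–Golay
  smoothing (order 3, window 39 ≈ 25 nm) and 1st/2nd derivatives, SNV and
  MSC scatter correction, band restriction to 700–1100 nm.
* **`reference_analysis`** — zonal reference targets from depth-wise
  microscopy profiles: the superficial/deep boundary is the minimum of the
  birefringence profile; collagen orientation, collagen content (FTIR
  amide I, 1584–1720 cm⁻¹), PG content (FTIR carbohydrate band,
  984–1140 cm⁻¹) and PG optical density are averaged per zone.
* **`ann_regression`** — filter-based forward input-variable selection
  (up to 200 wavelengths) and one-hidden-layer tanh/linear networks
  (≤ 10 neurons) trained by Levenberg–Marquardt with validation-based
  early stopping; model selection over hidden sizes × weight restarts by
  test-group RMSE.
* **`evaluation`** — generalized (all samples) versus condition-specific
  (per ICRS grade) protocols, with RMSE, NRMSE (RMSE ÷ reference range, in
  %), two-tailed Pearson correlation and Kruskal–Wallis statistics.
* **`synthetic_data`** — the phantom generator: grade-dependent lesion
  geometry and composition, depth profiles, three-repetition spectra with
  ≈ 0.8 % repetition variability, and speckled B-scans with sub-pixel
  ground-truth segmentation lines.

## Worked example

```python
import numpy as np
from cartinirs import synthetic_data as sd, oct_scoring as oct

rng = np.random.default_rng(7)
truth = sd.sample_composition(grade=2, rng=rng)   # degraded cartilage
lesion = sd.sample_lesion(grade=2, rng=rng)
bscan, gt = sd.make_bscan(lesion, truth, rng)
score = oct.score_bscan(bscan)
print(f"ORI {score.ori:.1f} um, loss {score.loss_fraction:.2f}, "
      f"ICRS {score.grade}")
```

prints

```
ORI 42.2 um, loss 0.18, ICRS 2
```

i.e. the detected surface roughness (42.2 µm RMS) is far above the 8 µm
healthy threshold and 18 % of the local cartilage thickness is missing, so
the decision tree assigns ICRS grade 2 — matching the grade the phantom
was generated with.

The modelling half, end to end on a 530-point synthetic cohort:

```python
from cartinirs import evaluation as ev
dataset = sd.generate_dataset(sd.PhantomSpec(n_points=530, seed=11))
cfg = ev.EvalConfig(max_vars=40, hidden_sizes=(2, 4, 6), restarts=3,
                    max_epochs=150, seed=11)
report = ev.run_generalized(dataset, cfg)
print(report.table[["target", "nrmse_pct", "r"]].head(2).to_string(index=False))
print(f"average NRMSE {report.average_nrmse:.2f}%")
```

```
                 target  nrmse_pct        r
superficial_orientation   1.783367 0.995630
       deep_orientation   3.130129 0.988155
average NRMSE 1.59%
```

Every zonal composition target is recovered from the spectra with test
correlations near 1 at the generator's (low) noise level; on real tissue
the errors are an order of magnitude larger, which is why the tests check
properties and orderings rather than absolute errors.

A CLI mirrors the library: `cartinirs simulate`, `score-oct`,
`preprocess`, `reference`, `train`, `evaluate` (see `--help`).

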