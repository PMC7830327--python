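# ramanmcr

Chemometric analysis of single-cell Raman microspectroscopy for
discriminating cancerous from normal epithelial cells — and, more
importantly, for explaining *why* they separate, by resolving the
measured spectra into pure biomolecular components and tracing the
discrimination back to a specific lipid species.

## The problem and the method

Single-cell Raman spectra are sums of overlapping vibrational band
systems (proteins, nucleic acids, lipids) riding on a broad
autofluorescence background.  Black-box classifiers (PCA-LDA, SVM)
separate cell groups well but say nothing about chemistry.  This package
implements the full analysis chain:

1. **Preprocessing** — dark-count subtraction, cosmic-ray spike removal
   (dual criterion: cross-spectrum robust z-score and local
   second-difference anomaly), SVD denoising, cropping to the
   fingerprint region 739–1800 cm⁻¹, and per-cell averaging of the five
   point spectra acquired per cell.
2. **Discrimination** — NIPALS-PCA on mean-centered per-cell spectra,
   two-class LDA on the first 4 PC scores with equal priors, and a
   linear ν-SVM with stratified 10-fold cross-validation; metrics
   (accuracy / sensitivity / specificity) from the 2×2 confusion matrix.
3. **Penalized non-negative MCR-ALS** (the core).  The hyperspectral
   matrix *A* (m wavenumbers × n spectra) is factorized as *A ≈ WH* with
   *W ≥ 0* (pure spectra) and *H ≥ 0* (abundances) by alternating
   regularized normal-equation solves

   (WᵀW + α²E) H = WᵀA,  (HHᵀ + β²I) W = HAᵀ,

   with *E* the all-ones matrix (an L1-type sparsity coupling,
   α² = 0.005), *I* the identity (ridge, β² = 0.005), k = 7 components,
   SVD initialization, projection of negatives to zero, and unit-norm
   *W* columns.
4. **Chemical interpretation** — rule-based annotation of the resolved
   components from their band patterns (autofluorescence, nucleic
   acid + protein, protein, lipids ranked by the 1745 cm⁻¹ ester band),
   relative-abundance marker statistics between groups (Welch t-tests),
   and an unsaturation-index calibration: the C=C/CH₂ band-area ratio
   I(1658)/I(1445) is linear in the number of C=C double bonds (NDB),
   so a resolved lipid can be assigned an unsaturation index, and the
   ester band separates glycerides from free fatty acids.

Because no real spectra are distributed, the package includes a
first-class synthetic-data generator (`ramanmcr.synth`) with full ground
truth: seven pure components built from the fingerprint band library,
two cell groups differing only by planted abundance effects (the
ester-bearing di-unsaturated lipid ×0.4 and the nucleic-acid+protein
component ×1.3 in the cancer-like group), organelle-scale point-to-point
abundance jitter, detector noise, and cosmic-ray spikes at recorded
coordinates.

## Worked example

```python
import numpy as np
import ramanmcr as rm

sim = rm.simulate_cells(rm.GeneratorConfig(seed=7))
points, info = rm.preprocess_dataset(sim.dataset, average=False)
cells = rm.average_per_cell(points)

pca = rm.nipals_pca(cells, 7)
model = rm.lda_fit(pca.scores[:, :4], cells.groups())
_, cm = rm.lda_predict(model, pca.scores[:, :4], actual=cells.groups())
print(rm.confusion_metrics(cm, positive_class="MCF7-like").display)

res = rm.fit_mcr_als(points, rm.MCRConfig())          # k=7, penalized
ann = rm.annotate_components(res.W, points.axis)
Hc, _ = rm.abundance_per_cell(res.H, points.columns["cell_id"])
rep = rm.marker_ratio_report(Hc, ann, cells.groups())
e = rep["ratios"]["Lipid 1/N+P"]

stds = [(s.name, s.spectrum, s.ndb)
        for s in rm.simulate_standards() if s.name != "TLA"]
cal = rm.fit_unsaturation_calibration(stds)
lip1 = next(a for a in ann if a.label == "Lipid 1")
pred = rm.predict_double_bonds(cal, (points.axis, res.W[:, lip1.index]))
```

prints (seed 7):

```
spikes removed: 17, matrix (1062, 300) -> (1062, 60) per-cell
LDA confusion: [[26, 2], [4, 28]] accuracy/sens/spec: {'accuracy': 90, 'sensitivity': 93, 'specificity': 86}
components: ['Lipid 3', 'N+P', 'Lipid 1', 'Lipid 2', 'unassigned', 'P', 'unassigned']
Lipid 1/(N+P): HMEpC-like 2.58, MCF7-like 0.50, Welch p = 1e-08
calibration: slope 0.300, R^2 1.0000
Lipid 1: 2.08 double bonds -> NDB 2, ester band True
```

Reading this: the classifier separates the groups at 90% resubstitution
accuracy, but the mechanistic finding is the last three lines — the
relative abundance of the resolved "Lipid 1" component against nucleic
acid + protein is five-fold lower in the cancer-like group (Welch
p ≈ 10⁻⁸), and the calibration identifies that component as a
di-unsaturated (NDB 2) lipid carrying the 1745 cm⁻¹ ester band, i.e. a
linoleate-type glyceride rather than a free fatty acid.  The two
`unassigned` entries are the autofluorescence envelopes, which mix with
each other without affecting the chemical conclusions.

## Command line

`ramanpipe` wraps the library:

```sh
ramanpipe synth cells --seed 17 --out data/ --truth truth/
ramanpipe synth standards --seed 17 --out standards/
ramanpipe preprocess --in data/dataset.csv --crop 739:1800 --svd-rank 10 --out clean.csv
ramanpipe mcr --in clean.csv --k 7 --alpha2 0.005 --beta2 0.005 --out-w W.csv --out-h H.csv
ramanpipe run --config run.yaml --out results/
```

`ramanpipe run` executes the whole chain from a declarative YAML config
(all defaults as above) and writes `report.json` with the resolved
configuration embedded; identical config and seed reproduce the report
bitwise.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full analysis from scratch at the given seed: it
generates the default synthetic study, runs preprocessing,
PCA/LDA/SVM discrimination, the penalized k = 7 MCR-ALS factorization,
component annotation, marker-ratio statistics and the unsaturation
calibration, prints a one-line summary and writes the results file.

## Layout

| module | contents |
|---|---|
| `ramanmcr.io` | `Spectrum`, `HyperspectralDataset`, two-column text and CSV persistence |
| `ramanmcr.preprocess` | dark subtraction, spike removal, SVD denoising, cropping, per-cell averaging |
| `ramanmcr.mcr` | penalized non-negative MCR-ALS, rank estimation, component matching |
| `ramanmcr.discriminate` | NIPALS-PCA, LDA, ν-SVM, confusion-matrix metrics |
| `ramanmcr.markers` | band integration, component annotation, marker ratios, unsaturation calibration |
| `ramanmcr.synth` | ground-truthed synthetic cells and fatty-acid standards |
| `ramanmcr.pipeline` | end-to-end orchestration and reporting |

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
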