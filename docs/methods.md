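# Methods

This note documents the models, parameter choices and numerical
decisions behind `ramanmcr`, and what the synthetic-data tests do and do
not establish.

## 1. Data model

A study is an m × n matrix *A* of detector counts: m wavenumbers on a
shared grid, n spectra (cells × points).  Spectra arrive as two-column
text files; assembly linearly interpolates every spectrum onto the first
spectrum's axis restricted to the common interval (multivariate analysis
requires a single grid; interpolation happens once, at assembly).
Column identity is `cellID_pointIndex`, which later drives per-cell
averaging.

## 2. Preprocessing

Order: dark subtraction → cosmic-ray removal → SVD denoising → crop to
739–1800 cm⁻¹ → per-cell averaging.

* **Dark subtraction** is optional (synthetic data needs none).
* **Cosmic-ray removal.** No published rule exists for this step, so the
  detector is a dual criterion designed around the physics of spikes:
  they are single-pixel and uncorrelated across acquisitions.  A pixel
  is repaired only if (a) its robust z-score against the per-wavenumber
  median of all spectra exceeds the threshold (default 8) *and* (b) its
  second difference along the axis exceeds the threshold times the
  *local* MAD of second differences (15-pixel window, floored at half
  the column-wide MAD).  The local window is essential: a genuine band
  apex has large curvature, but so does its neighbourhood, so it is not
  anomalous relative to its own local scale; a one-pixel spike towers
  over a smooth local baseline.  Repaired value: median of the two axis
  neighbours.  On synthetic data with recorded spike coordinates the
  detector removes 100% of injected spikes and modifies nothing else.
* **SVD denoising** truncates to rank 10 by default — safely above the
  7 chemical components assumed downstream.
* **Baseline is deliberately kept**: autofluorescence is resolved later
  as its own components rather than subtracted.

## 3. Penalized non-negative MCR-ALS

The factorization A ≈ WH (W: m × k pure spectra, H: k × n abundances,
both non-negative) minimizes ‖A − WH‖_F with default k = 7, by
alternating solves of the regularized normal equations

    (WᵀW + α²E) H = WᵀA        E = all-ones (k × k), α² = 0.005
    (HHᵀ + β²I) Wᵀ = HAᵀ       I = identity,          β² = 0.005

followed by projection of negative entries to zero.  Notes:

* The α² term couples components through the all-ones matrix E — this is
  the penalized form implemented verbatim, even though it differs from a
  textbook elementwise lasso.  It corresponds to penalizing the squared
  *sum* of each abundance column, which drives collinear solutions
  apart and favours sparse mixtures.
* Initialization: truncated SVD, each singular vector sign-flipped so
  its largest-magnitude entry is positive, negatives clipped; an
  all-zero clipped column falls back to the uniform vector 1/m.  The
  only use of the random seed is re-jittering a component that dies
  during iteration.
* Scale convention: W columns renormalized to unit Euclidean norm after
  every sweep, with the inverse scale folded into H.  WH is invariant
  under this step; it makes abundance magnitudes comparable across
  components, which the relative-abundance ratios require.
* Convergence: relative change of ‖A − WH‖_F below 1e-8, cap 1000
  sweeps.  Objective non-increase and non-negativity are asserted in the
  test suite.
* An exact per-column NNLS mode (`nonneg="nnls"`, solving the augmented
  least-squares problems whose normal equations are the two solves
  above) is available for comparison; projected ALS ("clip") is the
  default because it is the simplest algorithm consistent with the
  equations as printed.  The two agree when the unconstrained solution
  is already non-negative.
* **Which matrix enters MCR.** The factorization runs on the
  point-resolved matrix (n = 300), not the per-cell averages.  The five
  points of a cell sample different subcellular structures, and that
  contrast — spectra dominated by nucleus, droplet, or cytoplasm — is
  what pins down the rotational ambiguity of a non-negative bilinear
  model.  We verified the alternative directly: with per-cell averages
  and near-constant positive abundances, the ground-truth factors are a
  fixed point of the iteration but the SVD start converges to a
  different, equally well-fitting factorization.  Per-cell abundances
  for the marker statistics are the mean of each cell's five point
  abundances.
* Numerical zeros: projected ALS shrinks a vanished component to a tiny
  residual rather than a clean 0.  The ratio report therefore excludes
  denominators below 1% of the component's median positive abundance,
  mirroring how measured cells with zero computed abundance are omitted
  from ratio plots.  The low-level `relative_abundance` operation keeps
  exact-zero semantics.

Rank estimation (`estimate_rank`) reports the singular-value spectrum
and suggests k = #{σᵢ above 5 × the median of the trailing half},
floored at the numerical-rank tolerance.  It is advisory: the pipeline
default keeps k = 7, and the estimate should be computed on raw
(un-denoised) data — after rank-r truncation the trailing singular
values are round-off and the rule is meaningless.

## 4. Discrimination

* **NIPALS-PCA** on column-mean-centered per-cell spectra: sequential
  power iteration of score/loading pairs with deflation; loadings unit
  norm; explained fraction = score variance over total centered
  variance.  Agrees with direct SVD to |cos| > 1 − 1e-8 per component
  in the test suite.
* **LDA** on the first 4 PC scores, two classes, equal priors: direction
  w = S_w⁻¹(μ₁ − μ₀) from the pooled within-class covariance (ridge
  1e-8 added only if singular), threshold at the midpoint of the
  projected class means.  Resubstitution is the default evaluation; a
  leave-one-out mode is provided.
* **ν-SVM**, linear kernel, ν = 0.5 default, stratified 10-fold CV with
  seed-fixed fold layout (scikit-learn `NuSVC` under the hood).
* Metrics in percent; the integer display **truncates** toward zero
  (29/30 → 96), matching the convention of reporting 96% for 29 of 30.

## 5. Chemical interpretation

* **Band integration**: trapezoidal area over center ± 15 cm⁻¹ after
  subtracting a straight line through the window endpoints (peak-height
  mode available).  Area is the default because it is robust to grid
  spacing; the literature mixes peak-intensity and band-area language,
  so both are exposed.
* **Component annotation** is rule-based on significant peaks near the
  fingerprint band library (786, 879, 1003, 1263, 1300, 1440–1446,
  1576, 1657/1658, 1745 cm⁻¹).  Peak presence uses a prominence floor
  relative to the spectrum's largest peak (default 0.2): an absolute
  floor tied to the median spectrum level fails in both directions on
  unit-norm component spectra — it rejects protein peaks riding a
  dominant autofluorescence envelope and accepts curve-resolution
  crosstalk on sparse lipid spectra.  Nucleic-acid vetoes require both
  nucleic bands (786 *and* 1576); a single band at the floor is
  crosstalk.  Autofluorescence components are recognized by a high
  running-minimum background fraction, with the protein-bearing variant
  requiring 1003/1450/1657 peaks at ≥ 8% of the maximum intensity.
  Lipids are numbered by descending ester-band (1745 cm⁻¹) prominence,
  ties broken by unsaturation ratio, so a glyceride is always "Lipid 1".
* **Unsaturation calibration**: ordinary least squares of
  r = I(1658)/I(1445) (band areas after 1445-area normalization, which
  is algebraically the plain area ratio) against NDB over the
  fatty-acid standard panel (NDB 1–6).  Inverse prediction gives a
  continuous NDB estimate and a nearest-integer class; the ester flag
  (1745 cm⁻¹ peak) distinguishes glycerides from free fatty acids.

## 6. The synthetic world

The generator emulates the study design: 30 cells per group, 5 points
per cell, 370–1800 cm⁻¹ at 1 cm⁻¹, Lorentzian bands (FWHM 12 cm⁻¹,
typical for condensed-phase Raman), seven components (two
autofluorescence envelopes realized as 4th-order polynomials — one
carrying protein bands — nucleic acid + protein, three unsaturated
lipids, protein).  Lipid C=C band amplitude is proportional to NDB
against a constant CH₂ band, so the calibration law holds by
construction, and the same band model generates cells and standards so
one calibration applies to both.

Abundances: per-cell lognormal (CV 0.25 across cells) around component
base abundances; group effects are multipliers on the cancer-like group
(Lipid 1 × 0.4, N+P × 1.3 — chosen to reproduce the qualitative
finding that the ester-bearing lipid is depleted in cancer cells, not
measured values); a 2% per-lipid probability of a droplet-free cell
(abundance exactly zero); and component-specific lognormal jitter
across the five points of a cell (CV 0.25–0.9; large for the
nucleus-localized nucleic component and droplet-borne lipids, small for
diffuse autofluorescence).  The point-level heterogeneity is the
feature that makes the factorization identifiable — near-pure
observations bind the rotational ambiguity — and is far closer to real
point sampling of cells than uniform small jitter.  Noise is additive
Gaussian at 1% of the mean signal (plausible for 30 s acquisitions);
cosmic rays hit 10% of spectra at 100 × the column median, at recorded
coordinates.  The extra additive background field defaults to zero: the
autofluorescence components inside W carry the background, keeping the
ground truth exactly rank 7 as the k = 7 analysis assumes.

What a green synthetic test establishes: the solver recovers the
planted factors and the marker statistics recover the planted group
difference under realistic noise, heterogeneity and artifacts.  What it
does not establish: performance on real cells — real autofluorescence
photobleaches within and across exposures, real band shapes and
positions drift with instrument calibration, real lipid droplet
statistics are unknown, and real component spectra are not exact sums
of Lorentzians.  Effect sizes are generator parameters, not
measurements.

## 7. Known limitations

* Projected ALS is a heuristic for the non-negativity-constrained
  problem; it can stall in alternative factorizations when the data
  carry little abundance contrast (dense, near-constant positive H).
  The NNLS mode is exact per sub-problem but much slower and does not
  remove the intrinsic rotational ambiguity.
* The two autofluorescence envelopes overlap strongly and routinely mix
  with each other in resolved solutions; the chemical conclusions
  (lipid/nucleic/protein components and their ratios) are unaffected,
  and the annotation reports such components as AF or unassigned.
* Uncertainty quantification (rotational-ambiguity bands), closure and
  unimodality constraints, and multi-set MCR are out of scope.
* The two mono-unsaturated lipids are distinguishable here only because
  the generator gives them distinct chain signatures; the method itself
  cannot tell which mono-unsaturated fatty acid a component is, only
  its unsaturation index and ester status.
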