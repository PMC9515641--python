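# Methods

## Cell model and forward optics

A suspended cell is idealized as two concentric homogeneous spheres: the
nucleus (core) of refractive index RI_N inside the cytoplasm (shell) of
index RI_C, immersed in buffer of index n_m. Four parameters describe a
cell: total diameter D (µm), the nucleus-to-cell size ratio N/C (core
diameter over total diameter), RI_N and RI_C. The model deliberately
ignores discrete organelles (mitochondria, granules); their aggregate
optical effect is absorbed into the effective compartment indices, which
is the standard reading of core–shell fits to immune cells.

The exact electromagnetic solution for a coated sphere is the Aden–Kerker
extension of Mie theory. With size parameters x = πDncn_m/λ (core) and
y = πDn_m/λ (whole cell) and relative indices m₁ = RI_N/n_m,
m₂ = RI_C/n_m, the partial-wave coefficients aₙ, bₙ follow the classical
formulation in terms of Riccati–Bessel functions ψₙ, χₙ, ξₙ = ψₙ − iχₙ,
with core-boundary auxiliaries Aₙ, Bₙ that vanish when the core is
index-matched or vanishingly small (the solution then collapses to the
homogeneous Mie sphere, which the tests verify against an independent
implementation to better than 1e−8). All indices are real: cells are
treated as non-absorbing at 632.8 nm.

Numerical choices:

* **Truncation** at the Wiscombe order n_max = ⌈y + 4y^{1/3} + 2⌉
  (n_max ≈ 155 for the largest 20 µm grid cell).
* **Riccati–Bessel evaluation** by vectorized three-term recurrences —
  upward for χₙ (stable, grows with order) and Miller's downward
  recurrence with rescaling for ψₙ, normalized against ψ₀ = sin z. This
  evaluates the ~10⁶ (order, argument) pairs of a full table build in
  well under a second and agrees with scipy's spherical Bessel functions
  to ~1e−10 over the relevant argument range (asserted in tests).
  Orders whose auxiliaries over/underflow lie far beyond the physical
  cutoff; their coefficients are set to their correct limit, zero.
* **Degenerate shell** (N/C = 1) is rerouted to the homogeneous solution
  to avoid zero-thickness recurrences.
* **Polarization**: the instrument's detector polarization is not
  specified, so the default observable is the unpolarized average
  (|S₁|² + |S₂|²)/2; perpendicular/parallel are selectable.
* **Units** are relative — no radiometric calibration — so all downstream
  matching is scale-invariant by construction.
* **Angular grid**: the published "approximately 2–30°, approximately
  0.1°" window is fixed to exactly [2.0°, 30.0°] in 0.1° steps
  (281 points) for reproducibility.
* **Window energy**: the helper `integrated_intensity` integrates
  I(θ)sinθ dθ. The solid-angle weight matters: the plain angular sum is
  *not* monotone in diameter (interference redistributes intensity inside
  a fixed window), whereas the physically meaningful windowed power is,
  and the test suite asserts monotonicity for that quantity.

An optional idealized detector pair renders an LSP onto a square pixel
grid and recovers it by sampling thin circles of constant scattering
angle (bilinear interpolation, azimuthal averaging). Circle sampling
rather than annular binning is used because 0.1°-wide annuli smear the
interference minima by several percent, which would dominate the
round-trip error. The real instrument's camera-to-angle mapping is
undisclosed; this stage is an idealization and nothing downstream
depends on it.

## Lookup-table inversion

The published pipeline retrieves cell properties by matching each
measured profile against precomputed theoretical profiles; only the table
size (≥ 335,000 curves) is printed, not its axes. The default grid here
is

| axis | range | step | points |
|------|-------|------|--------|
| D | 6–20 µm | 0.25 µm | 57 |
| N/C | 0.70–0.95 | 0.01 | 26 |
| RI_N | 1.36–1.46 | 0.005 | 21 |
| RI_C | 1.33–1.43 | 0.01 | 11 |

giving 57·26·21·11 = 342,342 rows, covering every printed property value
with margin. Curves are stored log₁₀ unit-mean normalized; the matching
metric is the mean squared difference of these normalized curves. The log
domain balances the several-orders-of-magnitude dynamic range between the
forward lobe and the side angles (a linear-domain metric was evaluated
and recovers parameters measurably worse). Matching is pure nearest
lookup — no sub-grid refinement — with ties broken to the lowest row
index; the winning residual is recomputed exactly so a stored curve
self-matches at exactly zero. Queries on a different angular grid are
linearly interpolated onto the table grid; extrapolation is refused.
Tables persist to HDF5 with a configuration hash; a cache whose hash
disagrees with the requested configuration raises rather than serving
stale curves, and rebuilds with identical configuration are bit-identical.

**Identifiability limit.** The 2–30° window does not uniquely identify
all four parameters per cell: distinct tuples (shrinking the core while
raising index contrast, or trading diameter against N/C) can produce
nearly indistinguishable curve shapes. Empirically, a substantial
minority of noise-free off-grid cells invert to a tuple more than one
grid step from truth on the N/C or index axes even though the matcher
provably returns the exhaustive-scan optimum — the parameter-nearest grid
point simply fits worse than a distant near-degenerate one. Each
phenotype's *mean* cell recovers its nearest grid point exactly, and
population means and classification are robust to this scatter (it acts
as approximately unbiased retrieval noise), but single-cell N/C and index
estimates should be read with the degeneracy in mind. The corresponding
per-cell recovery test in the acceptance suite is expected to fail and is
kept as an honest record of this resolution limit.

## Synthetic populations

The generator replaces the instrument and donors. Each phenotype is a
product of independent truncated Gaussians over the four properties
(truncated at the grid bounds so every cell is representable), using the
published means, diameter SDs and pooled sample sizes:

| phenotype | D (µm) | N/C | RI_N | RI_C | n |
|-----------|--------|-----|------|------|---|
| monocyte | 9.82 ± 1.59 | 0.80 | 1.39 | 1.36 | 148 |
| M0 | 15.66 ± 2.84 | 0.85 | 1.42 | 1.39 | 149 |
| M1 | 11.76 ± 1.72 | 0.85 | 1.42 | 1.38 | 167 |
| M2 | 14.25 ± 2.29 | 0.85 | 1.43 | 1.39 | 215 |

Only diameter dispersions are published. The N/C and index SDs are the
generator's single calibration knob: one documented calibration pass
compared candidate values (SD_N/C ∈ {0.02, 0.03},
SD_RI ∈ {0.004, 0.006, 0.008, 0.010}) against the three published
cross-validated accuracies, selected **SD_N/C = 0.02, SD_RI = 0.006**,
and froze them; no per-test tuning. Measurement noise is pointwise
multiplicative log-normal with unit mean and 5% relative SD (unstated in
the source; chosen as realistic shot-to-shot variability that is
non-destructive to matching), with no angular jitter by default.

Two consequences of this design worth knowing:

* Truncation at the 20 µm grid bound shifts the effective M0 diameter
  mean from 15.66 to ≈15.29 µm (the bound sits 1.5 SD above the mean);
  recovered M0 means inherit this shift. It stays inside the recovery
  tolerance and is a property of keeping every cell invertible.
* Properties are sampled independently — the source reports no
  correlation structure — so the synthetic populations lack whatever
  size–index covariance real macrophages have. Passing tests therefore
  demonstrate that the *pipeline* reproduces the published numbers under
  the published marginal distributions, not that it would do so verbatim
  on donor cells.
* The monocyte sample size is printed inconsistently in the source (148
  in the population figure, 107 in the classification experiment); the
  generator defaults to 148, and the monocyte-vs-M0 classification
  experiment draws its own n = 107 monocyte population.

## Microfluidic alignment criterion

Viscoelastic focusing in the 0.4 wt% PEO carrier drives cells to the
channel centreline when 3 Wi β² (L/2R) > −ln(3.5β), with
Wi = λ_relax Ū / R, β = r₁/R. Defaults are the published operating point
(λ_relax = 0.197 ms, Ū = 1496 µm/s, R = 25 µm, L = 0.35 m); units are
declared per field and reconciled internally. The published velocity unit
is garbled ("µm⁻¹"); dimensional analysis of Wi fixes it as µm/s. The
"(L/2R)" factor is read literally as L/(2R). At the operating point
Wi ≈ 0.0118 and a 5 µm-radius cell clears the criterion by a factor of
~28 (margin ≈ 9.5).

## Classification and statistics

Features are the four recovered properties. Classifier presets mirror the
originating ML toolbox: quadratic SVM = SVC with 2nd-degree polynomial
kernel, box constraint 1, kernel scale 1 (γ = 1/scale², coef0 = 1),
one-vs-one; cosine KNN = 10 neighbours, cosine distance, equal weights;
fine KNN = 1-NN Euclidean; medium tree = 20 leaf nodes. The published
protocol is 5-fold cross-validation repeated 5 times; folds here are
stratified (the source says only "fivefold"), z-scoring is fit inside
each training fold only (no leakage — a label-shuffle test guards this),
and each repeat's out-of-fold predictions form one confusion matrix.
Reported are per-repeat accuracies and unit-cost misclassification
counts, plus PPV/FDR per class from the summed matrix
(PPV_c = 100·TP_c/column-sum; FDR = 100 − PPV; a never-predicted class
reports NaN). `compare_classifiers` reuses identical splits across
presets so ranking differences are paired. KNN ties resolve to the
smallest class index. The published quadratic-SVM parameter list mixes in
KNN parameters ("one neighbour, Euclidean metric"); that fragment is
treated as an editorial artifact and ignored.

Group comparisons use classical one-way ANOVA (scipy) with Tukey HSD
(statsmodels) and the conventional significance codes (n.s. > 0.05,
* < 0.05, ** < 0.01, *** < 0.001); the tests cross-check both against an
independent implementation (pingouin) and the two-group F = t² identity.
All-constant groups report F = ∞, p = 0, flagged degenerate.

## Problem sizes and reproducibility

The full default table (342,342 curves × 281 angles) builds in about a
minute on one CPU and ~800 MB; population-scale inversion (679 cells) is
a few seconds via a blocked matrix-product distance computation. Tests
use a 240-row coarse table for exhaustive brute-force comparisons and the
full table for end-to-end recovery and classification. Every random
draw flows from an explicit seed (populations, noise, CV splits);
pipeline runs carry a configuration hash and identical configurations
reproduce identical artifacts byte for byte.

## Known limitations

* Single-cell N/C and index retrievals are degenerate-limited (above);
  the pipeline's strength is at population level.
* The coated-sphere model has exactly two compartments; organelle-scale
  scatterers are not modelled discretely.
* The synthetic generator omits property correlations, cell–cell
  coincidences, flow dynamics and deformation.
* The detector stage is an idealization of an undisclosed camera
  geometry; quantitative claims rest on the LSP-domain pipeline.
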