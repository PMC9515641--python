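# scattercyte

Label-free phenotyping of single immune cells from small-angle
light-scattering profiles (LSPs), with supervised classification of
monocyte and macrophage (M0 / M1 / M2) populations.

Pro-inflammatory (M1) and anti-inflammatory (M2) macrophages are usually
told apart by staining, surface markers or transcript panels — slow,
costly, and destructive. An alternative is optical: a cell flowing in
single file through a laser produces a scattering pattern whose shape
encodes its morphology. `scattercyte` implements the complete analysis
behind that idea, for anyone who wants to simulate, invert or classify
such measurements:

1. **Forward optics** — a cell is modelled as a concentric coated sphere:
   nucleus (core, refractive index RI_N) inside cytoplasm (shell, RI_C).
   The exact Aden–Kerker extension of Mie theory gives the partial-wave
   coefficients aₙ, bₙ, and the unpolarized scattered intensity
   I(θ) = (|S₁(θ)|² + |S₂(θ)|²)/2 on the instrument window 2–30° at 0.1°
   (λ = 632.8 nm, medium index 1.334).
2. **Lookup-table inversion** — observed profiles are matched (mean squared
   difference of log₁₀ unit-mean curves) against 342,342 precomputed
   theoretical profiles on a grid over (D, N/C ratio, RI_N, RI_C),
   retrieving the four biophysical properties per cell.
3. **Synthetic populations** — monocyte/M0/M1/M2 cells drawn from the
   published per-phenotype property distributions (e.g. M0: D =
   15.66 ± 2.84 µm, n = 149), forward-modelled and corrupted with 5%
   multiplicative log-normal intensity noise, standing in for the
   microfluidic instrument.
4. **Microfluidics design check** — the viscoelastic centreline-focusing
   criterion 3 Wi β² (L/2R) > −ln(3.5β) with Wi = λ_relax·Ū/R.
5. **Classification & statistics** — quadratic/linear/cubic SVM, fine and
   cosine KNN, depth-limited tree; stratified 5-fold cross-validation
   repeated 5 times; confusion matrices with per-class PPV/FDR and unit
   misclassification cost; one-way ANOVA with Tukey HSD.

## Worked example

```python
from scattercyte import (CoreShellCell, NoiseModel, add_noise, build_lookup,
                         lsp_intensity, match_lsp)
from scattercyte.pipeline import toy_grid

table = build_lookup(toy_grid())            # coarse 240-curve demo table
cell = CoreShellCell(diameter=11.8, nc_ratio=0.84,
                     ri_nucleus=1.421, ri_cytoplasm=1.378)
measured = add_noise(lsp_intensity(cell), NoiseModel(0.05), seed=1)
m = match_lsp(measured, table)
print(m.best, round(m.residual, 4))
```

prints

```
CoreShellCell(diameter=12.0, nc_ratio=0.85, ri_nucleus=1.42, ri_cytoplasm=1.37) 0.0682
```

— the noisy profile of an off-grid 11.8 µm cell is matched to the nearest
grid cell of the coarse demo table; each recovered property is quantized
to that table's step. The scripts in `examples/` walk through every stage
(forward model, inversion, population simulation + classification,
alignment check, group statistics) and print annotated output;
`python examples/03_population_classification.py` shows the full
simulate → invert → classify chain at desk scale.

A thin CLI mirrors the stages:

```sh
scattercyte simulate --seed 42 --out lsps.h5
scattercyte build-lut --out lut.h5
scattercyte invert --lut lut.h5 --in lsps.h5 --out features.csv
scattercyte classify --features features.csv --task m1m2 --seed 42 --out report.json
scattercyte check-alignment --r1 7.8
```

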