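# specresolve

Chemometric resolution and quantification of a severely overlapped
quaternary UV-Vis mixture — paracetamol (PARA), ascorbic acid (ASC),
caffeine (CAF) and chlorpheniramine maleate (CPM), the classic cold-remedy
combination — without any chromatographic separation. The package is aimed at
analytical chemists and chemometricians who want a tested, scriptable
reference implementation of the full workflow: calibration design, four
calibration engines, validation diagnostics, statistical method comparison,
and analytical greenness scoring.

Because the four spectra overlap heavily over 220–300 nm, single-wavelength
quantification fails; multivariate calibration on the full spectral window
is required. The absorbance of a mixture follows the Beer-Lambert law
extended over wavelengths, **D** = **C Sᵀ** + **E**, with **C** the sample ×
analyte concentrations and **S** the pure unit-absorptivity spectra. Four
engines invert this relationship:

* **PCR** — principal component regression: regress concentrations on the
  leading SVD scores of the mean-centred spectra.
* **PLS** — NIPALS PLS2: latent variables maximizing X–Y covariance, all four
  analytes modelled jointly, **B** = **W**(**PᵀW**)⁻¹**Qᵀ**.
* **MCR-ALS** — alternating least squares on **D** ≈ **C Sᵀ** under
  non-negativity (active-set NNLS) and a correlation constraint that anchors
  the resolved concentrations to the calibration references in real units;
  figures of merit LOF = 100·√(Σe²/Σd²) and R² = 100 − LOF²/100. The only
  engine that also *resolves* the pure spectra.
* **ANN** — a feed-forward purelin–purelin network (81 → 5 → 4) trained by
  Levenberg–Marquardt with seeded 70/15/15 splits and early stopping; with
  linear transfers the network is exactly an affine map.

Latent-variable counts are chosen by leave-one-out cross-validation; the
validation set is judged by recovery %, RMSEP, Durbin-Watson statistics on
ordered residuals (permutation p-values), the elliptical joint confidence
region (EJCR) test for (slope, intercept) = (1, 0), and pooled t / F
comparison between methods. Greenness is scored with the Analytical
Eco-scale (100 minus penalty points) and an AGREE-style 12-principle mean.

Measured spectra for this system are not publicly deposited, so the package
ships a first-class synthetic data module: the published 30-mixture
five-level calibration design (verbatim fixture plus a cyclic generator),
sum-of-Gaussian pure spectra with the same kind of band overlap, additive
Beer-Lambert mixing with 0.002 AU photometric noise, and a simulated capsule
assay at the challenging 80:1:10:60 ratio with CPM spiking. See
`docs/methods.md` for every modelling decision and its rationale.

## Worked example

```python
import numpy as np
from specresolve import (table1_design, default_pure_spectra, simulate_spectra,
                         fit_pls, predict, recovery_stats, fit_mcr_als)
from specresolve.preprocessing import select_window

design = table1_design()                    # 25 calibration + 5 validation mixes
pure = default_pure_spectra()               # synthetic unit spectra, 200-400 nm
spectra = simulate_spectra(design, pure, noise_sd=0.002, seed=1)
windowed = select_window(spectra, 220.0, 300.0)   # 81 points

cal, val = design.calibration, design.validation
Xcal = windowed.subset(range(25)).absorbance
Xval = windowed.subset(range(25, 30)).absorbance

model = fit_pls(Xcal, cal.nominal, 4)
rec = recovery_stats(predict(model, Xval), val.nominal, design.analytes)
for name, m, s in zip(design.analytes, rec.mean, rec.sd):
    print(f"{name}: mean recovery {m:6.2f}%  SD {s:4.2f}")

mcr = fit_mcr_als(Xcal, cal.nominal)
print(f"MCR-ALS: {mcr.n_iter} iterations, LOF {mcr.lof_trace[-1]:.4f}%, R2 {mcr.r2:.4f}%")
```

prints

```
PARA: mean recovery  99.98%  SD 0.80
ASC: mean recovery 100.47%  SD 0.80
CAF: mean recovery 100.03%  SD 0.62
CPM: mean recovery 100.32%  SD 0.25
MCR-ALS: 2 iterations, LOF 0.1052%, R2 99.9999%
```

i.e. all four analytes are recovered within ±0.5% of nominal at the default
noise level despite the spectral overlap, and the curve-resolution model
explains essentially all spectral variance. The whole pipeline — simulation,
all four engines, diagnostics tables, greenness report, manifest — runs as

```sh
specresolve run-all --out my_run --seed 1
```

or stage by stage via `specresolve simulate | calibrate | predict | diagnose
| greenness`.

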