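# Methods

`specresolve` implements a complete chemometric workflow for quantifying a
severely overlapped quaternary drug mixture — paracetamol (PARA), ascorbic
acid (ASC), caffeine (CAF) and chlorpheniramine maleate (CPM) — from UV-Vis
absorbance spectra, exercised end-to-end on synthetic Beer-Lambert data. This
note records the models, the synthetic study conditions, and the design
choices made where the design was genuinely open.

## The synthetic study

**Calibration design.** A five-level, four-factor design with 25 calibration
mixtures and 5 hold-out validation mixtures. The concentration grids are
PARA 4–20, ASC 3–15, CAF 2.5–12.5 and CPM 1–9 µg/mL, five equidistant levels
each. The published mixture table ships verbatim as the default fixture
(`data/table1_design.csv`); its first and last calibration rows are the
duplicated all-centre point, preserved as printed. A cyclic generator
(`generate_design(source="cyclic")`) rebuilds designs for new grids: run 1
puts every factor at its centre level; runs 2–25 take factor 1's coded levels
from a fixed 24-term cyclic sequence and factor *j*+1 at run *i* equals
factor *j* at run *i*+1, cyclically. The shipped sequence is the fixture's
first-factor column, so the generator and the fixture agree except for a
handful of rows where the printed table deviates from the cyclic rule
(apparently misprints; the fixture is treated as ground truth). One
validation mixture (8, 8, 8, 8) is deliberately off-grid; coded levels are
NaN there.

**Pure spectra.** True molar absorptivities for this system are not tabulated
anywhere usable, so the pure-component spectra are sums of Gaussian bands
(`data/pure_bands.yaml`, editable). The band table was chosen once to satisfy
the qualitative features that make the problem interesting and solvable:

* all four absorption maxima inside the 220–300 nm working window, with every
  pairwise correlation of the pure spectra above 0.3 over that window
  (severe overlap — univariate quantification is impossible);
* unit absorptivities such that mixture absorbances stay below ≈1.5 AU at the
  top of each grid (a realistic photometric range);
* conditioning such that, at the default noise level, per-sample concentration
  errors are ≈1% of the smallest grid level — the precision scale a bench
  UV-Vis multivariate assay actually reports.

**Noise.** i.i.d. homoscedastic Gaussian absorbance noise, default
sd = 0.002 AU, the standard photometric-noise scale of a scanning
spectrophotometer. No wavelength correlation, no stray-light or baseline
drift, no intensity-dependent (shot-like) component. Consequences: passing
tests demonstrate algorithmic correctness and noise-propagation behaviour,
not robustness to instrumental artefacts or matrix effects that real spectra
carry.

**Dosage form.** The simulated capsule assay fixes the challenging
80 : 1 : 10 : 60 PARA : CPM : CAF : ASC ratio (20.00, 0.25, 2.50, 15.00 µg/mL
after dilution); CPM is spiked by 0.75 µg/mL to reach 1.00 µg/mL, the bottom
of its calibrated range. Three replicates; excipient absorbance defaults to
zero (an additive `baseline` hook exists).

## Preprocessing

Spectra are cut to the inclusive 220.0–300.0 nm window (81 points at 1 nm)
before any modelling; bounds must lie on the wavelength grid. PCR and PLS
mean-centre both blocks, storing the calibration means so that prediction
always subtracts *calibration* means. MCR-ALS and the purelin network consume
raw (uncentred) absorbances within the window: non-negativity constraints are
meaningless on centred data, and an affine network absorbs any offset in its
biases. This is a deliberate reading of "mean-centred prior to model
construction" as applying to the factor-regression models.

## Calibration engines

**PCR.** Components from the SVD of the centred X-block (identical subspace
to NIPALS PCA, numerically safer); centred Y regressed on the leading scores.

**PLS.** Classic NIPALS PLS2 over all four analytes simultaneously, deflating
X and Y per component (inner-loop tolerance 1e-10, cap 500 iterations);
coefficients assembled as B = W(PᵀW)⁻¹Qᵀ. A single-column Y degenerates to
PLS1 automatically.

**Latent-variable count.** Leave-one-out cross-validation, refitting and
re-centring on every fold, from 0 (mean-only model) to `max_lv` components.
The selected count is the *smallest* whose analyte-averaged RMSECV lies
within max(1e-8 µg/mL, 0.1% relative) of the global minimum. The tolerance
makes selection well-posed on noise-free data, where every count at or above
the true rank gives RMSECV at machine-noise level in an arbitrary order; it
is far below any chemically meaningful error difference. LV counts whose
extraction fails on some fold (no components left in rank-deficient data) are
excluded. RMSEC/RMSECV use an *n* denominator, so absolute comparability
with toolbox outputs that divide by n − LV − 1 is qualitative.

**MCR-ALS.** Bilinear model D ≈ CSᵀ refined by alternating least squares.
Initial spectra come from a greedy maximum-volume ("purest sample")
selection, or can be injected. Constraints per iteration: non-negativity on C
and S via per-row/per-column active-set NNLS (a clipping mode exists behind a
flag), and a correlation constraint on C — each component's ALS concentration
column is regressed on its reference column over the calibration rows
(c_als ≈ a + b·c_ref); calibration entries are then replaced by the
back-transformed fitted values (the reference concentrations, in µg/mL) and
appended unknown rows by the back-transformed ALS values (c − a)/b. The
components are matched to reference columns once, on the first iteration, by
Hungarian assignment on |r|. This strong anchoring removes the intensity and
rotational ambiguity of the bilinear model; a weaker variant that merely
rescales the column was tried and left visible rotational mixing in the
resolved spectra. Convergence: relative lack-of-fit change below 0.1%
(toolbox convention) or LOF below 1e-10%. A sustained LOF climb (10
consecutive rises beyond a small slack) aborts — transient rises are normal
while constraints reshape the profiles. Prediction is one-by-one: the test
spectrum is appended to the calibration matrix, ALS re-runs from the fitted
spectra with the correlation constraint applied to calibration rows only, and
the test row of C is returned. Figures of merit: LOF = 100·√(Σe²/Σd²) and
R² = 100·(1 − Σe²/Σd²), linked by the identity R² = 100 − LOF²/100.

**Purelin network.** 81 inputs → hidden layer (default 5 neurons; 4 is one
flag away, both sizes being defensible) → 4 linear outputs, linear transfer
on both layers, i.e. exactly an affine map y = W₂(W₁x + b₁) + b₂. Inputs and
targets are scaled per feature to [−1, 1] (mapminmax style). Training is
Levenberg–Marquardt on the full weight vector with the exact analytic
Jacobian: damping μ starts at 0.1 (the sensible reading of a quoted
"learning rate" for a damped Gauss–Newton method), is ×10 on a rejected step
and ×0.1 on an accepted one, so training MSE is non-increasing over accepted
steps; when no damped step improves the fit the optimum is declared. The 25
calibration samples are split 70/15/15 into train/validation/test by a
seeded shuffle (the 5-mixture hold-out never enters training); training stops
early after 6 consecutive epochs of rising validation MSE and the weights of
the best validation epoch are returned. Weight init is small fan-in-scaled
uniform(−0.5, 0.5), seeded — Nguyen-Widrow offers nothing for a linear net.
Because 81 inputs exceed the ~17 training spectra, the affine map is
identified only on the span of the pure spectra; projected onto that span it
coincides with the Beer-Lambert pseudo-inverse, and that is what the tests
assert.

## Diagnostics

Recovery % = 100·found/nominal, with column mean and sample SD (n−1). The
published validation tables label this column RSD but print SD-scale values;
both are reported, SD being the comparable field. RMSEC/RMSEP use the n
denominator. Predicted-vs-nominal regression gives slope/intercept/r; the
Durbin-Watson statistic Σ(eᵢ−eᵢ₋₁)²/Σeᵢ² is computed on residuals ordered by
ascending nominal concentration, with a seeded permutation p-value (default
10⁴ shuffles, two-sided departure from 2, add-one convention) — distribution
tables for DW assume a fixed regressor design that a 5-sample validation set
does not satisfy, whereas the permutation null is assumption-free and
testable (its p-values are uniform under i.i.d. residuals). Method
comparison: pooled-variance two-sample t (df = n₁+n₂−2) and variance-ratio
F ≥ 1 with two-sided critical values at 95% (6.39 ≈ one-sided 97.5% at
(4, 4) df, as conventionally printed). The EJCR test declares accuracy when
(intercept 0, slope 1) satisfies (β̂−β)ᵀXᵀX(β̂−β) ≤ 2s²F(2, n−2, 0.95); the
membership check carries a 1e-10 absolute slack so that exact predictions
(s² = 0 to rounding) are not rejected by floating-point residue.

## Greenness

Eco-scale: score = 100 − Σ penalty points; reagents score pictograms ×
signal-word (warning 1, danger 2) × amount bracket (<10 mL: 1, 10–100 mL: 2,
>100 mL: 3); instrument energy, occupational hazard and waste are direct
bracket lookups; >75 is "excellent", >50 "acceptable". The rule tables are an
editable YAML file. The methanol entry of the shipped item list decomposes
its published 12 points as 3 pictograms × danger × 10–100 mL — a reconstruction,
since only the total is published. AGREE: twelve principle scores in [0, 1]
aggregated by a weighted arithmetic mean, equal weights by default; the full
per-principle rubric automation is out of scope, scores are direct numeric
inputs. The shipped 12-score file is labelled synthetic: the source procedure
reports only the aggregate (0.77), and the breakdown was reconstructed to be
plausible and to average to it.

## Pipeline and problem sizes

`run_pipeline` simulates the 30-mixture study (default noise 0.002 AU), fits
all four engines (LV count by LOO-CV), predicts the 5 validation mixtures,
and writes recovery/FOM/EJCR/t–F reports plus the greenness scores and a
manifest of config and file hashes; everything flows from named seeds, so
runs are byte-identical. Default sizes throughout the tests are the study's
own: 25 + 5 samples, 81 wavelengths, 1000-replicate Monte-Carlo where a
sampling distribution is asserted — small enough that the whole suite runs in
seconds on one core.

## Known limitations

* The synthetic band table reproduces the *kind* of overlap, not the real
  absorptivities; published RMSEC/RMSEP/DW table values tied to the measured
  spectra are out of reproduction scope, and only formula-level fidelity is
  claimed for them.
* The noise model omits baseline drift, wavelength error and heteroscedastic
  components; engine rankings under such artefacts are not established here.
* MCR-ALS implements non-negativity and correlation constraints only;
  unimodality, closure, equality and trilinearity are named but unsupported.
* The Durbin-Watson p-value is permutation-based; it will not match Imhof/Pan
  exact-distribution p-values digit for digit.
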