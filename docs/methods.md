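# Methods

This note documents the models, numerical choices and limitations behind
`spacol`. It describes what the code computes and why the defaults are what
they are; every number quoted here is produced by the package's own tests or
scripts.

## Forward model and fluence normalization

A multiwavelength photoacoustic scan is modeled as

I(λ, x) = Φ(λ) · Γ · Σ_c ε̃_c(λ) · c_c(x) + noise,

with Φ(λ) the mean optical fluence of the scan at wavelength λ, Γ the
Grüneisen factor (assumed constant and absorbed into the arbitrary intensity
units, i.e. fixed at 1), ε̃_c(λ) the min-max-normalized absorptivity of
chromophore c and c_c(x) its relative concentration at pixel x. Fluence is
estimated per pulse as measured energy divided by the beam's focal-spot area
(default 0.51 cm², the instrument constant this pipeline was built around)
and averaged per wavelength over all pulses of the scan; each image is then
divided by its wavelength's mean fluence. Because the unmixing output is
renormalized per pixel, only *relative* errors between the per-wavelength
fluence estimates matter; a global fluence or gain error cancels exactly.

## Chromophore spectra

The packaged spectra (`src/spacol/data/*.tsv`, 650–1000 nm at 2 nm) are
synthetic stand-ins, as their filenames and `# source:` headers state:

* **Hb and HbO₂** are monotone-preserving (PCHIP) interpolants through
  anchor values reproducing the canonical NIR-I shapes of the standard
  compilations: deoxy-Hb's steep decline from 650 nm with the 760 nm bump,
  and oxy-Hb's minimum near 690 nm rising to a broad maximum near 920 nm.
* **Collagen** is an analytic sum of absorption bands with the documented
  NIR-I features: global maximum at 690 nm, local minimum at 850 nm, local
  maximum at 910 nm (modeled with a broader short-wavelength flank, as is
  typical of vibrational overtone bands), local minimum at 944 nm, then a
  rise toward the strong band just beyond 1000 nm.

Min-max normalization over 650–1000 nm (the full NIR-I window, the natural
default when no narrower window is specified)
removes absolute scale, so only these shapes enter the unmixing system. The
`mass_to_molar_absorptivity` conversion (µ_a divided by density/molar-mass)
is provided for completeness and is shape-neutral by construction. Spectrum
interpolation is piecewise linear on the 2 nm grid.

The resulting default design matrix A (5 wavelengths × 3 chromophores,
columns fixed as collagen, HbO₂, Hb to prevent silent label swaps) has full
rank and 2-norm condition number ≈ 6.4. The dominant small singular
direction mixes collagen and Hb: after normalization both spectra are large
at 690 nm and small at 850 nm, a physical quasi-collinearity that bounds how
well any solver can separate them under noise.

## Unmixing solvers

All solvers return non-negative relative concentrations summing to 1
(rescaled so 1000 a.u. = relative concentration 1), with all-zero pixels
flagged degenerate rather than NaN so ROI statistics stay well defined.

* **`ols-clip` (default).** The sequential recipe: unconstrained least
  squares on A, negative entries replaced by 0, renormalization to sum 1.
  The clip is applied before the renormalization — the opposite order would
  destroy the sum constraint — so both output constraints hold
  simultaneously. The radial renormalization makes the estimator exactly
  scale-invariant, the correct property for arbitrary-unit data.
* **`nnls`.** Non-negative least squares then renormalization. Also exactly
  scale-invariant (the feasible cone is scale-free). This is the joint
  maximum-likelihood estimate of (scale, mixture) under Gaussian noise.
* **`simplex`.** Exact least squares constrained to the probability simplex,
  by enumeration of the simplex's seven faces with a closed-form KKT solve
  on each; the global constrained minimizer lies in the relative interior of
  some face, so the feasible candidate with the smallest residual is the
  exact optimum. This solver assumes the intensity vector is on the
  relative-concentration scale (unit mixture sum in data units). When that
  calibration holds — e.g. synthetic mixtures, or data normalized by a known
  gain — it is the most accurate of the three, because the unit-sum
  constraint removes one noise dimension. It is not scale-invariant.

A structural trade-off follows, and the test suite pins it down: at 20 dB
per-pixel SNR on uniformly drawn unit-scale mixtures, the simplex solver
recovers the collagen fraction with mean absolute error ≈ 0.04, while the
scale-invariant solvers sit near 0.07. No scale-invariant estimator can
close that gap — invariance means discarding exactly the information the
constraint exploits — so the default remains the faithful, scale-robust
sequential recipe, and the simplex solver is the right tool for calibrated
or simulated data. The simplex solver is validated against an exhaustive
grid search over the simplex (10⁻² sweep with local refinement to 10⁻⁴) on
noisy mixtures: as an exact optimizer it matches the brute-force minimizer
to within the grid step.

sO₂ is computed per pixel as HbO₂/(HbO₂+Hb), undefined (NaN + mask) where
the hemoglobin sum is zero.

## ROI quantification

Organ outlines are simple polygons in 0-based pixel coordinates
((x, y) = (col, row), pixel centers at integer coordinates; the convention
is written into every annotation file). Rasterization uses an even-odd
crossing test at pixel centers. Per-organ means pool the union of ROI pixels
across frames (equivalently, pixel-count-weighted frame means — the identity
is tested), excluding degenerate pixels because their zeros are imputed, not
measured.

## Histology

Trichrome sections are separated with the Ruifrok–Johnston optical-density
method: OD = −log₁₀(I/255) per RGB channel, expressed in a basis of
unit-length stain vectors (the Fiji Masson-trichrome pair — aniline-blue
collagen and Ponceau-fuchsin cytoplasm — completed by the normalized cross
product), then clipped at zero. Tissue is everything whose summed OD exceeds
0.05 (white-background exclusion). The collagen measurement is the fraction
of tissue pixels whose blue-stain density exceeds a threshold: Otsu's method
within the tissue by default, with two guards chosen once — if the in-tissue
dynamic range is below 0.15 OD the section is treated as single-class, and
the single-class positive call requires density above 0.10 OD (safely above
8-bit quantization noise, below any real stain density). A fixed-value
threshold mode is available. Calibration against sPA means is ordinary least
squares of mean collagen a.u. on area fraction over (animal, organ)-matched
pairs, with the two-sided slope t-test on n−2 df.

## Cohort statistics

The statistical layer wraps standard implementations (scipy, statsmodels)
behind typed result objects and is validated in the tests against hand-coded
closed-form oracles (pooled-variance t formula, textbook balanced two-way
sums-of-squares decomposition, closed-form simple-regression inference):

* unpaired t-tests, Student's pooled-variance by default (the generic
  "unpaired t-test"), Welch by flag;
* two-way factorial ANOVA, Type II sums of squares by default (the designs
  of interest are balanced, where Types I/II/III coincide — tested; Type III
  is computed under sum-to-zero contrasts, the only coding under which it is
  meaningful);
* per-organ, per-group OLS age regressions.

`run_study_tables` runs the battery: per-organ normal-vs-prolapsed t-tests
on the age-matched slice (ages 4–8 months inclusive), per-group age
regressions across the full age range, the prolapse × organ ANOVA on the
age-matched slice, and age-binned (4-month bins, additive model) ANOVAs of
age with prolapse and with organ. Whether age should enter binned or as a
continuous covariate is genuinely open; both are exposed (`run_study_tables`
bins; `age_ancova` treats age continuously). Raw p-values are reported
per organ without multiple-testing correction, matching the per-organ
reporting style this pipeline supports; a Holm helper exists for users who
want family-wise control. Regressions are fitted separately per genotype
group by default (pooling is the caller's choice of slice).

## Synthetic data

The generators define the package's verifiable test bed; all are
deterministic given their seed.

* **Phantoms.** Four labeled polygonal regions (named after the organ
  cross-sections, with collagen fractions 0.15 / 0.30 / 0.45 / 0.44 ordered
  uterus < internal os < external os ≈ vagina — a documented fixture, not a
  claim about real tissue) rendered through the forward model at true
  fluences 18/24/20/16/14 mJ·cm⁻² (highest at 750 nm, as OPO output
  typically is), with additive Gaussian intensity noise truncated at zero.
  The noise model is the standard desk-scale stand-in; no claim about real
  photoacoustic noise statistics is implied. The pulse-energy log jitters
  each pulse by ±5 % multiplicatively and recenters the jitter so the
  scan-mean fluence equals the truth exactly, exercising the mean-fluence
  path without biasing it.
* **Histology.** An elliptical tissue footprint stained with cytoplasm
  density 0.7 everywhere and collagen-blue density 0.8 on an exactly
  counted random subset of pixels, rendered through Beer–Lambert with the
  default stain vectors and quantized to 8 bits. Truth masks are returned.
* **Cohorts.** Animal × organ tables with response = organ baseline
  (+ optional prolapsed-group shift) + group-and-organ-specific age slope ×
  age + shared per-animal effect + residual. Defaults (8 animals per group,
  ages uniform on 2–12 months, baselines 150–320 a.u., slopes +10…+40
  a.u./month in the normal group and −5…−20 in the prolapsed group, steepest
  in the external os; between-animal σ = 40, residual σ = 55 a.u.) emulate a
  two-genotype aging study in which collagen rises with age in normal
  animals and falls in prolapsed ones, with roughly two-thirds of the
  external-os variance explained by age.

What the generators do **not** emulate: acoustic propagation and the probe's
point-spread function, speckle, depth-dependent fluence (all images are
treated as already beamformed and uniformly illuminated), stain variability
and sectioning artifacts (tears/folds are handled as manifest-level
exclusion flags, not simulated), and any real-tissue concentration values.
Passing tests therefore demonstrate the correctness of the algorithms under
the stated model, not the accuracy of the model for real tissue.

## Problem sizes and numerical tolerances

The suite's simulation sizes are chosen as the smallest that make each
property sharp: the end-to-end noiseless identity runs a 10-frame 128×128
phantom (tolerance 10⁻⁶ a.u., i.e. 10⁻⁹ relative, achievable because the
pipeline is linear-algebraic in float64); oracle equivalence uses 1000 noisy
pixels against the refined grid; noisy recovery uses 10⁴ pixels at 20 dB
SNR; the ANOVA null calibration uses 2000 simulated balanced 2×2 tables
(acceptance band 3–7 % rejections at α = 0.05); closed-form statistical
oracles are matched to 10⁻¹⁰. Degenerate inputs (all-zero pixels, constant
spectra, empty ROIs and masks, saturated or empty designs) raise typed
errors rather than producing silent zeros, with the single documented
exception of degenerate *pixels*, which are zero-filled and flagged.

## Known limitations

* Only three chromophores: elastin (spectrally near-identical to collagen in
  NIR-I) and collagen subtypes are not separable with this design and are
  out of scope; water/lipid channels (NIR-II approaches) likewise.
* The collagen spectrum is a synthetic stand-in; absolute molar
  absorptivities are not reproduced, only the feature geometry that the
  wavelength selection and normalization actually use.
* The collagen–Hb quasi-collinearity bounds noise robustness (condition
  number ≈ 6.4); quantitative per-pixel estimates at low SNR should be
  interpreted with the solver trade-off above in mind.
* No depth-dependent fluence correction: valid for ex-vivo-style, uniformly
  illuminated scenes; in-vivo use would require a fluence model.
* The statistics treat each animal × organ mean as one observation (no
  mixed-effects modeling of repeated organs within animal).
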