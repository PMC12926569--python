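# spacol — spectral photoacoustic collagen quantification

Collagen content in soft tissue is a marker of reproductive health: altered
collagen with age is a risk factor for disorders such as pelvic organ
prolapse, yet quantifying it today requires a biopsy. Ultrasound-guided
spectral photoacoustic (sPA) imaging offers a non-invasive alternative:
photoacoustic images acquired at several NIR-I wavelengths can be decomposed
per pixel into the contributions of the tissue's light-absorbing species.

`spacol` implements that analysis end to end for the three-chromophore NIR-I
problem — collagen, oxygenated hemoglobin (HbO₂) and deoxygenated hemoglobin
(Hb) — as a tested, reusable Python library with a thin CLI. It is aimed at
photoacoustic-imaging researchers who want a reference implementation of the
unmixing-and-quantification pipeline and a synthetic test bed with known
ground truth.

## The model

After normalizing each image by the mean laser fluence of its wavelength
(Φ(λ) = pulse energy / 0.51 cm² focal-spot area, averaged over the scan),
each pixel's intensity vector across the W = 5 imaging wavelengths
{690, 750, 850, 910, 940} nm is modeled as a linear mixture

&nbsp;&nbsp;&nbsp;&nbsp; I(λ) = k · Σ_c ε̃_c(λ) · c_c ,&nbsp;&nbsp; c_c ≥ 0,&nbsp; Σ_c c_c = 1,

where ε̃_c is the chromophore's molar absorptivity min-max normalized to
[0, 1] over 650–1000 nm (hemoglobin absorbs orders of magnitude more strongly
than collagen; normalization lets the solver weight all three equally), c_c
are relative concentrations and k is an arbitrary global scale (Grüneisen
factor and system gain, absorbed into arbitrary units). The five wavelengths
target features of the collagen spectrum: its NIR-I absorption maximum
(690 nm), the peak laser output (750 nm), a local minimum (~850 nm), a local
maximum (~910 nm) and a local minimum (~940 nm).

The default solver follows the classic sequential recipe — ordinary least
squares, negative concentrations replaced by 0, renormalization to sum 1 —
and is exactly scale-invariant. An exact simplex-constrained least-squares
solver and an NNLS variant are provided as alternatives (see
`docs/methods.md` for when each is appropriate). Outputs are rescaled so
that **1000 a.u. = relative concentration 1**, and an sO₂ =
HbO₂/(HbO₂+Hb) map comes for free.

Downstream, the library rasterizes per-frame organ ROIs (uterus, internal
and external cervical os, vagina), pools per-organ collagen means, measures
collagen area fractions in Masson's-trichrome histology via
Ruifrok–Johnston color deconvolution, calibrates sPA estimates against
histology by OLS, and runs the cohort statistics (unpaired t-tests, two-way
ANOVAs, age regressions). A synthetic-data module generates phantoms,
trichrome-like sections and cohorts with known ground truth for all of it.

## Worked example

Simulate a noisy four-organ phantom, run the full pipeline, and compare the
recovered per-organ collagen concentrations with the ground truth:

```python
import numpy as np
from spacol import (default_design_matrix, default_phantom_spec, generate_phantom,
                    mean_fluence, fluence_normalize, unmix_stack, organ_mean,
                    so2_map, ORGANS)

design = default_design_matrix()
print(f"design matrix: {design.matrix.shape[0]} wavelengths x "
      f"{design.matrix.shape[1]} chromophores, condition number {design.condition_number:.2f}")

spec = default_phantom_spec((64, 64), n_frames=4, noise_sigma=0.4, seed=17)
stack, truth, pulses, rois = generate_phantom(spec, design)

fluences = mean_fluence(pulses, stack.config)
conc = unmix_stack(fluence_normalize(stack, fluences), design)

for organ in ORGANS:
    est = organ_mean(conc, rois, organ, "demo")
    true = organ_mean(truth, rois, organ, "demo")
    print(f"{organ:12s} collagen {est.mean_collagen_au:6.1f} a.u. "
          f"(truth {true.mean_collagen_au:6.1f}, n={est.n_pixels} px)")

so2 = so2_map(conc)
print(f"mean sO2 over tissue: {so2.mean_so2():.3f}")
```

prints

```
design matrix: 5 wavelengths x 3 chromophores, condition number 6.43
uterus       collagen  150.5 a.u. (truth  150.0, n=2304 px)
internal_os  collagen  300.8 a.u. (truth  300.0, n=2304 px)
external_os  collagen  451.4 a.u. (truth  450.0, n=2304 px)
vagina       collagen  442.2 a.u. (truth  440.0, n=2304 px)
mean sO2 over tissue: 0.430
```

Each phantom region was simulated with a prescribed collagen fraction
(0.15 / 0.30 / 0.45 / 0.44 of total chromophore content, i.e. 150–450 a.u.);
at this noise level the pipeline recovers every organ mean to within a few
a.u. The same steps are available from the shell:

```bash
spacol simulate phantom --out sim --size 64 --frames 4 --seed 17
spacol preprocess --stack sim/stack --energy-log sim/pulses.csv --out norm
spacol quantify --stack norm --rois sim/rois.json --animal M07 --out summaries.csv
```

plus `spacol spectra`, `spacol histology`, `spacol calibrate`, `spacol stats`
and the other `spacol simulate` subcommands for the rest of the pipeline.

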