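# ramanheal

Quantitative assessment of diabetic wound healing from in vivo skin Raman
spectra.

Delayed wound healing is one of the hard clinical problems of diabetes, and
judging how well a wound is healing — for example under low-dose
photodynamic therapy (LDPDT) with 5-aminolevulinic acid or methylene blue —
usually relies on caliper measurements and visual inspection. Raman
spectroscopy offers a noninvasive alternative: the spectrum of skin encodes
its biochemistry, and collagen deposition (the hallmark of proper healing)
shows up directly in the vibrational bands. This package turns point Raman
spectra of wounded and healthy skin into two quantitative healing read-outs,
for spectroscopists and biomedical researchers running longitudinal wound
studies.

## The method

**Preprocessing.** Tissue spectra sit on a broad autofluorescence
background. It is removed by an iterative peak-suppressing polynomial fit of
order 18 (fit, clip the signal to the curve, refit, then refit once more on
the identified baseline channels), performed in a Chebyshev basis on the
wavenumber axis rescaled to [−1, 1]. Spectra containing cosmic-ray spikes —
deviations from a 5-point running median beyond 8 robust SDs — are
discarded, and the rest are vector-normalized.

**Collagen index.** In the 1380–1750 cm⁻¹ window, the amide I band
(~1658 cm⁻¹, dominated by collagen type I) and the CH₂ bending band
(~1445 cm⁻¹, total dermal matrix protein) are deconvolved as Gaussians over
a local linear baseline, and the band-areas ratio

&nbsp;&nbsp;&nbsp;&nbsp;*R* = A₁₆₅₈ / A₁₄₄₅,&nbsp;&nbsp;A = a·σ·√(2π)

is a relative collagen-content index: larger *R* means more collagen, i.e.
better healing. Group cells are compared with a pooled two-sample Student's
*t*-test at α = 0.05.

**Healing distance.** PCA is fitted to all spectra in the CH-stretch region
(2800–3000 cm⁻¹, pooled over wound groups and healthy skin). In the PC2–PC3
plane, coordinates are rescaled by the healthy group's score SDs so the
healthy radius r = √(σ₂′² + σ₃′²) = √2. The healing distance of a wound
set S against the healthy set S_H is the grand mean of the Mahalanobis
quadratic form

&nbsp;&nbsp;&nbsp;&nbsp;d_M(x_i, x_j) = (x_i − x_j)ᵀ C⁻¹ (x_i − x_j),

with C the covariance of the scaled healthy coordinates — first averaged
over S_H per wound spectrum, then over S. Healing drives this distance down
toward the healthy self-distance baseline.

**Wound morphometry.** Caliper diameters give the elliptical area
S = A·B·π/4 and the closure percentage [(S₀ − S)/S₀]·100; CW light doses
scale linearly with exposure time (4 J/cm² at the irradiance of
1 J/cm² in 3 min 45 s takes 15 min).

Because no animal data ships with the package, a first-class synthetic-data
module generates cohorts with the same acquisition design (5 groups ×
4 days × 3 mice × 10 points + 30 healthy spectra per group = 750 spectra),
a skin band library, a smooth fluorescence background, channel noise,
cosmic spikes, and per-(group, day) healing trajectories — with every true
generating parameter recorded, so the whole pipeline is testable against
ground truth.

## Worked example

```python
import ramanheal as rh

cohort = rh.generate_cohort(rh.SyntheticConfig(seed=1))   # 750 spectra
processed, qc = rh.preprocess_set(cohort)                 # baseline, spikes, norm
dt = rh.distance_table(processed, rng_lohi=(2800.0, 3000.0))
print(dt.table.round(1))
```

prints

```
         day 1  day 3  day 7  day 14
ALA1      75.7   56.5   31.4    11.5
ALA4      57.4   30.0   11.1     4.5
MB1       69.8   55.2   31.3    12.1
MB4       59.7   32.0   18.2     6.5
control   83.7   70.4   59.9    62.3
```

Each entry is the mean Mahalanobis quadratic form between that group's
spectra on that day and the healthy-skin reference in the scaled PC2–PC3
plane. All treated arms converge toward healthy skin by day 14 — fastest
for 5-ALA at 4 J/cm² — while the untreated diabetic control stays far away:
the signature of impaired healing the method is designed to expose.

The `examples/` directory holds one short script per capability
(simulation, preprocessing, collagen index, healing distance, morphometry);
each prints the numbers it computes and what they mean. A thin CLI wraps
the same stages:

```sh
ramanheal all --seed 1 --out results_dir     # simulate -> report bundle
ramanheal --help                             # individual stage verbs
```

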