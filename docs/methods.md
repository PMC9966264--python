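# Methods

This note documents the models, parameters and numerical choices behind
`ramanheal`, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Signal model and preprocessing

A measured skin spectrum is treated as

    y(ν) = Σ_k a_k exp(−(ν − μ_k)² / 2σ_k²) + b(ν) + ε(ν) + spike,

Gaussian vibrational bands on a smooth autofluorescence background b(ν)
with i.i.d. channel noise ε and occasional single-channel cosmic spikes.
Wavenumbers ν are physical cm⁻¹ throughout (never channel indices), range
selections are closed intervals, and the working grid is 1 cm⁻¹ over
100–3500 cm⁻¹, matching a dispersive instrument with ~1 cm⁻¹ resolution.

**Baseline.** The background is estimated by the classic iterative
clip-to-curve polynomial fit of order 18: fit, clip intensities above the
fitted curve to the curve, refit; stop when the maximum coefficient change
falls below 1e-8 relative to the coefficient scale, or after 100
iterations. Two numerical points matter:

* The fit runs in a Chebyshev basis on the axis rescaled to [−1, 1]; raw
  cm⁻¹ powers overflow double precision at order 18.
* The clip iteration converges toward the *lower envelope* of the signal,
  not the background: left alone it drifts a fraction of the noise SD below
  the true baseline and, worse, acquires curvature between bands. We
  therefore use the iteration only to identify baseline channels (residual
  above the curve within the median + 3 robust SDs) and refit the
  polynomial on those channels by plain least squares. On noiseless
  synthetic input this recovers a polynomial background exactly; with noise
  it leaves only a roughly constant offset that downstream local baselines
  absorb. At the strict default tolerance the clip phase typically runs to
  the iteration cap; this is recorded in the QC table as a flag, not an
  error, and the mask refit makes the result insensitive to the exact
  stopping point.

**Cosmic spikes.** A spectrum is discarded (not repaired) when any
channel's deviation from a 5-point running median exceeds k = 8 robust
standard deviations, with the robust SD the MAD-based estimate 1.4826·MAD
of all deviations. The threshold is expressed in robust SDs rather than raw
MAD units because the deviation statistic has heavy tails in MAD units:
over ~3400 channels a raw 8·MAD cut flags the majority of clean spectra,
while 8 robust SDs keeps the false-flag rate well under 1% and still
catches spikes orders of magnitude larger. A constant spectrum (MAD = 0) is
never flagged. Discarding at spectrum granularity reflects how operators
handle spike-contaminated accumulations during acquisition.

**Normalization.** Vector (L2) normalization is the default: it is
scale-free, preserves band-area ratios, and needs no band choice. Per-band
and total-area variants sit behind a flag. Normalization is applied after
baseline subtraction (the order is configurable); applied before, the
background magnitude would leak into the normalization constant.

## Collagen index

The 1380–1750 cm⁻¹ window is modelled as a local linear baseline plus one
Gaussian per band of interest — CH₂ bending near 1445 cm⁻¹ and amide I near
1658 cm⁻¹. Two components are the minimal model for the ratio; an optional
third near 1585 cm⁻¹ can be added through `init_centers` for spectra with a
pronounced shoulder. Bounds and initial values are fixed (centers within
±15 cm⁻¹ of nominal, σ ∈ [2, 60] cm⁻¹, amplitudes ≥ 0, σ₀ = 10 cm⁻¹,
amplitude from the local maximum) and there are no stochastic restarts, so
the fit is deterministic. The window is rescaled by its maximum before
optimization; as a result the fitted ratio is exactly invariant under
positive rescaling of the input rather than merely approximately so. Band
areas use the closed form A = a·σ·√(2π), and the index is the ratio of
*fitted Gaussian* areas (raw window integration can be done through
`numpy.trapezoid` as a cross-check but is not the reported quantity, since
it mixes in neighboring-band tails and residual background).

Group comparisons use the classic pooled-variance two-sided Student's
t-test at α = 0.05 (Welch variant behind a flag). Degenerate inputs are
defined explicitly: identical constant samples give t = 0, p = 1; zero
variance with unequal means raises.

## Healing distance

PCA (mean-centered, no variance scaling) is fitted **once, pooled over all
spectra** — wound groups and healthy — in the chosen sub-range, so that all
(group, day) cells share one coordinate system and their distances are
comparable; per-group slicing happens on the scores. The CH-stretch window
2800–3000 cm⁻¹ is the default because the protein/lipid –CH profile
separates wound states best; the other fingerprint sub-ranges (600–800,
1020–1140, 1200–1370, 1390–1500, 1570–1750, 1200–1750 cm⁻¹) are accepted as
alternatives. Loadings follow a deterministic sign convention (largest
magnitude element positive). Component indices are 1-based: PC2 and PC3 are
the 2nd and 3rd components.

The PC2–PC3 plane is rescaled per axis by the reciprocal healthy score SDs,
which makes the healthy radius √(σ₂′² + σ₃′²) = √2 identically; the
covariance C of the healthy reference is computed *after* this scaling
(n − 1 denominator). If C is near-singular (condition number > 1e10) a
ridge of 1e-8·trace(C)/2 is added to the diagonal, and the regularization
is recorded in the result — healthy clusters of a few dozen points can be
nearly collinear in unlucky synthetic draws.

The pairwise statistic is the quadratic form dᵀC⁻¹d **without a square
root** — the squared-Mahalanobis convention — because that is the printed
definition this pipeline standardizes on; a square-root variant is
available behind a flag but changes only the scale, not any ordering. Set
distances are plain arithmetic means: per wound spectrum over the healthy
set, then over the wound set, which equals the grand mean over all pairs.
Note that the self-distance of the healthy set is not zero (it is the mean
pairwise spread, ≈ 2·dim for a unit-covariance cloud); distances should be
read against that baseline, not against zero.

## Synthetic cohorts

The generator reproduces the acquisition design of the target study: five
wound groups (untreated diabetic control; 5-ALA and methylene blue at 1 and
4 J/cm²) × days {1, 3, 7, 14} × 3 mice × 10 points, plus 30 healthy-skin
spectra per group — 750 spectra, 120 wound spectra per group. The band
library covers the standard skin assignments (755, 854, 877, 936, 1003,
1080, 1247, 1270, 1445, 1658, 2862, 2886, 2923 cm⁻¹).

Healing state enters in two places:

* the target 1658/1445 area ratio per (group, day): treated groups rise
  from ~0.70 toward the healthy 1.0 by day 14 (4 J/cm² arms fastest),
  the control decays from 0.70 to 0.64 — impaired collagen deposition;
* an additive CH-stretch perturbation along a fixed band-amplitude
  direction, large (≈25 a.u.) on day 1 and decaying toward zero for treated
  groups while staying ≈18 for the control.

Biological variability is explicit and recorded as ground truth: per-mouse
random effects (SD 2 a.u. along the healing direction, 2% on the ratio),
per-spectrum within-wound jitter (SD 2 a.u.), a group-independent
lipid/protein nuisance contrast (SD 15 a.u.) chosen roughly orthogonal to
the healing direction, and 3% amplitude jitter on the CH₂ band. The
nuisance contrast intentionally dominates pooled variance so the healing
signal lands in PC2/PC3 rather than PC1, as it does in real skin where the
leading component captures global composition variability. The fluorescence
background is an order-5 polynomial — deliberately far below the order-18
corrector so that recovery is well-posed. Channel noise is additive
Gaussian with SD 5 a.u. against a CH₂ amplitude of 100, i.e. band SNR ≈ 20;
no SNR is stated for the target instrument, so this value is an explicit
convention of the generator, not a measurement. Cosmic spikes are
single-channel positive excursions of 500 a.u. at 2% probability per
spectrum.

With zero channel noise and zero spike rate a generated spectrum equals the
Gaussian band sum at its recorded true amplitudes plus the background,
exactly — the biological jitters are part of the truth record, not of the
noise. Identical configuration (including seed) reproduces a cohort
bitwise. Wound caliper records are generated alongside: circular 5 mm
day-0 wounds shrinking by group-specific closure fractions (control 60% by
day 14, 4 J/cm² arms ≥ 93%) with 5% multiplicative noise.

**What the generator does not emulate:** Poisson/shot noise and detector
response, photobleaching dynamics, band-center shifts with healing state
(amplitudes only, by default), correlated baselines across points of one
wound, and any real tissue heterogeneity beyond the Gaussian random effects
above. Passing recovery tests therefore demonstrates that the pipeline's
estimators are correct and well-calibrated under this model — not that the
biological effect sizes in real diabetic wounds are as large or as clean.

## Problem sizes and determinism

The test suite runs most checks on a reduced design (2 groups × 2 days ×
1 mouse × 3 points + 6 healthy per group) and reserves the full 750-spectrum
design for the end-to-end recovery checks: per-cell collagen-ratio recovery
on one noiseless and one default-noise cohort, and healing-ordering
recovery across 20 seeded full cohorts. The acceptance script uses the same
sizes; a full cohort runs through preprocessing and the distance table in a
few seconds, and through per-spectrum band fitting in about ten. Every
random draw flows from a single `numpy.random.Generator` seeded explicitly,
and fixed inputs produce bitwise-identical tables across runs.

## Known limitations

* The order-18 baseline leaves small curvature residuals between bands;
  the collagen ratio absorbs most of this through the local linear term,
  with a residual per-cell bias below ~0.5% (noiseless) in tests.
* `fit_bands` with heavily overlapping extra bands inside the window would
  need the optional third component; the two-component default assumes the
  1380–1750 cm⁻¹ region is dominated by CH₂ and amide I, which holds for
  skin but not for every tissue.
* The distance table is only defined when the cohort contains healthy
  spectra; there is no fallback reference.
* Proprietary vendor file formats are out of scope; I/O is two-column text
  per spectrum and long-form CSV per cohort.
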