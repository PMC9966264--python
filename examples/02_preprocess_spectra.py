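"""Remove the autofluorescence background and reject cosmic spikes.

Runs the preprocessing stage on a small synthetic cohort: order-18
iterative polynomial baseline, spike rejection at 8 robust SDs, vector
normalization. Prints the QC summary a practitioner would check first.
"""

import numpy as np

import ramanheal as rh

cfg = rh.SyntheticConfig(
    seed=7,
    design=rh.CohortDesign(groups=("control",), days=(1,), mice=2, points=10,
                           healthy_per_group=10),
)
cohort = rh.generate_cohort(cfg)
processed, qc = rh.preprocess_set(cohort)

print(f"input spectra:        {len(cohort)}")
print(f"cosmic spikes dropped: {int(qc['cosmic_spike'].sum())}")
print(f"baseline iterations:   median {int(qc['baseline_iterations'].median())} "
      f"(clip iterations before the band-free refit)")
print(f"output norm check:     ||spectrum|| = "
      f"{np.linalg.norm(processed.matrix[0]):.6f} (vector normalization)")

# a single spectrum, the long way around
s = next(cohort.spectra())
baseline = rh.fit_baseline(s, order=18)
corrected = rh.subtract_baseline(s, baseline)
free = (s.wavenumbers > 1850) & (s.wavenumbers < 2650)  # band-free region
print(f"\nresidual on band-free channels after subtraction: "
      f"mean {corrected.intensities[free].mean():+.3f} a.u. "
      f"(noise sd = {cfg.noise_sd})")
print("A mean near zero shows the background is removed without biasing "
      "the Raman bands.")
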