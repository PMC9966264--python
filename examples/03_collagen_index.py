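"""Collagen index: Gaussian deconvolution of the 1658/1445 cm^-1 bands.

Fits amide I (collagen) and CH2 bending (total matrix protein) Gaussians
in the 1380-1750 cm^-1 window of every preprocessed spectrum and tabulates
the band-areas ratio per group and day. Rising values mean collagen is
being deposited — the wound is healing.
"""

import ramanheal as rh

cfg = rh.SyntheticConfig(
    seed=5,
    design=rh.CohortDesign(groups=("control", "ALA4"), days=(1, 14),
                           mice=2, points=5, healthy_per_group=10),
)
cohort, truth = rh.generate_cohort_with_truth(cfg)
processed, _ = rh.preprocess_set(cohort)

table = rh.ratio_table(processed)
print("collagen index (1658/1445 band-areas ratio), mean ± SD:\n")
for r in table.itertuples():
    healthy = r.group == "healthy"
    day = "        " if healthy else f"day {int(r.day):>2}"
    print(f"  {r.group:>8} {day}:  {r.mean_ratio:.3f} ± {r.sd_ratio:.3f}  (n={r.n})")

target = truth.groupby("group")["true_ratio"].mean()
print(f"\ngenerator truth, healthy cell: {target['healthy']:.3f}")
print("The treated group's day-14 cell approaches the healthy value while "
      "the control drifts away — impaired collagen deposition.")
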