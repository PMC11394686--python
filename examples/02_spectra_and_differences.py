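"""Condition recordings and compute band powers and walk-rest differences.

Runs the full spectral pass: 0.5-80 Hz zero-phase filtering, earliest
artifact-free 10 s segment per state, 1 s epochs, Welch spectra, band
integration over delta/theta/alpha/beta/gamma, and the per-subject
walking-minus-resting power difference that is the study's headline
statistic.
"""

import lfpbands as lb

spec = lb.calibration_spec(seed=0, band_effects=lb.recovery_band_effects())
recordings, truth = lb.generate_lfp_dataset(spec)
band_table, diff_table, spectra = lb.build_band_power_table(recordings)

print(f"band-power table: {len(band_table)} rows "
      "(subjects x regions x states x bands)")
print(f"difference table: {len(diff_table)} rows\n")

gamma = diff_table[diff_table.band == "gamma"]
print("mean gamma walk-rest difference (uV^2) per group and region:")
print(gamma.pivot_table(index="group", columns="region", values="diff").round(2))
print("\nPositive values mean more gamma power while walking. The lesion rows")
print("exceed sham everywhere except CPu, mirroring the injected ground truth.")
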