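# lfpbands

Movement-state band-power analysis of multi-region local field potential
(LFP) recordings, built for the hemiparkinsonian (unilateral 6-OHDA) mouse
design: two groups (sham vs lesion), five recorded regions (M1, CPu, STN,
SNc, PPN), and two behavioral states (resting vs walking) per animal.

The package is for systems-neuroscience and biostatistics users who want a
tested, reproducible implementation of this analysis chain — from raw
signal conditioning to the final ANOVA report — plus a synthetic-data
generator with known ground truth, so every stage can be validated by
parameter recovery rather than by eyeballing.

## What it computes

1. **Signal conditioning** — zero-phase 4th-order Butterworth band-pass
   (0.5–80 Hz), earliest artifact-free 10 s segment per behavioral state
   (default rule: |x − median| > 6 robust SD), cut into 1 s epochs.
2. **Spectra and band power** — Welch PSD with the 1 s epochs as Hann-windowed
   segments (1 Hz resolution); band power is the integral of the one-sided
   density over delta [1,4), theta [4,8), alpha [8,21), beta [21,32),
   gamma [32,100) Hz.
3. **The difference statistic** — per subject × region × band,
   Δ = P(walk) − P(rest) in absolute power (µV²): the transient
   movement-related change in oscillatory power.
4. **Split-plot repeated-measures ANOVA** on Δ, one per band, with group as
   the between-subject factor and region ("channel") as the within-subject
   factor. Sphericity is tested with Mauchly's W on the pooled within-group
   covariance; on violation (α = 0.05) the Greenhouse–Geisser
   ε = (Σλ)² / ((k−1) Σλ²) multiplies the within-effect degrees of freedom.
   Effect sizes are partial η² = F·df₁ / (F·df₁ + df₂). Post hoc contrasts
   are Fisher's LSD on the ANOVA's pooled error mean square, compressed into
   ordering strings such as `PPN/SNc/STN > M1`.
5. **Behavioral and histology endpoints** — cylinder asymmetry ratio
   (inj − non-inj)/(inj + non-inj + both) × 100, gait support percentages,
   rotarod/beam/pole/open-field summaries, and TH⁺ neuron density
   (cells/mm², mean over slices) with percent loss vs sham. Two-group tests
   follow a fixed cascade: Shapiro–Wilk + Levene; log then sqrt transform on
   violation; pooled-variance t if assumptions hold, else Mann–Whitney U
   (p < 0.05 significant, 0.05 ≤ p < 0.1 marginal).

The synthetic generator produces all three data types with known ground
truth: 1/f^β pink-noise background plus band-limited oscillations whose RMS
depends on (group, state, region, band), lognormal between-subject
variability, and matching behavior and cell-count tables.

## Worked example

```bash
python examples/03_anova_table.py
```

generates a reduced cohort (2 × 10 mice, 20 s per state at 250 Hz) with a
lesion-specific walking gamma injection in M1/STN/SNc/PPN, runs the whole
pipeline, and prints the per-band ANOVA table. The closing lines read:

```
gamma group effect: F(1,18) = 5.258, p = 0.034, partial eta^2 = 0.226
sphericity: Mauchly W = 0.235 (p = 0.005), GG epsilon = 0.616, correction applied: True
```

F(1,18) is the between-subject group effect at n = 10 per group (df₂ =
N − g = 18): the lesion group's walking gamma increase is recovered as
significant, with partial η² = 0.226 of effect-plus-error variance
attributable to group. Mauchly's p < 0.05 means the region covariance is
non-spherical, so within-subject p values in the printed table are
Greenhouse–Geisser corrected. Other examples cover the generator ground
truth (`01`), the band-power/difference tables (`02`), and the behavioral
and histology endpoints (`04`).

The same pipeline runs from the shell:

```bash
lfpbands run-all --config examples/demo_config.yaml --out out/ --seed 0
```

writes `band_power.csv`, `diff.csv`, `anova_table.csv` (15 rows: 5 bands ×
group/channel/interaction), `spectra.csv`, endpoint and histology
summaries, and a `manifest.json` recording the seed and every analysis
decision.

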