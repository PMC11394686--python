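# Methods

This note documents the models, estimators, and design choices behind
`lfpbands`, in the order data flows through the package.

## Synthetic data model

Each recording is one subject's five-region LFP with one contiguous
resting block followed by one walking block (default 300 s each at
1000 Hz, matching a two-phase rotarod session). A region's trace is

    x(t) = background(t) + Σ_bands oscillation_b(t) · 1[state active]

- **Background**: Gaussian noise with power spectral density ∝ 1/f^β,
  synthesized in the frequency domain and rescaled to an exact RMS
  (default β = 1, RMS 20 µV). Pink noise is the canonical broadband LFP
  background; β is configurable because real recordings vary between
  roughly white (β ≈ 0) and Brownian (β ≈ 2).
- **Oscillations**: random-phase sinusoids whose instantaneous frequency is
  redrawn uniformly within ±0.5 Hz of the band's synthesis frequency every
  second (phase-continuous). This is the simplest narrow-band process whose
  injected band power is analytically known (RMS² = a², since the signal is
  rescaled to exact RMS) while avoiding a zero-width spectral line.
  Synthesis frequencies: delta 2.5, theta 6, alpha 14, beta 26, gamma
  40 Hz — all inside the 0.5–80 Hz acquisition passband.
- **Between-subject variability**: one lognormal multiplier per subject
  (σ = 0.2) scales every amplitude, keeping powers positive and inducing
  the positive within-subject covariance a repeated-measures design
  assumes.

Behavior tables draw endpoint values from Gaussian baselines (latency
200 ± 40 s, etc.) with lesion shifts expressed in SD units; cylinder
touches and gait frames are Poisson/multinomial counts. Cell-count tables
are Poisson counts around density × slice area with a prescribed loss
fraction on each side (defaults 0.8952 injection / 0.6121 non-injection).

**What the generator does not emulate**: non-stationary artifacts
(movement transients, electrode drift), cross-region coherence, burst-like
oscillation dynamics, and line noise. Passing recovery tests therefore
demonstrates correctness of the estimation chain under the stated
generative model, not robustness to every property of real recordings.

## Bundled effect presets

`demo_band_effects()` encodes the qualitative study pattern as injected
walking powers (µV², both groups) with lesion-specific excesses: gamma
carries the main lesion effect (+7 µV² in M1, STN, SNc, PPN; none in CPu),
and delta (SNc), theta (CPu, SNc), alpha (CPu), beta (STN) carry smaller
region-specific excesses. `recovery_band_effects()` is the gamma-only
subset used by the recovery experiment. The amplitudes were fixed by a
design-phase power calculation: the lesion excess corresponds to ≈1.6 SD
of between-subject noise in the subject-level gamma difference (so a
group effect is recoverable at n = 10 but not trivially so), and the
regional walking gradient (M1 0.5, CPu 6.75, STN/SNc/PPN 5.0 µV², i.e.
margins 4.0 / 6.25 / 8.5 µV² after averaging groups) places CPu midway
between M1 and the top tier so that only the tier-vs-M1 post hoc contrasts
are reliably significant — the ordering pattern the analysis should
recover.

## Signal conditioning

- **Filter**: 4th-order Butterworth 0.5–80 Hz, applied forward-backward
  (zero phase). Padding uses even reflection with length
  max(3·(2·order+1), 3·fs/f_low) samples: the 0.5 Hz corner has a ~2 s
  transient, and even reflection keeps the edge value continuous, bounding
  the transient an out-of-band component can inject (worst-case stopband
  leakage ≈ 0.8% in amplitude, vs ~16% with odd reflection).
- **Artifact rule**: a sample is an artifact when its deviation from the
  state-interval median exceeds k = 6 robust SDs (1.4826 × MAD, so large
  artifacts do not inflate their own threshold). A fully flat interval is
  rejected wholesale (rail saturation). Absolute-threshold and
  accept-everything rules are available.
- **Segment choice**: the earliest 10 s window inside the state interval
  with no flagged sample; an explicit error names subject/region/state
  when none exists. Contiguity of the segment is assumed.
- **Epoching**: consecutive non-overlapping 1 s epochs; a trailing partial
  epoch is dropped with a warning. The order is fixed — filter the full
  recording, then segment, then epoch — because per-epoch filtering would
  put an edge transient in every epoch.

## Spectral estimation

Welch's method with the 1 s epochs as segments: Hann window, mean removal
per epoch, no overlap (the epoching already defines the segmentation),
giving 1 Hz resolution and a one-sided density normalized so that
Σ psd·Δf equals the windowed variance. Band edges are half-open
[low, high), so shared edges are counted once and the five bands sum
exactly to the total over [1, 100) Hz. The gamma band keeps its printed
100 Hz upper edge even though the filter passband ends at 80 Hz; power in
80–100 Hz is whatever passes the filter skirt, and the run manifest flags
this. The difference statistic subtracts absolute power (µV²), not dB.

## Split-plot ANOVA

For each band, subject-level differences Δ_sr (s = subject, r = region)
are decomposed as a balanced split-plot: group tested against subjects
within groups (df = (g−1, N−g), i.e. (1,18) at n = 10); region and
group×region tested against the region×subject residual (df = (4,72)).
Mauchly's W is computed on the pooled within-group covariance of the k
region measures (error df N−g), the same matrix SPSS-style mixed GLMs
use — pooling without removing group means would count group effects as
covariance. When Mauchly rejects at α = 0.05, the Greenhouse–Geisser
ε — eigenvalue form on the doubly-centred covariance, clipped to
[1/(k−1), 1] — multiplies both within-effect dfs for the reported p; F
itself is never altered. Partial η² = F·df₁/(F·df₁+df₂) for every effect.

A note on the correction's monotonicity: the corrected p is not always
larger than the uncorrected p — for F < 1 (and marginally above 1 at very
small dfs) shrinking both dfs can lower the tail probability. What holds,
and what the tests assert, is the decision-level property: the correction
never turns a non-significant effect significant at α = 0.05.

**Fisher LSD**: all pairwise contrasts of marginal means using the
ANOVA's pooled error MS and df for the matching stratum (within error for
regions, between error for groups), two-sided, unadjusted. Ordering
strings render pairs with p < 0.05 when the omnibus effect is at least
marginal (p < 0.1 — the report convention keeps orderings for marginal
group effects); greater members sharing an identical set of lesser members
are merged, listed in the fixed region order PPN, SNc, STN, CPu, M1.
Region orderings pool marginal means across groups.

In replicated experiments the "modal ordering" is assembled from the
modal outcome of each pairwise contrast (significant in more than half the
replicates), not from the mode over whole strings — compound strings
fragment combinatorially while each contrast's modal outcome is stable.

## Two-group test cascade

Shapiro–Wilk per group and Levene (absolute deviations from group means)
across groups at α = 0.05; on violation the data are re-tested after log
(requires positivity) then square-root (requires non-negativity)
transforms; the pooled-variance t runs on the first passing scale, else
Mann–Whitney U on the original data with a tie-corrected,
continuity-corrected normal Z (exact p for small untied samples). The
cascade always returns a result for valid input (n ≥ 3 per group).
Significance classes: p < 0.05 significant, 0.05 ≤ p < 0.1 marginal.
Report tables round to 3 decimals, half away from zero.

## Problem sizes

The bundled demo runs the full study design (2×10 subjects, 5 regions,
two 300 s states at 1000 Hz; ~15 s on one CPU). Replicated experiments —
type-I calibration (1000 cohorts) and gamma recovery (50 cohorts) — use a
reduced per-cohort size of 20 s per state at 250 Hz, chosen so the full
10 s analysis segment per state is retained (the spectral estimates are
identical in distribution) while a thousand end-to-end replicates stay
inexpensive; 250 Hz still satisfies fs > 2 × 100 Hz.

## Known limitations

- The 8–21 Hz "alpha" and 21–32 Hz "beta" partitions are kept as the study
  defines them; they are nonstandard and results are not comparable to
  analyses using conventional rodent band edges without re-integration.
- Only two within/between factor designs are supported (no three-way
  layouts, no Huynh–Feldt correction, no multilevel models).
- EDF export is not provided (no writer backend among the dependencies);
  EDF reading requires the optional mne dependency. The native interchange
  format is one CSV per subject plus a JSON sidecar.
- Spectra are absolute power; no relative/normalized mode beyond the
  optional dB difference is offered.
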