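"""Synthetic data generator with known ground truth.

Emulates the study design the analysis assumes: two groups (sham vs
6-OHDA lesion) of ``n_per_group`` mice, five recorded regions (M1, CPu,
STN, SNc, PPN), and one contiguous resting block followed by one walking
block per recording.  Each region's trace is a 1/f^beta pink-noise
background plus band-limited oscillations whose RMS amplitude depends on
(group, state, region, band); a per-subject lognormal multiplier adds
between-animal variability.  The injected band powers are returned as a
ground-truth table so that the downstream spectral pipeline and ANOVA can
be tested for recovery.

Behavioral endpoint tables (rotarod, beam, pole, open field, cylinder,
gait) and TH+ cell-count tables with a prescribed dopaminergic-loss
fraction are generated alongside, with the same determinism contract:
identical seed and spec give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bands import BAND_CENTER_FREQS, BAND_NAMES

GROUPS = ("sham", "lesion")
STATES = ("rest", "walk")
DEFAULT_REGIONS = ("M1", "CPu", "STN", "SNc", "PPN")

#: key = (group, state, region, band) -> oscillation RMS amplitude (uV)
BandEffects = dict[tuple[str, str, str, str], float]


@dataclass
class SyntheticSpec:
    """Ground-truth parameters of a synthetic LFP dataset."""

    n_per_group: int = 10
    regions: tuple[str, ...] = DEFAULT_REGIONS
    fs: float = 1000.0
    state_duration_s: float = 300.0
    noise_exponent: float = 1.0
    noise_scale: float = 20.0
    band_effects: BandEffects = field(default_factory=dict)
    subject_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if len(set(self.regions)) != len(self.regions):
            raise ValueError("regions must be distinct")
        if self.fs <= 2 * 100.0:
            raise ValueError("fs must exceed twice the highest band edge (100 Hz)")
        if any(a < 0 for a in self.band_effects.values()):
            raise ValueError("oscillation amplitudes must be >= 0")
        for g, s, r, b in self.band_effects:
            if g not in GROUPS or s not in STATES:
                raise ValueError(f"unknown group/state in band_effects key {(g, s, r, b)}")
            if r not in self.regions:
                raise ValueError(f"band_effects references unknown region {r!r}")
            if b not in BAND_NAMES:
                raise ValueError(f"band_effects references unknown band {b!r}")


@dataclass
class LfpRecording:
    """One subject's multi-channel recording with state annotations."""

    subject_id: str
    group: str
    fs: float
    channels: dict[str, np.ndarray]  # region -> signal (uV)
    state_intervals: list[tuple[str, float, float]]  # (state, start_s, end_s)

    def __post_init__(self) -> None:
        lengths = {len(x) for x in self.channels.values()}
        if len(lengths) != 1:
            raise ValueError("all channel arrays must have equal length")
        dur = lengths.pop() / self.fs
        ivs = sorted(self.state_intervals, key=lambda iv: iv[1])
        for (s0, a0, b0), (s1, a1, b1) in zip(ivs, ivs[1:]):
            if b0 > a1:
                raise ValueError("state intervals overlap")
        for s, a, b in ivs:
            if a < 0 or b > dur + 1e-9:
                raise ValueError("state interval outside signal duration")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    def state_interval(self, state: str) -> tuple[float, float]:
        for s, a, b in self.state_intervals:
            if s == state:
                return a, b
        raise KeyError(f"recording {self.subject_id} has no {state!r} interval")


def generate_pink_noise(
    n_samples: int, fs: float, exponent: float, rms: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Zero-mean noise with power spectral density proportional to 1/f^exponent.

    Synthesized in the frequency domain: Gaussian Fourier coefficients scaled
    by f^(-exponent/2) (DC excluded), inverse-transformed, then rescaled so
    the empirical RMS equals ``rms`` exactly.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if fs <= 0:
        raise ValueError("fs must be positive")
    if rms < 0:
        raise ValueError("rms must be >= 0")
    if not 0 <= exponent <= 2:
        raise ValueError("exponent must be in [0, 2]")
    if rms == 0:
        return np.zeros(n_samples)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    coeff = amp * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    coeff[0] = 0.0
    x = np.fft.irfft(coeff, n=n_samples)
    x -= x.mean()
    return x * (rms / x.std())


def generate_oscillation(
    freq: float,
    rms: float,
    n_samples: int,
    fs: float,
    seed: int | np.random.Generator,
    jitter_hz: float = 0.5,
) -> np.ndarray:
    """Narrow-band oscillation: random-phase sinusoid with per-second frequency jitter.

    The instantaneous frequency is redrawn uniformly from freq +/- jitter_hz
    every second (phase-continuous), which keeps essentially all power within
    freq +/- 1 Hz while avoiding a zero-width spectral line.  The empirical
    RMS is scaled to equal ``rms`` exactly.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if not 0 < freq < fs / 2:
        raise ValueError(f"oscillation frequency {freq} Hz would alias at fs={fs} Hz")
    if rms < 0:
        raise ValueError("rms must be >= 0")
    if rms == 0:
        return np.zeros(n_samples)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    block = max(1, int(round(fs)))  # 1 s blocks
    n_blocks = int(np.ceil(n_samples / block))
    inst = np.repeat(freq + rng.uniform(-jitter_hz, jitter_hz, size=n_blocks), block)[:n_samples]
    phase = rng.uniform(0, 2 * np.pi) + 2 * np.pi * np.cumsum(inst) / fs
    x = np.sin(phase)
    x -= x.mean()
    return x * (rms / x.std())


def generate_lfp_dataset(spec: SyntheticSpec) -> tuple[list[LfpRecording], pd.DataFrame]:
    """Generate 2 x n_per_group recordings plus the injected-power ground truth.

    Each recording holds one rest block then one walk block of
    ``state_duration_s`` seconds.  The ground-truth table has one row per
    subject x region x state x band with the injected oscillation power
    (RMS**2, uV^2) after the subject-level multiplier, aligned with the rows
    of the band-power table the spectral pipeline will later produce.
    """
    rng = np.random.default_rng(spec.seed)
    n_state = int(round(spec.state_duration_s * spec.fs))
    n_total = 2 * n_state
    recordings: list[LfpRecording] = []
    truth_rows: list[dict] = []
    for group in GROUPS:
        for i in range(spec.n_per_group):
            subject = f"{group}{i + 1:02d}"
            mult = float(np.exp(rng.normal(0.0, spec.subject_sd)))
            channels: dict[str, np.ndarray] = {}
            for region in spec.regions:
                sig = generate_pink_noise(
                    n_total, spec.fs, spec.noise_exponent, spec.noise_scale * mult, rng
                )
                for si, state in enumerate(STATES):
                    sl = slice(si * n_state, (si + 1) * n_state)
                    for band in BAND_NAMES:
                        amp = spec.band_effects.get((group, state, region, band), 0.0) * mult
                        if amp > 0:
                            sig[sl] = sig[sl] + generate_oscillation(
                                BAND_CENTER_FREQS[band], amp, n_state, spec.fs, rng
                            )
                        truth_rows.append(
                            {
                                "subject": subject,
                                "group": group,
                                "region": region,
                                "state": state,
                                "band": band,
                                "injected_power": amp**2,
                            }
                        )
                channels[region] = sig
            recordings.append(
                LfpRecording(
                    subject_id=subject,
                    group=group,
                    fs=spec.fs,
                    channels=channels,
                    state_intervals=[
                        ("rest", 0.0, spec.state_duration_s),
                        ("walk", spec.state_duration_s, 2 * spec.state_duration_s),
                    ],
                )
            )
    return recordings, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Behavioral tables
# ---------------------------------------------------------------------------

#: endpoint -> (sham mean, within-group SD); units in the column name
BEHAVIOR_BASELINES: dict[str, tuple[float, float]] = {
    "rotarod_latency_s": (200.0, 40.0),
    "rotarod_speed_rpm": (30.0, 5.0),
    "rotarod_distance_cm": (1200.0, 250.0),
    "beam_time_s": (8.0, 2.0),
    "beam_hindlimb_errors": (1.5, 1.0),
    "pole_descent_s": (7.0, 2.0),
    "openfield_distance_cm": (2500.0, 500.0),
    "openfield_centre_entries": (12.0, 4.0),
    "openfield_centre_time_pct": (8.0, 3.0),
}

#: lesion-group shift in units of the sham SD, mirroring the qualitative
#: deficit pattern of the hemiparkinsonian model (shorter rotarod latency and
#: distance, more hindlimb errors, less centre time); endpoints reported as
#: unaffected get no shift.
DEFAULT_EFFECT_PROFILE: dict[str, float] = {
    "rotarod_latency_s": -1.0,
    "rotarod_distance_cm": -1.0,
    "beam_hindlimb_errors": 1.0,
    "openfield_centre_time_pct": -1.0,
    "cylinder_bias": 0.3,
    "gait_shift": 0.10,
}

GAIT_CLASSES = ("diagonal", "three_limb", "other")
_SHAM_GAIT_P = np.array([0.55, 0.25, 0.20])
_CYLINDER_RATES = {"injection": 10.0, "non_injection": 10.0, "both": 8.0}
_N_GAIT_FRAMES = 500


def generate_behavior_dataset(
    n_per_group: int,
    effect_profile: dict[str, float] | None = None,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Per-subject behavioral tables with group shifts from ``effect_profile``.

    Returns ``{"endpoints": ..., "cylinder": ..., "gait": ...}``.  Endpoint
    values are truncated at zero (times, counts, distances cannot be
    negative).  ``cylinder_bias`` moves a fraction of the lesion group's
    single-forelimb touch rate toward the injection side; ``gait_shift``
    moves probability mass from diagonal to three-limb support.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    profile = DEFAULT_EFFECT_PROFILE if effect_profile is None else effect_profile
    if any(not np.isfinite(v) for v in profile.values()):
        raise ValueError("effect_profile values must be finite")
    rng = np.random.default_rng(seed)

    endpoint_rows, cylinder_rows, gait_rows = [], [], []
    for group in GROUPS:
        for i in range(n_per_group):
            subject = f"{group}{i + 1:02d}"
            row = {"subject": subject, "group": group}
            for ep, (mu, sd) in BEHAVIOR_BASELINES.items():
                shift = profile.get(ep, 0.0) * sd if group == "lesion" else 0.0
                row[ep] = max(0.0, float(rng.normal(mu + shift, sd)))
            endpoint_rows.append(row)

            bias = profile.get("cylinder_bias", 0.0) if group == "lesion" else 0.0
            single = _CYLINDER_RATES["injection"] + _CYLINDER_RATES["non_injection"]
            lam_inj = single * (0.5 + bias / 2)
            lam_non = single * (0.5 - bias / 2)
            cylinder_rows.append(
                {
                    "subject": subject,
                    "group": group,
                    "touches_injection": int(rng.poisson(lam_inj)),
                    "touches_non_injection": int(rng.poisson(lam_non)),
                    "touches_both": int(rng.poisson(_CYLINDER_RATES["both"])),
                }
            )

            shift = profile.get("gait_shift", 0.0) if group == "lesion" else 0.0
            p = _SHAM_GAIT_P + np.array([-shift, shift, 0.0])
            counts = rng.multinomial(_N_GAIT_FRAMES, p)
            gait_rows.append(
                {"subject": subject, "group": group}
                | dict(zip((f"frames_{c}" for c in GAIT_CLASSES), (int(c) for c in counts)))
            )
    return {
        "endpoints": pd.DataFrame(endpoint_rows),
        "cylinder": pd.DataFrame(cylinder_rows),
        "gait": pd.DataFrame(gait_rows),
    }


def generate_cell_counts(
    n_per_group: int,
    sham_density: float = 300.0,
    loss_injection: float = 0.8952,
    loss_noninjection: float = 0.6121,
    n_slices: int = 3,
    seed: int = 0,
    subject_cv: float = 0.10,
    mean_area_mm2: float = 0.30,
) -> pd.DataFrame:
    """TH+ counts per subject x side x slice with a prescribed loss fraction.

    Lesion-side expected density is ``sham_density * (1 - loss)``; sham
    animals have no loss on either side.  Counts are Poisson around
    density x delineated area; a lognormal subject factor (CV ``subject_cv``)
    models animal-to-animal variability.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if not (0 <= loss_injection <= 1 and 0 <= loss_noninjection <= 1):
        raise ValueError("loss fractions must be in [0, 1]")
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    if sham_density <= 0:
        raise ValueError("sham_density must be positive")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log(1 + subject_cv**2))
    rows = []
    for group in GROUPS:
        for i in range(n_per_group):
            subject = f"{group}{i + 1:02d}"
            mult = float(np.exp(rng.normal(-sigma**2 / 2, sigma)))
            for side, loss in (("injection", loss_injection), ("non_injection", loss_noninjection)):
                dens = sham_density * mult * ((1 - loss) if group == "lesion" else 1.0)
                for s in range(n_slices):
                    area = float(rng.normal(mean_area_mm2, 0.1 * mean_area_mm2))
                    area = max(area, 0.05 * mean_area_mm2)
                    rows.append(
                        {
                            "subject": subject,
                            "group": group,
                            "side": side,
                            "slice": s + 1,
                            "th_count": int(rng.poisson(dens * area)),
                            "area_mm2": area,
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Study-condition presets
# ---------------------------------------------------------------------------

#: walking-state oscillation power (uV^2) per region, both groups — the
#: movement-related regional gradient each band carries
_WALK_POWER_SHAM: dict[str, dict[str, float]] = {
    "delta": {"M1": 6.0, "CPu": 6.0, "STN": 6.0, "SNc": 6.0, "PPN": 6.0},
    "theta": {"M1": 3.0, "CPu": 0.5, "STN": 5.5, "SNc": 5.5, "PPN": 5.5},
    "alpha": {"M1": 1.0, "CPu": 1.0, "STN": 3.5, "SNc": 3.5, "PPN": 6.0},
    "beta": {"M1": 0.5, "CPu": 3.5, "STN": 6.5, "SNc": 5.0, "PPN": 5.0},
    "gamma": {"M1": 0.5, "CPu": 6.75, "STN": 5.0, "SNc": 5.0, "PPN": 5.0},
}

#: additional walking power (uV^2) the lesion group gains, by band/region —
#: the band- and region-specific excesses of the hemiparkinsonian condition
_WALK_POWER_LESION_EXTRA: dict[str, dict[str, float]] = {
    "delta": {"SNc": 25.0},
    "theta": {"CPu": 7.0, "SNc": 7.0},
    "alpha": {"CPu": 6.0},
    "beta": {"STN": 5.0},
    "gamma": {"M1": 7.0, "STN": 7.0, "SNc": 7.0, "PPN": 7.0},
}


def demo_band_effects() -> BandEffects:
    """Walking-state oscillation amplitudes (uV RMS) embodying the study's pattern.

    Both groups gain walking oscillations with a band-specific regional
    gradient; the lesion group gains extra walking power, strongest and most
    widespread in gamma (M1/STN/SNc/PPN), plus region-specific excesses in
    delta (SNc), theta (CPu, SNc), alpha (CPu) and beta (STN).  Resting-state
    amplitudes are zero, so the walk-rest difference in a band equals the
    injected walking power (times the squared subject multiplier).
    """
    effects: BandEffects = {}
    for band in BAND_NAMES:
        for region, power in _WALK_POWER_SHAM[band].items():
            extra = _WALK_POWER_LESION_EXTRA[band].get(region, 0.0)
            effects[("sham", "walk", region, band)] = float(np.sqrt(power))
            effects[("lesion", "walk", region, band)] = float(np.sqrt(power + extra))
    return effects


def recovery_band_effects() -> BandEffects:
    """Gamma-only injection used by the parameter-recovery experiment.

    Walking gamma power (uV^2): M1 0.5, CPu 6.75, STN/SNc/PPN 5.0 in both
    groups; the lesion group gains +7.0 in M1, STN, SNc and PPN — roughly a
    2-SD group effect relative to between-subject noise, with CPu sitting
    midway between M1 and the top tier so that only the tier-vs-M1 post hoc
    contrasts are reliably significant.
    """
    effects: BandEffects = {}
    for region, power in _WALK_POWER_SHAM["gamma"].items():
        extra = _WALK_POWER_LESION_EXTRA["gamma"].get(region, 0.0)
        effects[("sham", "walk", region, "gamma")] = float(np.sqrt(power))
        effects[("lesion", "walk", region, "gamma")] = float(np.sqrt(power + extra))
    return effects


def demo_spec(seed: int = 0) -> SyntheticSpec:
    """The bundled full-size study configuration: 2 x 10 mice, 5 regions,
    two 5-min states at 1000 Hz."""
    return SyntheticSpec(band_effects=demo_band_effects(), seed=seed)


def calibration_spec(
    seed: int = 0, band_effects: BandEffects | None = None
) -> SyntheticSpec:
    """Reduced-size configuration used for replicated simulation experiments
    (type-I calibration, power/recovery): 20 s per state at 250 Hz, which
    keeps the full 10 s analysis segment per state and leaves room for the
    artifact search to skip a flagged stretch."""
    return SyntheticSpec(
        fs=250.0,
        state_duration_s=20.0,
        band_effects={} if band_effects is None else band_effects,
        seed=seed,
    )
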