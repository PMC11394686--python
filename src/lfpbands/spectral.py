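"""Power spectra, band power, and the walking-minus-resting difference statistic.

The estimator is Welch's method using the conditioned 1 s epochs as its
segments (Hann window, no overlap — the epoching already defines the
segmentation), giving 1 Hz resolution.  Band power integrates the one-sided
density over half-open bands, so the five default bands sum exactly to the
total power on the common [1, 100) Hz grid.  The headline statistic is the
per subject x region x band difference walk - rest in absolute power
(uV^2); the spectra are subtracted directly, not in dB.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .bands import DEFAULT_BANDS, BandDefinition
from .pipeline import ArtifactCriterion, EpochSet, condition_recording
from .synth import LfpRecording


@dataclass
class PowerSpectrum:
    """Averaged one-sided power spectral density for one subject/region/state."""

    freqs: np.ndarray  # Hz
    psd: np.ndarray  # uV^2/Hz
    n_epochs_averaged: int
    subject_id: str = ""
    group: str = ""
    region: str = ""
    state: str = ""

    def __post_init__(self) -> None:
        if np.any(self.psd < 0):
            raise ValueError("psd must be non-negative")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


def compute_psd(epochs: EpochSet) -> PowerSpectrum:
    """Welch PSD: Hann-windowed periodogram per epoch, averaged over epochs.

    Density-normalized: sum(psd) * df equals the windowed signal variance
    (up to the window's variance correction), i.e. Parseval holds.
    """
    x = np.stack(epochs.epochs)  # (n_epochs, n)
    n = x.shape[1]
    fs = epochs.fs
    win = sps.get_window("hann", n)
    xd = (x - x.mean(axis=1, keepdims=True)) * win
    spec = np.fft.rfft(xd, axis=1)
    # one-sided density normalization: sum(psd)*df = windowed variance
    psd = (np.abs(spec) ** 2) / (fs * np.sum(win**2))
    psd[:, 1:] *= 2.0
    if n % 2 == 0:  # Nyquist bin is not doubled
        psd[:, -1] /= 2.0
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    return PowerSpectrum(
        freqs=f,
        psd=psd.mean(axis=0),
        n_epochs_averaged=x.shape[0],
        subject_id=epochs.subject_id,
        group=epochs.group,
        region=epochs.region,
        state=epochs.state,
    )


def band_power(spectrum: PowerSpectrum, band: BandDefinition) -> float:
    """Integrated power over [band.low, band.high): sum of psd * df."""
    f = spectrum.freqs
    if band.low < f[0] - 1e-9 or band.high > f[-1] + spectrum.df + 1e-9:
        raise ValueError(f"band {band.name} [{band.low}, {band.high}) outside spectral grid")
    mask = (f >= band.low) & (f < band.high)
    return float(np.sum(spectrum.psd[mask]) * spectrum.df)


def state_difference(table: pd.DataFrame, mode: str = "power") -> pd.DataFrame:
    """Walk-minus-rest band power per subject x region x band.

    Requires exactly one rest and one walk row per (subject, region, band);
    anything else raises a pairing error rather than silently dropping.
    ``mode='power'`` (default) subtracts absolute power in uV^2; the
    optional ``mode='db'`` reports 10*log10(walk/rest) instead.
    """
    if mode not in ("power", "db"):
        raise ValueError(f"unknown difference mode {mode!r}")
    keys = ["subject", "region", "band"]
    wide = table.pivot_table(
        index=keys + ["group"], columns="state", values="power", aggfunc="count"
    )
    bad = wide.isna().any(axis=1) | (wide != 1).any(axis=1)
    if bad.any():
        missing = wide.index[bad].tolist()[:5]
        raise ValueError(f"unpaired rest/walk rows for {missing} (showing up to 5)")
    pivot = table.pivot_table(index=keys + ["group"], columns="state", values="power")
    out = pivot.reset_index()
    if mode == "db":
        out["diff"] = 10.0 * np.log10(out["walk"] / out["rest"])
    else:
        out["diff"] = out["walk"] - out["rest"]
    return out[["subject", "group", "region", "band", "diff"]]


def build_band_power_table(
    recordings: list[LfpRecording],
    criterion: ArtifactCriterion | None = None,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    band_limits: tuple[float, float] = (0.5, 80.0),
    segment_s: float = 10.0,
    epoch_length_s: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame, list[PowerSpectrum]]:
    """Full spectral pass: condition every recording, integrate band powers,
    form the walk-rest difference table.

    Returns (band-power table, difference table, per subject/region/state
    spectra).  The band-power table has one row per subject x region x
    state x band.
    """
    rows = []
    spectra: list[PowerSpectrum] = []
    for rec in recordings:
        try:
            epoch_sets = condition_recording(
                rec, criterion, band_limits, segment_s, epoch_length_s
            )
        except Exception as exc:  # re-raise with subject context
            raise type(exc)(f"subject {rec.subject_id}: {exc}") from exc
        for es in epoch_sets:
            spec = compute_psd(es)
            spectra.append(spec)
            for band in bands:
                rows.append(
                    {
                        "subject": es.subject_id,
                        "group": es.group,
                        "region": es.region,
                        "state": es.state,
                        "band": band.name,
                        "power": band_power(spec, band),
                    }
                )
    table = pd.DataFrame(rows)
    return table, state_difference(table), spectra


def group_mean_spectra(spectra: list[PowerSpectrum]) -> pd.DataFrame:
    """Mean +/- SEM spectra per group x region x state on the common grid,
    long format — the data behind per-region PSD panels."""
    rows = []
    for spec in spectra:
        for f, p in zip(spec.freqs, spec.psd):
            rows.append(
                {
                    "group": spec.group,
                    "region": spec.region,
                    "state": spec.state,
                    "freq": f,
                    "psd": p,
                }
            )
    df = pd.DataFrame(rows)
    g = df.groupby(["group", "region", "state", "freq"])["psd"]
    out = g.agg(mean="mean", sem=lambda x: x.std(ddof=1) / np.sqrt(len(x))).reset_index()
    return out
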