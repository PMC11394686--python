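"""Signal conditioning: band-pass filter, artifact-free segment search, epoching.

The processing order is fixed by contract: the full recording is filtered
first (0.5-80 Hz zero-phase Butterworth), then a single artifact-free
segment is located inside each behavioral-state interval, then the segment
is cut into fixed-length epochs.  Filtering per-epoch instead would leak
edge transients into every epoch and is deliberately not offered.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal as sps

from .synth import LfpRecording

logger = logging.getLogger(__name__)

FILTER_ORDER = 4  # Butterworth order (applied forward-backward -> 8th-order magnitude)


@dataclass
class ArtifactCriterion:
    """Rule deciding whether a sample is an artifact.

    ``amplitude_sd``: a sample is an artifact when its deviation from the
    interval median exceeds ``k`` robust standard deviations (MAD-based, so
    large artifacts do not inflate their own threshold).  ``absolute``:
    |signal| above ``abs_limit`` uV.  ``none``: accept everything.
    """

    method: str = "amplitude_sd"
    k: float = 6.0
    abs_limit: float | None = None

    def __post_init__(self) -> None:
        if self.method not in ("amplitude_sd", "absolute", "none"):
            raise ValueError(f"unknown artifact method {self.method!r}")
        if self.method == "amplitude_sd" and self.k <= 0:
            raise ValueError("k must be positive for amplitude_sd")
        if self.method == "absolute" and (self.abs_limit is None or self.abs_limit <= 0):
            raise ValueError("absolute criterion needs a positive abs_limit")

    def bad_samples(self, x: np.ndarray) -> np.ndarray:
        """Boolean mask of artifact samples within one state interval."""
        if self.method == "none":
            return np.zeros(len(x), dtype=bool)
        if self.method == "absolute":
            return np.abs(x) > self.abs_limit
        med = np.median(x)
        robust_sd = 1.4826 * np.median(np.abs(x - med))
        if robust_sd == 0:
            # flat signal: any deviation is an artifact; a fully flat signal
            # is itself pathological and rejected wholesale
            return np.ones(len(x), dtype=bool)
        return np.abs(x - med) > self.k * robust_sd


@dataclass
class EpochSet:
    """Fixed-length epochs for one subject x region x state."""

    subject_id: str
    group: str
    region: str
    state: str
    epochs: list[np.ndarray]
    fs: float
    epoch_length_s: float = 1.0

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("EpochSet needs at least one epoch")
        n = int(round(self.fs * self.epoch_length_s))
        if any(len(e) != n for e in self.epochs):
            raise ValueError(f"every epoch must have exactly {n} samples")
        if self.state not in ("rest", "walk"):
            raise ValueError(f"state must be rest or walk, got {self.state!r}")


class NoArtifactFreeSegmentError(RuntimeError):
    pass


@lru_cache(maxsize=32)
def _butter_sos(low: float, high: float, fs: float) -> np.ndarray:
    return sps.butter(FILTER_ORDER, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass_filter(x: np.ndarray, fs: float, low: float = 0.5, high: float = 80.0) -> np.ndarray:
    """Zero-phase Butterworth band-pass (order 4, applied forward-backward)."""
    if not 0 < low < high < fs / 2:
        raise ValueError(f"need 0 < low < high < fs/2, got low={low}, high={high}, fs={fs}")
    sos = _butter_sos(low, high, fs)
    # pad past the slowest transient (the low corner's time constant); even
    # reflection keeps the edge value continuous, which bounds the edge
    # transient an out-of-band component can inject
    padlen = max(3 * (2 * FILTER_ORDER + 1), int(3 * fs / low))
    if len(x) <= padlen:
        raise ValueError(f"signal too short to filter ({len(x)} samples)")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float), padlen=padlen, padtype="even")


def find_artifact_free_segment(
    recording: LfpRecording,
    region: str,
    state: str,
    duration_s: float = 10.0,
    criterion: ArtifactCriterion | None = None,
    filtered: np.ndarray | None = None,
) -> tuple[float, float]:
    """Earliest ``duration_s`` window inside the state interval with no artifact.

    ``filtered`` optionally supplies an already-filtered version of the
    region's channel to scan (the criterion statistics are always computed
    on the state interval of whichever signal is scanned).
    """
    criterion = criterion or ArtifactCriterion()
    start_s, end_s = recording.state_interval(state)
    if end_s - start_s < duration_s:
        raise ValueError(
            f"{recording.subject_id}/{region}/{state}: state interval shorter than {duration_s} s"
        )
    fs = recording.fs
    sig = recording.channels[region] if filtered is None else filtered
    i0, i1 = int(round(start_s * fs)), int(round(end_s * fs))
    x = sig[i0:i1]
    win = int(round(duration_s * fs))
    bad = criterion.bad_samples(x).astype(int)
    csum = np.concatenate([[0], np.cumsum(bad)])
    window_bad = csum[win:] - csum[:-win]  # artifacts in [j, j+win)
    ok = np.flatnonzero(window_bad == 0)
    if len(ok) == 0:
        raise NoArtifactFreeSegmentError(
            f"no artifact-free {duration_s} s segment for subject "
            f"{recording.subject_id}, region {region}, state {state}"
        )
    j = int(ok[0])
    return start_s + j / fs, start_s + (j + win) / fs


def epoch_segment(
    x: np.ndarray, fs: float, epoch_length_s: float = 1.0
) -> list[np.ndarray]:
    """Cut a segment into consecutive non-overlapping fixed-length epochs.

    A trailing remainder shorter than one epoch is dropped with a warning.
    """
    n_epoch = int(round(fs * epoch_length_s))
    if len(x) < n_epoch:
        raise ValueError(f"segment shorter than one epoch ({len(x)} < {n_epoch} samples)")
    n_full = len(x) // n_epoch
    if len(x) % n_epoch:
        msg = f"dropping trailing {len(x) % n_epoch} samples (< one epoch)"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    return [x[i * n_epoch : (i + 1) * n_epoch] for i in range(n_full)]


def condition_recording(
    recording: LfpRecording,
    criterion: ArtifactCriterion | None = None,
    band: tuple[float, float] = (0.5, 80.0),
    segment_s: float = 10.0,
    epoch_length_s: float = 1.0,
) -> list[EpochSet]:
    """Filter -> locate artifact-free segment -> epoch, for every region x state."""
    criterion = criterion or ArtifactCriterion()
    out: list[EpochSet] = []
    for region, raw in recording.channels.items():
        filt = bandpass_filter(raw, recording.fs, *band)
        for state in ("rest", "walk"):
            t0, t1 = find_artifact_free_segment(
                recording, region, state, segment_s, criterion, filtered=filt
            )
            i0, i1 = int(round(t0 * recording.fs)), int(round(t1 * recording.fs))
            out.append(
                EpochSet(
                    subject_id=recording.subject_id,
                    group=recording.group,
                    region=region,
                    state=state,
                    epochs=epoch_segment(filt[i0:i1], recording.fs, epoch_length_s),
                    fs=recording.fs,
                    epoch_length_s=epoch_length_s,
                )
            )
    return out
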