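"""Frequency-band definitions.

Bands follow the study's printed edges: delta 1-4, theta 4-8, alpha 8-21,
beta 21-32, gamma 32-100 Hz.  The 8-21 Hz "alpha" and 21-32 Hz "beta"
partitions are nonstandard for rodent LFP but are kept as printed rather
than remapped.  Edges are half-open [low, high) so a shared edge (4, 8, 21,
32 Hz) is counted in exactly one band and the five bands partition
[1, 100) Hz without overlap.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [low, high) in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"band {self.name!r}: low must be < high")

    @property
    def width(self) -> float:
        return self.high - self.low

    def contains(self, freq: float) -> bool:
        return self.low <= freq < self.high


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 21.0),
    BandDefinition("beta", 21.0, 32.0),
    BandDefinition("gamma", 32.0, 100.0),
)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in DEFAULT_BANDS)

#: Representative synthesis frequency per band (Hz), used by the synthetic
#: generator when injecting a band-limited oscillation.  Gamma sits at 40 Hz,
#: inside the 0.5-80 Hz acquisition passband.
BAND_CENTER_FREQS: dict[str, float] = {
    "delta": 2.5,
    "theta": 6.0,
    "alpha": 14.0,
    "beta": 26.0,
    "gamma": 40.0,
}


def band_by_name(name: str, bands: tuple[BandDefinition, ...] = DEFAULT_BANDS) -> BandDefinition:
    for b in bands:
        if b.name == name:
            return b
    raise KeyError(f"unknown band {name!r}")
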