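import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make helpers importable

import lfpbands as lb


@pytest.fixture(scope="session")
def small_dataset():
    """One reduced-size synthetic dataset with the recovery gamma effects."""
    spec = lb.calibration_spec(seed=7, band_effects=lb.recovery_band_effects())
    recordings, truth = lb.generate_lfp_dataset(spec)
    return spec, recordings, truth


@pytest.fixture(scope="session")
def small_tables(small_dataset):
    _, recordings, _ = small_dataset
    band_table, diff_table, spectra = lb.build_band_power_table(recordings)
    return band_table, diff_table, spectra
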