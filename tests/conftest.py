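import numpy as np
import pytest

from segbeat import (SynthConfig, WORKING_FS, generate_record, resample_record)


@pytest.fixture(scope="session")
def clean_record_pair():
    """A noise-free synthetic record plus its truth (default conditions)."""
    cfg = SynthConfig(seed=11, noise_sd=0.0, baseline_wander_amp=0.0)
    return generate_record(cfg, "clean-11")


@pytest.fixture(scope="session")
def noisy_record_pair():
    """A synthetic record under the default (noisy) conditions."""
    cfg = SynthConfig(seed=5)
    return generate_record(cfg, "noisy-5")


@pytest.fixture(scope="session")
def working_rate_record(noisy_record_pair):
    rec, truth = noisy_record_pair
    return resample_record(rec, WORKING_FS), truth.rescale(WORKING_FS)


@pytest.fixture(scope="session")
def short_record_pair():
    """A small, fast record for CLI and IO round trips."""
    cfg = SynthConfig(seed=3, rhythm_blocks=(("NSR", 20.0), ("AFIB_LIKE", 20.0)))
    return generate_record(cfg, "short-3")


def metronome_peaks(n_beats: int, rr: int = 120, start: int = 200) -> np.ndarray:
    return start + rr * np.arange(n_beats)
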