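"""Shared fixtures.

Heavy objects (HRTF sets, neuron banks, the speech-band pipeline config)
are session-scoped: deriving a best-ILD table means spatializing and
filtering noise for every azimuth, so tests share one instance. All test
configs run the speech-band (200 Hz - 8 kHz) filterbank at a 20 kHz sample
rate to keep runtimes reasonable; the full-range defaults are exercised by
the configuration-fidelity tests, which need no audio.
"""

from dataclasses import replace

import numpy as np
import pytest

from bossa import CueParams, FilterbankSpec, MixtureSpec, PipelineConfig, default_mixture
from bossa.config import narrowband_demo_config, tuning_demo_config
from bossa.spatial import make_spherical_hrtf_set

FS = 20000.0


@pytest.fixture(scope="session")
def speech_spec() -> FilterbankSpec:
    return FilterbankSpec(f_max=8000.0, fs=FS)


@pytest.fixture(scope="session")
def small_spec() -> FilterbankSpec:
    """16-channel speech-band bank for cheap per-channel tests."""
    return FilterbankSpec(n_channels=16, f_max=8000.0, fs=FS)


@pytest.fixture(scope="session")
def cue_params() -> CueParams:
    return CueParams()


@pytest.fixture(scope="session")
def hrtf():
    return make_spherical_hrtf_set(fs=FS)


@pytest.fixture(scope="session")
def speech_config(hrtf) -> PipelineConfig:
    cfg = narrowband_demo_config()
    cfg.filterbank = replace(cfg.filterbank, fs=FS)
    return cfg


@pytest.fixture(scope="session")
def speech_bank(speech_config, hrtf):
    return speech_config.build_bank(hrtf=hrtf)


@pytest.fixture(scope="session")
def demo9_config() -> PipelineConfig:
    cfg = tuning_demo_config()
    cfg.filterbank = replace(cfg.filterbank, f_max=8000.0, fs=FS)
    return cfg


@pytest.fixture(scope="session")
def fixture_mixture(hrtf, speech_config):
    """One 0 dB TMR five-source mixture plus its clean spatialized target."""
    return default_mixture(
        MixtureSpec(tmr_db=0.0, seed=11), hrtf, duration=2.0, fs=FS
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
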