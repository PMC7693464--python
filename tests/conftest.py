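import sys
from dataclasses import replace
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # reference_tables

from nirsclench.synth import (CohortConfig, EffectProfile, NoiseProfile,
                              generate_recording)
from nirsclench.preprocess import preprocess_recording
from nirsclench.imaging import ChannelLayout


@pytest.fixture(scope="session")
def layout() -> ChannelLayout:
    return ChannelLayout.default()


@pytest.fixture(scope="session")
def silent_config() -> CohortConfig:
    """Noise-free cohort with the default effect profile but no
    between-subject spread: realized effects equal the configured ones."""
    zero = np.zeros(22)
    effects = replace(EffectProfile(), oxy_subject_sd=zero, deoxy_subject_sd=zero)
    return CohortConfig(effects=effects, noise=NoiseProfile.silent(), seed=11)


@pytest.fixture(scope="session")
def noisy_epoch():
    """One preprocessed subject with default effects and noise."""
    rec = generate_recording(CohortConfig(seed=5), 0)
    return preprocess_recording(rec)
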