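"""Shared fixtures: montage, templates, and one fully processed subject."""

from __future__ import annotations

import numpy as np
import pytest

from eegcomplexity import (
    EntropyParams,
    SimulationParams,
    default_layout,
    entropy_profile,
    make_templates,
    microstate_measures,
    backfit,
    MicrostateMaps,
    preprocess_recording,
    simulate_subject,
)
from eegcomplexity.preprocess import Recording


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def templates(layout):
    return make_templates(layout, k=5, seed=1)


@pytest.fixture(scope="session")
def short_params():
    """Short-duration study parameters used for per-subject fixtures."""
    return SimulationParams(n_subjects=2, duration=36.0, seed=11)


@pytest.fixture(scope="session")
def subject(short_params, templates, layout):
    """(Recording, GroundTruth) for one synthetic subject."""
    return simulate_subject(short_params, templates, 0, layout=layout)


@pytest.fixture(scope="session")
def epoched(subject):
    ep, report = preprocess_recording(subject[0])
    assert report["keep"]
    return ep


@pytest.fixture(scope="session")
def profile(epoched):
    """Entropy profile of the fixture subject (the expensive step, shared)."""
    return entropy_profile(epoched, EntropyParams())


@pytest.fixture(scope="session")
def measures(epoched, templates):
    rec = Recording(
        data=epoched.concatenated(), fs=epoched.fs, layout=epoched.layout,
        reference="average",
    )
    group = MicrostateMaps(maps=templates, gev=1.0, level="group")
    return microstate_measures(backfit(rec, group))
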