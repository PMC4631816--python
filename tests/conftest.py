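"""Shared fixtures: small geometries and simulated subjects.

Everything is generated at test time from seeds; the sizes are scaled
down from the study design (fewer channels, vertices and repetitions,
coarser sampling) so the whole suite runs on one core in minutes.
"""

from __future__ import annotations

import numpy as np
import pytest

from megbody.geometry import build_geometry
from megbody.preprocess import PreprocessConfig, preprocess
from megbody.simulate import (
    EpochSet,
    SimulationConfig,
    build_model,
    generate_subject,
)

#: scaled-down study conditions used across tests: 32-channel helmet
#: (24 retained), 200-vertex shell, 10 repetitions, 250 Hz sampling
SMALL_CONFIG = SimulationConfig(
    n_channels=32,
    n_vertices=200,
    repetitions=10,
    sfreq=250.0,
    amplitude_nam=2.0,
    n_background=10,
)


@pytest.fixture(scope="session")
def small_geometry():
    return build_geometry(n_channels=32, n_vertices=200, head_radius=0.09, seed=3)


@pytest.fixture(scope="session")
def small_model():
    return build_model(SMALL_CONFIG, seed=3)


@pytest.fixture(scope="session")
def small_subject(small_model):
    return generate_subject(SMALL_CONFIG, seed=11, model=small_model)


@pytest.fixture(scope="session")
def clean_subject(small_subject):
    clean, _ = preprocess(small_subject, PreprocessConfig())
    return clean


@pytest.fixture(scope="session")
def noiseless_config():
    return SimulationConfig(
        n_channels=32,
        n_vertices=200,
        repetitions=2,
        sfreq=250.0,
        amplitude_nam=2.0,
        sensor_noise_sd=0.0,
        n_background=0,
        gain_jitter_sd=0.0,
        image_gain_sd=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_model(noiseless_config):
    # same geometry seed as small_model, but a template without image gains
    return build_model(noiseless_config, seed=3)


@pytest.fixture(scope="session")
def noiseless_subject(noiseless_config, noiseless_model):
    return generate_subject(noiseless_config, seed=11, model=noiseless_model)


def make_epochs(
    data: np.ndarray,
    sfreq: float = 250.0,
    tmin_ms: float = -500.0,
    image_id: np.ndarray | None = None,
    category: np.ndarray | None = None,
    regions: list[str] | None = None,
) -> EpochSet:
    """Construct a minimal EpochSet around a raw data array."""
    n_trials, n_ch, n_samp = data.shape
    sens, _ = build_geometry(n_channels=max(n_ch, 8), n_vertices=16, seed=0)
    sens = sens.subset(np.arange(sens.n_channels) < n_ch)
    if regions is not None:
        sens = sens.subset(np.ones(n_ch, dtype=bool))
        object.__setattr__(sens, "region", np.asarray(regions, dtype=object))
    times = tmin_ms + np.arange(n_samp) * 1000.0 / sfreq
    if image_id is None:
        image_id = np.ones(n_trials, dtype=int)
    if category is None:
        category = np.asarray(["foot"] * n_trials, dtype=object)
    return EpochSet(
        data=np.asarray(data, dtype=float),
        times=times,
        image_id=np.asarray(image_id),
        category=np.asarray(category, dtype=object),
        sensors=sens,
        sfreq=sfreq,
    )
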