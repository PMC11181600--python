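"""Shared fixtures: synthetic sessions with ground truth, reused across
modules (generation and feature extraction are the expensive steps)."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ecapkit import ecaps, physio, synth

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_session():
    """Biomarker-grid session (two frequencies, 5 s trains) + ground truth."""
    return synth.generate_session(seed=0)


@pytest.fixture(scope="session")
def default_features(default_session):
    session, _ = default_session
    return ecaps.compute_activations(session)


@pytest.fixture(scope="session")
def default_physio(default_session):
    """Physio metrics with the segmentation matched to the generator's
    response latency (2 s ramp, plateau through the post window)."""
    session, _ = default_session
    return physio.compute_physio_responses(
        session, segmentation=physio.Segmentation(5.0, 2.0, 5.0))


@pytest.fixture(scope="session")
def recruitment_session():
    """Neural-focus grid: two pulse widths, 3 s / 10 Hz trains."""
    return synth.generate_session(synth.recruitment_grid(), seed=1)


@pytest.fixture(scope="session")
def recruitment_features(recruitment_session):
    session, _ = recruitment_session
    return ecaps.compute_activations(session)


@pytest.fixture(scope="session")
def latent_session():
    """Ten stimulation locations probed at the five vector currents."""
    return synth.generate_session(synth.latent_grid(), seed=0)


@pytest.fixture(scope="session")
def latent_features(latent_session):
    session, _ = latent_session
    return ecaps.compute_activations(session)


@pytest.fixture(scope="session")
def noisefree_train_session():
    """Same pulse parameters at 2, 10 and 50 Hz with zero neural noise."""
    from dataclasses import replace
    nerve = replace(synth.default_nerve_model(), noise_sd=0.0)
    cfg = synth.SessionConfig(
        currents=(1.2,), frequencies=(2.0, 10.0, 50.0), durations=(1.0,),
        nerve=nerve, inter_event_gap=5.0, lead_in=8.0, tail=5.0)
    return synth.generate_session(cfg, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
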