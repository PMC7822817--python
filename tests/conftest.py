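"""Shared fixtures: small synthetic trials and encoded responses.

Unit tests mostly run on a shortened indentation profile (50/400/50 ms) to
keep the suite fast; the acceptance tests use the full 2500 ms protocol.
"""

from __future__ import annotations

import numpy as np
import pytest

from neurotactile import encoder, innervation, stimuli


@pytest.fixture(scope="session")
def short_profile() -> stimuli.IndentationProfile:
    return stimuli.IndentationProfile(onset_ms=50, hold_ms=400, offset_ms=50, depth_mm=1.4)


@pytest.fixture(scope="session")
def grid() -> stimuli.GridSpec:
    return stimuli.GridSpec()


@pytest.fixture(scope="session")
def default_imap() -> innervation.InnervationMap:
    return innervation.build_innervation(seed=42)


@pytest.fixture(scope="session")
def sharp_trial(short_profile) -> stimuli.TrialRecord:
    """Noise-free 1 mm cone indentation (short profile)."""
    return stimuli.generate_trial(
        stimuli.StimulusObject("cone", 1.0),
        short_profile,
        noise_sd=0.0,
        jitter_mm=0.0,
        force_scale_sd=0.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def blunt_trial(short_profile) -> stimuli.TrialRecord:
    """Noise-free 9 mm cone indentation (short profile)."""
    return stimuli.generate_trial(
        stimuli.StimulusObject("cone", 9.0),
        short_profile,
        noise_sd=0.0,
        jitter_mm=0.0,
        force_scale_sd=0.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def short_dataset(short_profile) -> list[stimuli.TrialRecord]:
    """8 objects x 5 trials on the short profile."""
    return stimuli.generate_dataset(
        n_trials_per_object=5, profile=short_profile, master_seed=7
    )


@pytest.fixture(scope="session")
def short_responses(short_dataset, default_imap) -> list[encoder.PopulationResponse]:
    return encoder.encode_dataset(short_dataset, default_imap, noc_gain_seed=7)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
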