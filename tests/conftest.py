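"""Shared fixtures and deterministic hypothesis settings."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from edgecode import PopulationConfig, build_paired_fingertips

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# A small patch keeps unit counts ~100 instead of ~400; all geometric and
# statistical invariants are scale-free, so the fast config is used wherever
# the full-size fingertip is not itself under test.
SMALL_CONFIG = PopulationConfig(patch_width=10.0, patch_height=10.0)


@pytest.fixture(scope="session")
def small_config() -> PopulationConfig:
    return SMALL_CONFIG


@pytest.fixture(scope="session")
def small_pair(small_config):
    """One subfield fingertip and its uniform twin on the small patch."""
    return build_paired_fingertips(np.random.default_rng(7), small_config)


@pytest.fixture(scope="session")
def full_pair():
    """One full-size (default-config) fingertip pair."""
    return build_paired_fingertips(np.random.default_rng(11))
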