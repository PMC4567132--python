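"""Shared fixtures: small synthetic cohorts generated at test time."""

from __future__ import annotations

import pytest

from xciscope import SimulationConfig, generate_cohort
from xciscope.types import HISTOLOGIES, XCI_GROUPS


def small_config(seed: int = 7, n: int = 12, **overrides) -> SimulationConfig:
    """A reduced cohort (12 per histology x state cell, 60 X-island probes)
    that keeps every structural feature of the default conditions."""
    kwargs = dict(
        seed=seed,
        n_samples={(h, s): n for h in HISTOLOGIES for s in XCI_GROUPS},
        n_x_island_probes=60,
        n_x_nonisland_probes=6,
        n_autosomal_island_probes=120,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def small_cohort():
    """(methylation, expression, segments, clinical, manifest, truth)."""
    return generate_cohort(small_config())


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size default cohort (60 per cell), shared across tests."""
    return generate_cohort(SimulationConfig(seed=11))
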