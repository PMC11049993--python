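"""Shared fixtures: one small seeded synthetic bundle reused across tests.

Everything is generated programmatically; no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from umiseq import build_error_model, simulate_panel, simulate_pon


@pytest.fixture(scope="session")
def small_panel():
    rng = np.random.default_rng(101)
    return simulate_panel(400, rng)


@pytest.fixture(scope="session")
def pon_bundle(small_panel):
    """(pon tables, generating truth, estimated error model) on the small panel."""
    rng = np.random.default_rng(202)
    pon, truth = simulate_pon(
        small_panel, rng, n_samples=24, depth_median=4000, depth_sigma=0.2
    )
    model = build_error_model(pon, small_panel)
    return pon, truth, model


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
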