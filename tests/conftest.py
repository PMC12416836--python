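"""Shared fixtures: default parameter sets and small reusable simulations."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import lineagesim as ls


@pytest.fixture(scope="session")
def params():
    return ls.MinimalModelParams()


@pytest.fixture(scope="session")
def noise_free():
    return dataclasses.replace(ls.MinimalModelParams(), noise=False)


@pytest.fixture(scope="session")
def reference(params):
    return ls.deterministic_reference(params)


@pytest.fixture(scope="session")
def control_result():
    """Small untreated population with full trajectory retention."""
    return ls.simulate_population(seed=11, n_start=20, duration_h=72.0)


@pytest.fixture(scope="session")
def saturating_result():
    """Population under a saturating CDK4/6-inhibitor-like dose."""
    drug = ls.builtin_drug("palbociclib", 1900.0)
    return ls.simulate_population(seed=7, n_start=60, duration_h=72.0, drug=drug)
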