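"""Shared fixtures: one study-scale simulated cohort, reused across modules."""

from __future__ import annotations

import numpy as np
import pytest

from quasimendel.cohort_sim import (
    CohortConfig,
    default_panel_genes,
    simulate_annotations,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def demo_cohort():
    """28 ascertained cases vs 3554 controls at the default study conditions."""
    return simulate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def demo_annotations(demo_cohort):
    cases, _, _ = demo_cohort
    return simulate_annotations(cases, seed=11)


@pytest.fixture(scope="session")
def panel():
    return tuple(default_panel_genes())


@pytest.fixture()
def rng():
    return np.random.default_rng(2019)
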