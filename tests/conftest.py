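"""Shared fixtures.

The expensive objects — the default synthetic cohort and a reduced cohort
for clock unit tests — are session-scoped so every module reuses one copy.
"""

import numpy as np
import pytest

from frogclock.io import default_registry
from frogclock.simulate import (
    SimulationConfig,
    SpeciesPlan,
    default_study_plan,
    generate_cohort,
)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def default_cohort():
    """The full default study cohort (65 frogs + 200 humans), seed 1."""
    return generate_cohort(default_study_plan(seed=1))


@pytest.fixture(scope="session")
def frog_cohort(default_cohort):
    cohort, sets, truth = default_cohort
    return cohort.select_samples(cohort.cohorts == "frog"), sets, truth


def small_config(seed=1, **overrides):
    """A reduced two-frog-species plan for fast clock/pipeline unit tests."""
    plans = (
        SpeciesPlan("laevis", 0.005, 19.0,
                    {"blood": 4, "muscle": 5, "skin": 4, "whole": 7}),
        SpeciesPlan("tropicalis", 0.005, 8.0,
                    {"blood": 4, "muscle": 4, "skin": 4, "whole": 4}),
    )
    defaults = dict(n_cpgs=400, plans=plans, n_positive_cpgs=60,
                    n_negative_cpgs=40, seed=seed)
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    """36 frog samples, 400 CpGs, planted signal; for clock unit tests."""
    return generate_cohort(small_config())
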