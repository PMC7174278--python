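"""Shared fixtures: formulation, reference operating point and baseline simulations.

Expensive noise-free simulations are session-scoped; tests must not mutate
them in place (copy first).
"""

import numpy as np
import pytest

from granudry import (
    BedConfig,
    ResistanceFit,
    aggregate_isotherm,
    load_formulation,
    simulate_drying,
)

#: Reference resistance parameters of the 600 L/min operating point.
TRUTH_600 = dict(omega_ext=0.028, omega_max=0.58, f_w_crit=0.10, f_w_end=0.05)


@pytest.fixture(scope="session")
def formulation():
    return load_formulation()


@pytest.fixture(scope="session")
def aggregate(formulation):
    """(table, fitted GAB params) of the placebo aggregate isotherm."""
    return aggregate_isotherm(formulation)


@pytest.fixture(scope="session")
def agg_params(aggregate):
    return aggregate[1]


@pytest.fixture()
def bed():
    return BedConfig()


@pytest.fixture()
def truth():
    return ResistanceFit(**TRUTH_600)


@pytest.fixture(scope="session")
def baseline_run(agg_params):
    """Noise-free 120 min batch at the reference 600 L/min operating point."""
    return simulate_drying(BedConfig(), ResistanceFit(**TRUTH_600), agg_params)


@pytest.fixture(scope="session")
def offspec_run(agg_params):
    """Truncated batch (stopped at 50 min) that never reaches the 2% endpoint."""
    return simulate_drying(BedConfig(), ResistanceFit(**TRUTH_600), agg_params,
                           duration=3000.0)
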