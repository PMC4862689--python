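import numpy as np
import pytest

from scaffold_cycle.motif_model import (
    ConcentrationTotals,
    RateConstants,
    build_model,
)
from scaffold_cycle.screen import SamplingSpec, sample_parameters


@pytest.fixture(scope="session")
def unit_rates():
    return RateConstants(*([1.0] * 10))


@pytest.fixture(scope="session")
def unit_model(unit_rates):
    return build_model(unit_rates)


@pytest.fixture(scope="session")
def default_totals():
    return ConcentrationTotals(S_total=1.0, K_total=0.5, P_total=0.1,
                               T_total=0.2)


def random_parameter_sets(n, seed=123, regime="saturated"):
    """Deterministic stream of feasible (rates, totals) draws."""
    spec = SamplingSpec(n_samples=n, seed=seed, regime=regime)
    return list(sample_parameters(spec))


@pytest.fixture(scope="session")
def random_sets_small():
    return random_parameter_sets(20)
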