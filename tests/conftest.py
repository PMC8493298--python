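import numpy as np
import pytest

from cardiorom import (
    ConductivityModel,
    assemble_operators,
    build_spline_space,
    make_fiber_field,
    make_fixture,
    run_pipeline,
)


@pytest.fixture(scope="session")
def unit_space():
    """p=2 tensor-product space on the unit square (36 basis functions)."""
    return build_spline_space(2, (4, 4), ((0.0, 1.0), (0.0, 1.0)))


@pytest.fixture(scope="session")
def unit_conductivity(unit_space):
    fiber = make_fiber_field(unit_space, "constant", (1.0, 0.0))
    return ConductivityModel(
        sigma_l_i=2.3e-3, sigma_t_i=2.4e-4, sigma_l_e=1.5e-3, sigma_t_e=1.0e-3,
        fiber=fiber,
    )


@pytest.fixture(scope="session")
def unit_operators(unit_space, unit_conductivity):
    return assemble_operators(unit_space, unit_conductivity)


@pytest.fixture(scope="session")
def tiny_result():
    """One tiny-fixture pipeline run shared by pipeline/acceptance tests."""
    return run_pipeline(make_fixture("tiny"))
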