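"""Shared fixtures: layer stacks, fast solver configs, and the case-table
results that several test modules reuse."""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from skinburn import SolverConfig, back_skin_stack, build_grid, case_catalog, run_case

# explicit scheme at dx = 2 um, Fo ~ 0.45 -- the resolution at which the
# damage results are grid-converged (see docs/methods.md)
EXPLICIT_DX2 = SolverConfig(dx=2e-6, dt=1.6e-5, scheme="explicit", probe_depths=(0.0, 1e-4))
# Crank-Nicolson at 1 ms: agrees with the explicit basal series to <1e-3 degC
FAST_IMPLICIT = SolverConfig(dx=2e-6, dt=1e-3, scheme="implicit", probe_depths=(0.0, 1e-4))


@pytest.fixture(scope="session")
def back_stack():
    return back_skin_stack()


@pytest.fixture(scope="session")
def back_grid_dx2(back_stack):
    return build_grid(back_stack, 2e-6)


@pytest.fixture(scope="session")
def case_results_dx2():
    """All thirteen catalogued cases, explicit scheme at dx = 2 um."""
    return {spec.label: run_case(spec, EXPLICIT_DX2) for spec in case_catalog()}


@pytest.fixture(scope="session")
def case_a_result(case_results_dx2):
    return case_results_dx2["A"]


def basal_series(result):
    """(times, temperatures) at the 0.1 mm probe of a CaseResult."""
    from skinburn import probe_series

    return probe_series(result.history, 1e-4)


def milestone(times, temps, t):
    return float(np.interp(t, times, temps))
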