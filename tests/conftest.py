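"""Shared fixtures: converged baseline beat and full aging studies.

The heavy periodic-steady-state runs are session-scoped; every test that
needs a converged beat or a per-decade study reuses them.
"""

import pytest

from cardioage import ElastanceParams, ValveParams, decade_arterial_params
from cardioage.aging import compute_baseline, run_aging_study


@pytest.fixture(scope="session")
def cardiac20():
    return ElastanceParams()


@pytest.fixture(scope="session")
def arterial20():
    return decade_arterial_params(20)


@pytest.fixture(scope="session")
def valves():
    return ValveParams()


@pytest.fixture(scope="session")
def baseline(cardiac20, valves):
    """Calibrated age-20 operating point: (Baseline, AgingRecord)."""
    return compute_baseline(cardiac20, valves)


@pytest.fixture(scope="session")
def arterial_only_records(cardiac20, valves):
    return run_aging_study("arterial_only", cardiac=cardiac20, valves=valves)


@pytest.fixture(scope="session")
def combined_records(cardiac20, valves):
    return run_aging_study("combined", cardiac=cardiac20, valves=valves)
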