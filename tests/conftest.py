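import pytest

import opmdsim as om


@pytest.fixture(scope="session")
def params():
    return om.ParameterSet.base_case()


@pytest.fixture(scope="session")
def table():
    return om.default_life_table("male")


@pytest.fixture(scope="session")
def calib(params):
    return om.default_calibration(params)


@pytest.fixture(scope="session")
def cohort_results(params, table, calib):
    """All eight strategies on the deterministic cohort engine."""
    return om.run_all_strategies(params, table, calibration=calib, engine="cohort")


@pytest.fixture(scope="session")
def micro_results(params, table, calib):
    """Microsimulation (n = 100,000, fixed seed) for the tallied strategies."""
    return {
        sid: om.run_microsimulation(
            params, om.make_strategy(sid), table, n=100_000, seed=123, calibration=calib
        )
        for sid in (1, 3, 6)
    }
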