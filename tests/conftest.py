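import matplotlib
import pytest

matplotlib.use("Agg")

import fhsim


@pytest.fixture(scope="session")
def cities():
    return fhsim.load_packaged_cities()


@pytest.fixture(scope="session")
def hr_table():
    return fhsim.gen_hr_table(fhsim.SynthConfig(seed=1))


@pytest.fixture(scope="session")
def schedule(cities, hr_table):
    return fhsim.build_schedule(cities, hr_table)


@pytest.fixture(scope="session")
def sweep(schedule, cities):
    return fhsim.scenario_sweep(schedule, cities)


@pytest.fixture(scope="session")
def rio(cities):
    return next(c for c in cities if c.name == "Rio de Janeiro")
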