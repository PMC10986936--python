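import pytest

import wingflux as wf
from wingflux import drosophila


@pytest.fixture(scope="session")
def fluid():
    return wf.HAEMOLYMPH


@pytest.fixture(scope="session")
def bc():
    return wf.BoundaryConditions(inflow_rate_um3_s=5.2e2)


@pytest.fixture(scope="session")
def forewing():
    return drosophila.build_drosophila_forewing()


@pytest.fixture(scope="session")
def forewing_no_pcv(forewing):
    return wf.remove_vein(forewing, "PCV")


@pytest.fixture(scope="session")
def sol_with(forewing, fluid, bc):
    return wf.solve_loops(forewing, fluid, bc)


@pytest.fixture(scope="session")
def sol_without(forewing_no_pcv, fluid, bc):
    return wf.solve_loops(forewing_no_pcv, fluid, bc)


@pytest.fixture(scope="session")
def vein_table():
    return drosophila.load_vein_table()


@pytest.fixture(scope="session")
def m6_cell():
    return drosophila.load_simplified_cell("M6")
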