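import pytest
from hypothesis import HealthCheck, settings

from heatherdss import MonitoringModel, builtin_table1

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def table1():
    return builtin_table1()


@pytest.fixture(scope="session")
def result10k():
    """The headline simulation: built-in table, 10,000 iterations, seed 42."""
    return MonitoringModel.table1().fit(iterations=10_000, seed=42)
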