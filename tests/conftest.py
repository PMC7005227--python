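import pytest
from hypothesis import HealthCheck, settings

from pelvidose import io

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table3_rows():
    """Historical mean dose vectors (1905 ... 2018) from the packaged fixture."""
    return io.load_table(io.packaged_fixture("table3_doses.csv"), "doses")


@pytest.fixture(scope="session")
def table3_by_year(table3_rows):
    return {row.label.split()[0]: row for row in table3_rows}
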