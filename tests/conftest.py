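import pytest
from hypothesis import HealthCheck, settings

import fuzzytr as ft

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def unit_model():
    return ft.build_model("unit")


@pytest.fixture(scope="session")
def b50_model():
    return ft.build_model("BLOSUM50")


@pytest.fixture(scope="session")
def b62_model():
    return ft.build_model("BLOSUM62")
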