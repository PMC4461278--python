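import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")

from amperr import construct_preset, make_barcode_set, synthetic_panel  # noqa: E402


@pytest.fixture(scope="session")
def panel():
    return synthetic_panel()


@pytest.fixture(scope="session")
def miseq_spec():
    return construct_preset("miseq")


@pytest.fixture(scope="session")
def pgm_spec():
    return construct_preset("pgm")


@pytest.fixture(scope="session")
def flx454_spec():
    return construct_preset("flx454")


@pytest.fixture(scope="session")
def barcodes16():
    return make_barcode_set(10, 16)


@pytest.fixture(scope="session")
def barcodes10():
    return make_barcode_set(10, 10)
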