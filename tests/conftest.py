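import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def catalog():
    from vizonto.catalog import shipped_catalog

    return shipped_catalog()


@pytest.fixture(scope="session")
def base():
    from vizonto.ontology import base_model

    return base_model()


@pytest.fixture(scope="session")
def dermoscopy(catalog):
    from vizonto.ontology import dermoscopy_model

    return dermoscopy_model(catalog)


@pytest.fixture(scope="session")
def palette():
    from vizonto.palette import default_palette

    return default_palette()
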