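import pytest
from hypothesis import HealthCheck, settings

from firstreports.synthetic import CorpusSpec, ErrorModel, generate_corpus

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_corpus():
    """25 synthetic reports with ground truth, fixed seed."""
    return generate_corpus(CorpusSpec(n_reports=25), seed=123)


@pytest.fixture(scope="session")
def coord_corpus():
    """Corpus where every report prints coordinates and two locations occur often."""
    spec = CorpusSpec(n_reports=15, p_coordinates=1.0, p_second_location=1.0)
    return generate_corpus(spec, seed=321)


@pytest.fixture()
def zero_noise_model():
    return ErrorModel.none(seed=5)
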