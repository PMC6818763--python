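import pytest

from corepress.pipeline import make_fixture_bundle, run_pipeline


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """Small noise-free synthetic bundle with full ground truth."""
    return make_fixture_bundle(7, "small", tmp_path_factory.mktemp("small_bundle"))


@pytest.fixture(scope="session")
def small_result(small_bundle):
    return run_pipeline(small_bundle.config)


@pytest.fixture(scope="session")
def paper_bundle(tmp_path_factory):
    """Published-scale synthetic bundle (set sizes 1613/311/231 etc.)."""
    return make_fixture_bundle(1, "paper", tmp_path_factory.mktemp("paper_bundle"))


@pytest.fixture(scope="session")
def paper_result(paper_bundle):
    return run_pipeline(paper_bundle.config)
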