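import pytest

from splicecat import ThresholdPolicy, build_catalog, merge_samples
from splicecat.fixtures import (fixture_sample_records, load_fixture,
                                published_established_names,
                                published_whitelist)
from splicecat.simulate import make_toy_model


@pytest.fixture(scope="session")
def toy4():
    """4 exons x 20 nt, introns 30 nt, 5 nt UTR at each end."""
    return make_toy_model(4, 20, 30, strand="+", utr5_len=5, utr3_len=5)


@pytest.fixture(scope="session")
def toy4_minus():
    return make_toy_model(4, 20, 30, strand="-", utr5_len=5, utr3_len=5)


@pytest.fixture(scope="session")
def stk11_model():
    return load_fixture("stk11_model")


@pytest.fixture(scope="session")
def nbn_model():
    return load_fixture("nbn_model")


@pytest.fixture(scope="session")
def stk11_table():
    return load_fixture("stk11_table1")


@pytest.fixture(scope="session")
def nbn_table():
    return load_fixture("nbn_table2")


@pytest.fixture(scope="session")
def stk11_catalog(stk11_model):
    """Catalog rebuilt from the published per-sample counts (table means
    replicated into the detected samples), with the published whitelist and
    established names, exactly as the control-panel analysis ran."""
    matrix = merge_samples(fixture_sample_records("stk11_table1"))
    policy = ThresholdPolicy(whitelist=published_whitelist("stk11_table1"))
    return build_catalog(stk11_model, matrix, policy=policy,
                         established_names=published_established_names("stk11_table1"))
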