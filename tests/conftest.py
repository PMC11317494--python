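import pytest

from hydrochem.samples import to_meq
from hydrochem.synthetic import fixture_site_means


@pytest.fixture(scope="session")
def site_means():
    """The seven packaged site-mean samples."""
    return fixture_site_means()


@pytest.fixture(scope="session")
def balances(site_means):
    return [to_meq(s) for s in site_means]


@pytest.fixture(scope="session")
def s1(site_means):
    return site_means[0]


@pytest.fixture(scope="session")
def s1_balance(balances):
    return balances[0]
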