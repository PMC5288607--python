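import numpy as np
import pytest

from exprk.models import one_gene_model, p53_model, two_gene_model


@pytest.fixture(scope="session")
def one_gene():
    return one_gene_model()


@pytest.fixture(scope="session")
def two_gene():
    return two_gene_model()


@pytest.fixture(scope="session")
def p53():
    return p53_model()


@pytest.fixture(scope="session")
def all_models(one_gene, two_gene, p53):
    return {"one-gene": one_gene, "two-gene": two_gene, "p53": p53}


@pytest.fixture()
def rng():
    return np.random.default_rng(20170119)
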