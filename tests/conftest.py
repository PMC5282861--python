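import pytest

from epokb.fixtures import build_mini_epo
from epokb.reasoner import compute_closure, materialize_relations


@pytest.fixture(scope="session")
def mini_kb():
    return build_mini_epo()


@pytest.fixture(scope="session")
def mini_closure(mini_kb):
    return compute_closure(mini_kb)


@pytest.fixture(scope="session")
def mini_relations(mini_kb, mini_closure):
    return materialize_relations(mini_kb, mini_closure)
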