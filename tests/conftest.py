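import pytest

from tinx.corpus import build_publications, read_mentions, read_pubmeta, read_targets
from tinx.ontology import parse_obo, propagate_support
from tinx.scoring import score_all
from tinx.simulate import make_golden_fixture


@pytest.fixture(scope="session")
def golden_paths(tmp_path_factory):
    return make_golden_fixture(tmp_path_factory.mktemp("golden"))


@pytest.fixture(scope="session")
def golden_index(golden_paths):
    rows = read_mentions(golden_paths["mentions"])
    return build_publications(rows, read_pubmeta(golden_paths["pubmeta"]))


@pytest.fixture(scope="session")
def golden_graph(golden_paths):
    return parse_obo(golden_paths["obo"])


@pytest.fixture(scope="session")
def golden_catalog(golden_paths):
    return read_targets(golden_paths["targets"])


@pytest.fixture(scope="session")
def golden_support(golden_index, golden_graph):
    return propagate_support(golden_index, golden_graph)


@pytest.fixture(scope="session")
def golden_support_direct(golden_index):
    return propagate_support(golden_index, None)


@pytest.fixture(scope="session")
def golden_table(golden_index, golden_support, golden_catalog, golden_graph):
    return score_all(golden_index, golden_support, golden_catalog, golden_graph)
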