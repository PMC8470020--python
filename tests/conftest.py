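import pytest

from magpot import ledger, markers, pathways, synthetic


@pytest.fixture(scope="session")
def catalog():
    return markers.load_marker_catalog()


@pytest.fixture(scope="session")
def definitions():
    return pathways.load_pathway_definitions()


@pytest.fixture(scope="session")
def reference_ledger():
    return ledger.load_reference_ledger()


@pytest.fixture(scope="session")
def marker_table():
    return synthetic.load_reference_marker_table()


@pytest.fixture(scope="session")
def community_annotations(marker_table, definitions, catalog):
    return synthetic.build_community_annotations(
        seed=11, marker_table=marker_table, definitions=definitions, catalog=catalog)
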