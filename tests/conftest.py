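import pytest

from topoqspr import data, pipeline, read_graph


@pytest.fixture(scope="session")
def g12():
    """Tranylcypromine skeleton: the worked example of the study."""
    return data.load_graph("tranylcypromine")


@pytest.fixture
def p3():
    return read_graph("a b\nb c")


@pytest.fixture(scope="session")
def degree_partitions():
    return data.load_degree_partitions()


@pytest.fixture(scope="session")
def neighborhood_partitions():
    return data.load_neighborhood_partitions()


@pytest.fixture(scope="session")
def properties():
    return data.load_properties()


@pytest.fixture(scope="session")
def index_tables():
    return pipeline.compute_index_tables()


@pytest.fixture(scope="session")
def grids(index_tables, properties):
    return pipeline.compute_grids(index_tables, properties)


@pytest.fixture(scope="session")
def selected_models(grids, index_tables, properties):
    from topoqspr import select_best_models

    return select_best_models(grids, index_tables, properties)
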