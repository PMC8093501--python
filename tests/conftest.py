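import pytest

from genespectrum import load_fixture


@pytest.fixture(scope="session")
def table1_rows():
    return load_fixture("table1_breast")


@pytest.fixture(scope="session")
def table2_outcomes():
    return load_fixture("table2_spectrum")


@pytest.fixture(scope="session")
def example_studies():
    return load_fixture("adjudication_examples")


@pytest.fixture(scope="session")
def studies_by_id(example_studies):
    return {s.study_id: s for s in example_studies}
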