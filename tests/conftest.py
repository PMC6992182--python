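import pytest

from lipidqual import all_indices, load_study_fixture


@pytest.fixture(scope="session")
def study():
    """The packaged Pearl River Estuary dataset (22 species, 26 acids)."""
    return load_study_fixture()


@pytest.fixture(scope="session")
def study_indices(study):
    """Five-index table for the packaged dataset, default omega convention."""
    return all_indices(study)
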