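import pytest

from ltlrisk.fixtures import lead_dossier, make_fixtures, ttc_only_dossier


@pytest.fixture
def pb_dossier():
    return lead_dossier()


@pytest.fixture
def ttc_dossier():
    return ttc_only_dossier()


@pytest.fixture
def fixture_dir(tmp_path):
    return make_fixtures(tmp_path / "fixtures")
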