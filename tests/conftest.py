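import pytest

from mmclone import AnalysisConfig, build_inpaper_fixture


@pytest.fixture(scope="session")
def cohort():
    """The six-patient cohort fixture (15 tumours + 1 dura)."""
    return build_inpaper_fixture()


@pytest.fixture(scope="session")
def cases_by_id(cohort):
    return {case.patient_id: case for case in cohort}


@pytest.fixture()
def config():
    return AnalysisConfig()
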