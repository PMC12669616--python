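import pytest

from ecostoich.pipeline import analysis_frame
from ecostoich.synthetic_data import generate_dataset, preset_study_design


@pytest.fixture(scope="session")
def preset_design():
    return preset_study_design(seed=1)


@pytest.fixture(scope="session")
def preset_samples(preset_design):
    return generate_dataset(preset_design, seed=1)


@pytest.fixture(scope="session")
def study_frame(preset_samples):
    """Enzyme-fraction rows with stoichiometry and numeric depth attached."""
    return analysis_frame(preset_samples)
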