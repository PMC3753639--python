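import pytest

from wbscan.geometry import build_default_section_matrix, map_to_analysis_plate
from wbscan.quantify import fit_standard_curve, make_default_dilution_series
from wbscan.simulate import (
    default_assay_models,
    default_atlas,
    make_default_section,
    simulate_dilution_series,
)


@pytest.fixture(scope="session")
def matrix():
    return build_default_section_matrix()


@pytest.fixture(scope="session")
def layout(matrix):
    return map_to_analysis_plate(matrix)


@pytest.fixture(scope="session")
def section():
    return make_default_section(seed=0)


@pytest.fixture(scope="session")
def atlas():
    return default_atlas()


@pytest.fixture(scope="session")
def noiseless_models():
    return default_assay_models(noise_sd=0.0)


@pytest.fixture(scope="session")
def ladder():
    return make_default_dilution_series()


@pytest.fixture(scope="session")
def noiseless_curves(noiseless_models, ladder):
    return {
        a: fit_standard_curve(
            simulate_dilution_series(noiseless_models[a], ladder, replicates=3, seed=11)
        )
        for a in noiseless_models
    }
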