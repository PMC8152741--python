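import numpy as np
import pytest

import geoerr as g


@pytest.fixture(scope="session")
def landscape():
    return g.default_config(seed=11)


@pytest.fixture(scope="session")
def tess(landscape):
    return g.make_tessellation(landscape.rows, landscape.cols)


@pytest.fixture(scope="session")
def survey(tess, landscape):
    return g.generate_survey(tess, landscape)


@pytest.fixture(scope="session")
def fits(survey):
    return {m: g.fit_three_param_lognormal(survey.errors(m)) for m in survey.metals}


@pytest.fixture(scope="session")
def tract_matrix(survey, tess):
    return g.tract_average(survey, tess)


@pytest.fixture(scope="session")
def reference(tract_matrix):
    return g.factor_solution(tract_matrix, k=4)


@pytest.fixture(scope="session")
def weights(tess):
    return g.SpatialWeights.from_tessellation(tess, style="binary")


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
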