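import numpy as np
import pytest

from mtdrift import KimuraParams


@pytest.fixture(scope="session")
def embryo_cohort_params():
    """Fitted parameters of the embryo cohort (mean 33.7%, drift parameter 0.72)."""
    return KimuraParams(p=0.337, b=0.72)


@pytest.fixture(scope="session")
def oocyte_params():
    """Fitted parameters of the published oocyte series (mean 12.6%, b 0.87)."""
    return KimuraParams(p=0.126, b=0.87)


@pytest.fixture()
def rng():
    return np.random.default_rng(3243)


@pytest.fixture(scope="session")
def fixture_tsv():
    from importlib.resources import files

    return str(files("mtdrift").joinpath("data/synthetic_embryo_cohort_n35.tsv"))
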