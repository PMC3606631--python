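import numpy as np
import pytest

from kirhap.assays import expected_peaks, get_solver, load_assay_definitions
from kirhap.reference import load_catalog


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def assays():
    return load_assay_definitions()


@pytest.fixture(scope="session")
def solver(assays):
    return get_solver(assays)


def diplotype_counts(catalog, h1, h2, s3_split=None):
    """Concrete diploid copy vector of a catalog pair.

    ``s3_split``: how many 2DS35 block copies are 2DS3 (rest 2DS5);
    default all 2DS3.
    """
    dip = {}
    for name in (h1, h2):
        for k, v in catalog[name].content.as_dict().items():
            dip[k] = dip.get(k, 0) + v
    m = dip.pop("2DS35", 0)
    s3 = m if s3_split is None else s3_split
    if s3:
        dip["2DS3"] = dip.get("2DS3", 0) + s3
    if m - s3:
        dip["2DS5"] = dip.get("2DS5", 0) + (m - s3)
    return dip


def noiseless_peaks(catalog, assays, h1, h2, sample_id="s", s3_split=None):
    dip = diplotype_counts(catalog, h1, h2, s3_split)
    obs = []
    for a in assays:
        obs.extend(expected_peaks(dip, a, sample_id=sample_id))
    return dip, obs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
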