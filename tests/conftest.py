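import numpy as np
import pytest

from capdyn.io_model import RoiTimeSeries, zscore_series
from capdyn.synthetic import make_atlas, make_truth, simulate_cohort


@pytest.fixture(scope="session")
def atlas116():
    return make_atlas()


@pytest.fixture(scope="session")
def small_truth():
    """Small, fast cohort truth: 4 states over 24 ROIs."""
    from capdyn.synthetic import make_atlas

    atlas = make_atlas({"ATN": 4, "DMN": 4, "SMN": 4, "VN": 4, "SCN": 4, "CN": 4})
    return make_truth(k=4, atlas=atlas, snr=2.0, effect_delta=0.15, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_truth):
    manifest, series, latent = simulate_cohort(small_truth, 8, 8, t=120, seed=7)
    return manifest, series, latent


@pytest.fixture()
def cohort_on_disk(tmp_path, small_truth):
    """A small synthetic cohort written in the text dialects."""
    simulate_cohort(small_truth, 3, 3, t=60, seed=3, out_dir=tmp_path)
    return tmp_path


@pytest.fixture()
def standardized_series(small_cohort):
    _, series, _ = small_cohort
    return [zscore_series(ts) for ts in series]


def random_series(rng, t=240, r=116, subject_id="sub"):
    return RoiTimeSeries(subject_id, rng.normal(size=(t, r)))
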