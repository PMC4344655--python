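import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from seascapes.features import build_feature_table, range_standardize
from seascapes.grids import GridGeo, RasterGrid
from seascapes.synthetic import SynthConfig, make_truth, sbs_geo, synth_variable_fields


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_geo():
    """10x12 grid over a 5x6-degree box."""
    return GridGeo(lon_min=100.0, lon_max=106.0, lat_min=-5.0, lat_max=0.0,
                   n_rows=10, n_cols=12)


@pytest.fixture
def random_grid(small_geo, rng):
    vals = rng.normal(size=small_geo.shape)
    mask = rng.random(small_geo.shape) > 0.2
    vals[~mask] = np.nan
    return RasterGrid(geo=small_geo, values=vals, mask=mask, units="degC", name="sst")


@pytest.fixture(scope="session")
def planted():
    """Session-shared 40x40 planted scene with its feature tables."""
    geo = sbs_geo(40, 40)
    cfg = SynthConfig(K=5, seed=7)
    truth = make_truth(geo, cfg)
    fields = synth_variable_fields(truth, cfg)
    table = build_feature_table(fields, truth.sea_mask)
    std, params = range_standardize(table)
    return {"geo": geo, "config": cfg, "truth": truth, "fields": fields,
            "table": table, "std": std, "params": params}


@pytest.fixture
def two_blobs(rng):
    """Two well-separated Gaussian blobs in 2-D, with labels."""
    a = rng.normal([0.2, 0.2], 0.01, size=(60, 2))
    b = rng.normal([0.8, 0.8], 0.01, size=(60, 2))
    X = np.vstack([a, b])
    labels = np.repeat([0, 1], 60)
    return X, labels
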