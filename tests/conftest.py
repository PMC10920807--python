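import warnings

import pytest

from abitower.fixtures import FixtureConfig, generate_scene_stack
from abitower.fusion import assemble_site_timeseries
from abitower.geometry import FixedGridSpec, GOES_EAST


@pytest.fixture(scope="session")
def goes_east():
    return GOES_EAST


@pytest.fixture(scope="session")
def full_grid_2km():
    return FixedGridSpec.full_disk("2km")


@pytest.fixture(scope="session")
def noiseless_case():
    """Two sites, two clear-ish days, zero tower noise: exact ground truth."""
    cfg = FixtureConfig(seed=11, days=2).noiseless()
    return cfg, generate_scene_stack(cfg)


@pytest.fixture(scope="session")
def noiseless_assembled(noiseless_case):
    cfg, result = noiseless_case
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for site in cfg.sites:
            out[site.site_id] = assemble_site_timeseries(site, result.scenes)
    return cfg, result, out
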