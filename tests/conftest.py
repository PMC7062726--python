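import numpy as np
import pytest

from stormfall.imaging import default_endmembers
from stormfall.inventory import AllometryParams, PlotRecord, TreeRecord
from stormfall.synthetic import SceneConfig


@pytest.fixture(scope="session")
def endmembers():
    return default_endmembers(6)


@pytest.fixture(scope="session")
def allometry():
    return AllometryParams.default()


@pytest.fixture
def identity_allometry():
    """ln(AGB) = ln(driver) for every component: AGB equals the driver."""
    return AllometryParams(
        coeffs={(g, c): (0.0, 1.0) for g in ("dicot", "palm") for c in ("stem", "branch", "leaf")},
        palm_height=(0.5, 0.5),
    )


@pytest.fixture
def small_config():
    return SceneConfig(n_rows=40, n_cols=40, seed=7)


@pytest.fixture
def three_stem_plot():
    trees = [
        TreeRecord(dbh_cm=20, status="standing", canopy_class="low", stem_id="a", height_m=15),
        TreeRecord(dbh_cm=30, status="standing", canopy_class="low", stem_id="b", height_m=20),
        TreeRecord(dbh_cm=15, status="standing", canopy_class="low", stem_id="c", height_m=12),
    ]
    return PlotRecord(plot_id="T", area_ha=0.25, trees=trees)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
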