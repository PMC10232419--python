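import numpy as np
import pytest

from bsscatter import (
    BeamStopperSpec,
    CorrectionConfig,
    ScatterModelParams,
    default_chest_phantom,
    default_geometry,
    estimate_scatter,
    simulate_acquisition,
)


@pytest.fixture(scope="session")
def desk_geom():
    """536x440 detector at 0.8 mm: the desk-scale chest geometry."""
    return default_geometry(scale=8)


@pytest.fixture(scope="session")
def desk_bs():
    return BeamStopperSpec(hole_diameter_mm=5.132, hole_pitch_mm=10.264)


@pytest.fixture(scope="session")
def desk_acq(desk_geom, desk_bs):
    """Noiseless paired acquisition of the default chest phantom."""
    phantom = default_chest_phantom(desk_geom)
    return simulate_acquisition(phantom, desk_geom, desk_bs, ScatterModelParams(), seed=0)


@pytest.fixture(scope="session")
def desk_correction(desk_acq, desk_geom, desk_bs):
    """Five-step correction of the desk acquisition (shared: it is the slow step)."""
    return estimate_scatter(
        desk_acq.full_field.data,
        desk_acq.bs_projection.data,
        desk_geom,
        desk_bs,
        CorrectionConfig(downsample_factor=1),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
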