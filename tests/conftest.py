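import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from endoph import (
    STED,
    get_sensor,
    place_endosomes,
    region_stats,
    render_image_pair,
    segment_endosomes,
)
from endoph.synthetic import Endosome, Scene


@pytest.fixture(scope="session")
def srphi1():
    return get_sensor("SRpHi1")


@pytest.fixture(scope="session")
def srphi2():
    return get_sensor("SRpHi2")


@pytest.fixture(scope="session")
def srphi3():
    return get_sensor("SRpHi3")


@pytest.fixture(scope="session")
def small_scene():
    """12 well-separated endosomes on the STED grid."""
    return place_endosomes(12, seed=3, min_separation=1500)


@pytest.fixture(scope="session")
def small_pair(small_scene, srphi1):
    pair, truth = render_image_pair(small_scene, srphi1, STED, seed=4)
    return pair, truth


@pytest.fixture(scope="session")
def small_regions(small_pair):
    pair, _ = small_pair
    regions = segment_endosomes(pair.dye)
    region_stats(regions, pair)
    return regions


def single_endosome_scene(
    diameter_nm: float,
    pH: float,
    optics,
    field: int = 128,
    amplitude: float = 20000.0,
) -> Scene:
    """One endosome placed exactly on a pixel centre in mid-field."""
    px = optics.pixel_size_nm
    c = (field // 2 + 0.5) * px
    e = Endosome(x_nm=c, y_nm=c, diameter_nm=diameter_nm, true_pH=pH,
                 amplitude=amplitude)
    return Scene(endosomes=(e,), field_px=field, pixel_size_nm=px, seed=0)
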