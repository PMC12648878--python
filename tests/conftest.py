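import pytest
from shapely.geometry import Point, box

import postbuffer as pb


@pytest.fixture
def unit_square_composite():
    """1 km x 1 km frame, left half class A, right half class B."""
    frame = box(0, 0, 1000, 1000)
    layer = pb.LandCoverLayer.from_features(
        [(box(0, 0, 500, 1000), "A"), (box(500, 0, 1000, 1000), "B")],
        crs="EPSG:27700",
    )
    comp = pb.LandCoverComposite(layer=layer, frame=frame)
    comp.validate()
    return comp


@pytest.fixture
def uniform_composite():
    """2 km x 2 km frame entirely one class."""
    frame = box(0, 0, 2000, 2000)
    layer = pb.LandCoverLayer.from_features([(frame, "A")], crs="EPSG:27700")
    return pb.LandCoverComposite(layer=layer, frame=frame)


@pytest.fixture
def stripes_scene():
    return pb.scene_stripes(seed=11)


@pytest.fixture
def urban_rural_scene():
    return pb.scene_urban_rural(seed=11)


@pytest.fixture
def simple_units():
    return [
        pb.StatUnit("u1", box(0, 0, 1000, 1000)),
        pb.StatUnit("u2", box(1000, 0, 2000, 1000)),
        pb.StatUnit("u3", box(0, 1000, 2000, 2000)),
    ]


def make_postcode(pid, x, y, weight, unit_id):
    return pb.PostcodeRecord(pid, Point(x, y), weight, unit_id)
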