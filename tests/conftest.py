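import pytest
from shapely.geometry import LineString, Polygon, box

import riparify as rp


@pytest.fixture(scope="session")
def worked():
    """Hand-built 6-segment network with hand-computed expected scores."""
    return rp.make_worked_fixture()


@pytest.fixture()
def chain300():
    """A(flagged, 400 m) - B(300 m) - C(200 m) chain along the x-axis."""
    segs = [
        rp.RiverSegment("A", LineString([(0, 0), (400, 0)]),
                        nps="present", hdas="present", barrier="no",
                        ec="natural"),
        rp.RiverSegment("B", LineString([(400, 0), (700, 0)]),
                        nps="absent", hdas="absent", barrier="no",
                        ec="natural"),
        rp.RiverSegment("C", LineString([(700, 0), (900, 0)]),
                        nps="absent", hdas="absent", barrier="no",
                        ec="natural"),
    ]
    return rp.build_network(segs, snap_tol=0.0)


def square(x, y, side=10.0):
    return box(x, y, x + side, y + side)


@pytest.fixture()
def two_class_map():
    """Two abutting 100x100 m polygons: Farmland west, Forest east."""
    return rp.LandCoverMap(polygons=[
        rp.LandCoverPolygon(box(0, 0, 100, 100), "Farmland"),
        rp.LandCoverPolygon(box(100, 0, 200, 100), "Forest"),
    ], epoch="t0")
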