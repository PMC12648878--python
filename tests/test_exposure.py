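"""Buffer covers and both exposure methods."""

import math

import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import Point, Polygon, box

import postbuffer as pb
from conftest import make_postcode


class TestBufferPoint:
    def test_area_close_to_disc(self):
        buf = pb.buffer_point(Point(0, 0), 300)
        assert abs(buf.area - math.pi * 300**2) / (math.pi * 300**2) < 5e-4

    def test_refinement_monotonic(self):
        target = math.pi * 300**2
        errors = [
            target - pb.buffer_point(Point(0, 0), 300, segments_per_quadrant=s).area
            for s in (8, 16, 32, 64)
        ]
        assert all(e > 0 for e in errors)
        assert errors == sorted(errors, reverse=True)

    def test_distant_points_disjoint(self):
        a = pb.buffer_point(Point(0, 0), 300)
        b = pb.buffer_point(Point(1000, 0), 300)
        assert not a.intersects(b)

    @pytest.mark.parametrize("radius", [0, -5])
    def test_nonpositive_radius_rejected(self, radius):
        with pytest.raises(pb.ParameterError):
            pb.buffer_point(Point(0, 0), radius)


class TestBufferCover:
    def test_uniform_landscape(self, uniform_composite):
        buf = pb.buffer_point(Point(1000, 1000), 300)
        bc = pb.buffer_cover(buf, uniform_composite)
        assert bc.covers["A"] == pytest.approx(1.0, abs=1e-9)
        assert sum(bc.covers.values()) == pytest.approx(1.0, abs=1e-9)

    def test_halfplane_symmetry(self, unit_square_composite):
        buf = pb.buffer_point(Point(500, 500), 300)
        bc = pb.buffer_cover(buf, unit_square_composite)
        assert bc.covers["A"] == pytest.approx(0.5, abs=1e-9)
        assert bc.covers["B"] == pytest.approx(0.5, abs=1e-9)

    def test_circular_segment_closed_form(self, unit_square_composite):
        # centre 150 m left of the A|B boundary at x=500, r=300
        buf = pb.buffer_point(Point(350, 500), 300)
        bc = pb.buffer_cover(buf, unit_square_composite)
        expected = pb.halfplane_cover_fraction(150.0, 300.0)
        assert expected == pytest.approx(0.19550, abs=1e-5)
        assert bc.covers["B"] == pytest.approx(expected, abs=1e-3)

    def test_fully_excluded_buffer_flagged_unusable(self, uniform_composite):
        exclusion = pb.ExclusionLayer(box(0, 0, 2000, 2000), crs="EPSG:27700")
        buf = pb.buffer_point(Point(1000, 1000), 300)
        bc = pb.buffer_cover(buf, uniform_composite, exclusion, "p1")
        assert not bc.usable
        assert bc.denominator_area == 0.0

    def test_exclusion_removed_from_denominator(self, unit_square_composite):
        # exclude the A half: denominator halves, B becomes the whole cover
        exclusion = pb.ExclusionLayer(box(0, 0, 500, 1000), crs="EPSG:27700")
        buf = pb.buffer_point(Point(500, 500), 300)
        bc = pb.buffer_cover(buf, unit_square_composite, exclusion)
        assert bc.denominator_area == pytest.approx(buf.area / 2, rel=1e-9)
        assert bc.covers["B"] == pytest.approx(1.0, abs=1e-9)


class TestProposedExposure:
    def test_single_postcode_identity(self, simple_units):
        covers = {"p1": pb.BufferCover("p1", 1.0, {"A": 0.3, "B": 0.7})}
        recs = [make_postcode("p1", 10, 10, 12, "u1")]
        table = pb.proposed_exposure(recs, covers, simple_units[:1])
        assert table.rows["u1"] == pytest.approx({"A": 30.0, "B": 70.0})
        assert table.total_weight["u1"] == 12

    def test_weighted_mean(self, simple_units):
        covers = {
            "p1": pb.BufferCover("p1", 1.0, {"A": 0.2, "B": 0.8}),
            "p2": pb.BufferCover("p2", 1.0, {"A": 0.8, "B": 0.2}),
        }
        recs = [make_postcode("p1", 1, 1, 1, "u1"), make_postcode("p2", 2, 2, 3, "u1")]
        table = pb.proposed_exposure(recs, covers, simple_units[:1])
        assert table.rows["u1"]["A"] == pytest.approx(65.0)

    def test_weight_scale_invariance(self, simple_units):
        covers = {
            "p1": pb.BufferCover("p1", 1.0, {"A": 0.2, "B": 0.8}),
            "p2": pb.BufferCover("p2", 1.0, {"A": 0.9, "B": 0.1}),
        }
        base = [make_postcode("p1", 1, 1, 2, "u1"), make_postcode("p2", 2, 2, 5, "u1")]
        scaled = [make_postcode(r.postcode_id, r.location.x, r.location.y,
                                r.delivery_count * 10, r.unit_id) for r in base]
        t1 = pb.proposed_exposure(base, covers, simple_units[:1])
        t2 = pb.proposed_exposure(scaled, covers, simple_units[:1])
        assert t1.rows["u1"] == pytest.approx(t2.rows["u1"])

    def test_all_zero_weights_unit_is_missing_not_zero(self, simple_units):
        covers = {"p1": pb.BufferCover("p1", 1.0, {"A": 1.0})}
        recs = [make_postcode("p1", 1, 1, 0, "u1")]
        table = pb.proposed_exposure(recs, covers, simple_units[:1])
        assert table.missing_units == {"u1"}
        assert "u1" not in table.rows

    def test_unknown_unit_rejected(self, simple_units):
        recs = [make_postcode("p1", 1, 1, 5, "nope")]
        with pytest.raises(pb.ParameterError):
            pb.proposed_exposure(recs, {}, simple_units)

    @settings(deadline=None, max_examples=25)
    @given(
        weights=st.lists(st.integers(1, 50), min_size=2, max_size=6),
        fracs=st.lists(st.floats(0.0, 1.0), min_size=2, max_size=6),
        scale=st.integers(2, 9),
        data=st.data(),
    )
    def test_permutation_and_scale_invariance(self, weights, fracs, scale, data):
        n = min(len(weights), len(fracs))
        weights, fracs = weights[:n], fracs[:n]
        unit = pb.StatUnit("u1", box(0, 0, 1000, 1000))
        covers = {
            f"p{i}": pb.BufferCover(f"p{i}", 1.0, {"A": f, "B": 1 - f})
            for i, f in enumerate(fracs)
        }
        recs = [make_postcode(f"p{i}", 1, 1, w, "u1") for i, w in enumerate(weights)]
        perm = data.draw(st.permutations(recs))
        scaled = [make_postcode(r.postcode_id, 1, 1, r.delivery_count * scale, "u1")
                  for r in perm]
        t_base = pb.proposed_exposure(recs, covers, [unit])
        t_perm = pb.proposed_exposure(list(perm), covers, [unit])
        t_scaled = pb.proposed_exposure(scaled, covers, [unit])
        for t in (t_perm, t_scaled):
            assert t.rows["u1"]["A"] == pytest.approx(t_base.rows["u1"]["A"], abs=1e-9)
        assert sum(t_base.rows["u1"].values()) == pytest.approx(100.0, abs=1e-6)


class TestTypicalExposure:
    def test_half_half(self, unit_square_composite):
        units = [pb.StatUnit("u1", box(0, 0, 1000, 1000))]
        table = pb.typical_exposure(units, unit_square_composite)
        assert table.rows["u1"]["A"] == pytest.approx(50.0, abs=1e-6)
        assert table.rows["u1"]["B"] == pytest.approx(50.0, abs=1e-6)

    def test_uniform_unit(self, uniform_composite):
        units = [pb.StatUnit("u1", box(100, 100, 900, 900))]
        table = pb.typical_exposure(units, uniform_composite)
        assert table.rows["u1"]["A"] == pytest.approx(100.0, abs=1e-6)

    def test_quadrant_partition(self):
        frame = box(0, 0, 1000, 1000)
        layer = pb.LandCoverLayer.from_features(
            [
                (box(0, 0, 500, 500), "A"),
                (box(0, 500, 500, 1000), "A"),
                (box(500, 500, 1000, 1000), "B"),
                (box(500, 0, 1000, 500), "C"),
            ],
            crs="EPSG:27700",
        )
        comp = pb.LandCoverComposite(layer=layer, frame=frame)
        table = pb.typical_exposure([pb.StatUnit("u1", frame)], comp)
        assert table.rows["u1"]["A"] == pytest.approx(50.0, abs=1e-6)
        assert table.rows["u1"]["B"] == pytest.approx(25.0, abs=1e-6)
        assert table.rows["u1"]["C"] == pytest.approx(25.0, abs=1e-6)

    def test_fully_excluded_unit_is_missing(self, uniform_composite):
        exclusion = pb.ExclusionLayer(box(0, 0, 500, 500), crs="EPSG:27700")
        units = [pb.StatUnit("u1", box(100, 100, 400, 400))]
        table = pb.typical_exposure(units, uniform_composite, exclusion)
        assert table.missing_units == {"u1"}


class TestAssignRegion:
    regions = [("North", box(0, 500, 1000, 1000)), ("South", box(0, 0, 1000, 500))]

    def test_containment(self):
        unit = pb.StatUnit("u1", box(100, 600, 300, 800))
        assert pb.assign_region(unit, self.regions) == "North"

    def test_c_shape_centroid_rule(self):
        """The centroid rule, not the overlap rule: a C-shaped unit with most
        of its area in East is assigned West because its centroid falls in
        the cavity, which lies West."""
        regions = [("East", box(500, 0, 2000, 1000)), ("West", box(0, 0, 500, 1000))]
        # C opening left: bar at x in [520, 560], arms reaching to x = 300
        c_shape = Polygon([
            (300, 0), (560, 0), (560, 1000), (300, 1000), (300, 900),
            (520, 900), (520, 100), (300, 100),
        ])
        unit = pb.StatUnit("u1", c_shape)
        east_overlap = unit.boundary.intersection(box(500, 0, 2000, 1000)).area
        assert east_overlap > unit.boundary.area / 2  # majority of area East
        assert unit.boundary.centroid.x < 500  # but the centroid is West
        assert pb.assign_region(unit, regions) == "West"

    def test_edge_tie_breaks_lexicographically(self):
        # centroid exactly on the shared edge y = 500
        unit = pb.StatUnit("u1", box(200, 400, 400, 600))
        assert unit.boundary.centroid.y == 500
        assert pb.assign_region(unit, self.regions) == "North"

    def test_unassigned_when_outside_all_regions(self):
        unit = pb.StatUnit("u1", box(5000, 5000, 6000, 6000))
        assert pb.assign_region(unit, self.regions) == "unassigned"


def test_assign_units_by_location_tie_break():
    units = [pb.StatUnit("u2", box(0, 0, 100, 100)),
             pb.StatUnit("u1", box(100, 0, 200, 100))]
    recs = [make_postcode("p1", 100, 50, 5, "unset")]  # exactly on shared edge
    out = pb.assign_units_by_location(recs, units)
    assert out[0].unit_id == "u1"  # first by sorted unit id


def test_boundary_spill(unit_square_composite):
    """A unit containing none of class B still receives B exposure through
    postcode buffers that cross its boundary; the whole-unit method gives 0."""
    unit = pb.StatUnit("uA", box(0, 0, 500, 1000))  # entirely class A
    recs = [make_postcode("p1", 400, 500, 10, "uA")]  # 100 m from the boundary
    covers = pb.compute_buffer_covers(recs, unit_square_composite, radius=300)
    proposed = pb.proposed_exposure(recs, covers, [unit])
    typical = pb.typical_exposure([unit], unit_square_composite)
    assert proposed.rows["uA"]["B"] > 0
    assert typical.rows["uA"]["B"] == pytest.approx(0.0, abs=1e-9)
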