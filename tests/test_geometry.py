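"""Spatial predicates: intersection flags, truth table, oracle agreement."""

import numpy as np
import pytest

from vizonto.errors import DegenerateGeometryError, VocabularyError
from vizonto.geometry import (
    CircleGeom,
    PolygonGeom,
    PolylineGeom,
    SegmentGeom,
    SpatialConfig,
    classify,
    classify_point,
    dump_scene_json,
    geometry_from_dict,
    geometry_to_dict,
    intersection_state,
    load_scene_json,
    spatial_predicate,
)

C = lambda x, y, r: CircleGeom((x, y), r)


def random_geometry(rng):
    if rng.integers(0, 2) == 0:
        return CircleGeom(tuple(rng.uniform(0.0, 1.0, 2)), float(rng.uniform(0.05, 0.4)))
    cx, cy = rng.uniform(0.0, 1.0, 2)
    r = rng.uniform(0.05, 0.4)
    ang = np.sort(rng.uniform(0, 2 * np.pi, 5))
    return PolygonGeom(tuple((cx + r * np.cos(a), cy + r * np.sin(a)) for a in ang))


class TestIntersectionState:
    # expectations frozen from the grid oracle at resolution 0.01, eps 0.02
    @pytest.mark.parametrize(
        "a,b,flags",
        [
            (C(0, 0, 1), C(5, 0, 1), (False, False, False, False)),
            (C(0, 0, 1), C(0, 0, 1), (True, True, False, False)),
            (C(0.5, 0, 1), C(0, 0, 3), (False, True, True, False)),
            (C(0, 0, 1), C(2, 0, 1), (True, False, False, False)),
            (C(0, 0, 1), C(1, 0, 1), (True, True, True, True)),
        ],
        ids=["separated", "identical", "strictly-inside", "tangent", "crossing"],
    )
    @pytest.mark.parametrize("method", ["grid", "analytic"])
    def test_flag_cases(self, a, b, flags, method):
        st = intersection_state(a, b, resolution=0.01, eps=0.02, method=method)
        assert st.as_tuple() == flags

    def test_swap_symmetry(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            a, b = random_geometry(rng), random_geometry(rng)
            st_ab = intersection_state(a, b, 0.02)
            st_ba = intersection_state(b, a, 0.02)
            assert st_ab.swapped() == st_ba

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            intersection_state(C(0, 0, 0.005), C(1, 0, 1), resolution=0.01)

    def test_resolution_stability(self):
        # halving the resolution must not flip flags on well-separated /
        # deeply-overlapping configurations (support regions >> resolution)
        for a, b in [(C(0, 0, 1), C(5, 0, 1)), (C(0, 0, 1), C(1, 0, 1)), (C(0.2, 0, 1), C(0, 0, 3))]:
            coarse = intersection_state(a, b, resolution=0.02, eps=0.04, method="grid")
            fine = intersection_state(a, b, resolution=0.01, eps=0.04, method="grid")
            assert coarse == fine


class TestPredicates:
    def test_disjoint_on_far_circles(self):
        assert spatial_predicate("spatialDisjoint", C(0, 0, 1), C(5, 0, 1))

    def test_meet_on_external_tangency(self):
        assert spatial_predicate("spatialMeet", C(0, 0, 1), C(2, 0, 1))

    def test_inside_small_circle_in_big(self):
        assert spatial_predicate("spatialInside", C(0.5, 0, 1), C(0, 0, 3))

    def test_equal_on_identical_circles(self):
        assert "spatialEqual" in classify(C(0, 0, 1), C(0, 0, 1))

    def test_overlap_on_crossing_circles(self):
        assert "spatialOverlap" in classify(C(0, 0, 1), C(1, 0, 1))

    def test_unknown_predicate_lists_vocabulary(self):
        with pytest.raises(VocabularyError, match="spatialDisjoint"):
            spatial_predicate("spatialNextTo", C(0, 0, 1), C(5, 0, 1))

    def test_surround_composite_frame(self):
        frame = [
            SegmentGeom((0.2, 0.2), (0.8, 0.2)),
            SegmentGeom((0.8, 0.2), (0.8, 0.8)),
            SegmentGeom((0.8, 0.8), (0.2, 0.8)),
            SegmentGeom((0.2, 0.8), (0.2, 0.2)),
        ]
        assert spatial_predicate("spatialSurround", frame, C(0.5, 0.5, 0.15))
        assert not spatial_predicate("spatialSurround", frame, C(0.5, 0.5, 0.45))

    def test_converse_pairs_on_random_scenes(self):
        rng = np.random.default_rng(5)
        cfg = SpatialConfig(resolution=0.02)
        for _ in range(30):
            a, b = random_geometry(rng), random_geometry(rng)
            assert spatial_predicate("spatialInside", a, b, cfg) == spatial_predicate(
                "spatialContains", b, a, cfg
            )
            assert spatial_predicate("spatialCoveredBy", a, b, cfg) == spatial_predicate(
                "spatialCovers", b, a, cfg
            )

    def test_symmetric_predicates_on_random_scenes(self):
        rng = np.random.default_rng(6)
        cfg = SpatialConfig(resolution=0.02)
        for _ in range(30):
            a, b = random_geometry(rng), random_geometry(rng)
            for name in ("spatialDisjoint", "spatialMeet", "spatialEqual", "spatialOverlap"):
                assert spatial_predicate(name, a, b, cfg) == spatial_predicate(name, b, a, cfg)

    def test_classify_returns_fixed_vocabulary_order(self):
        preds = classify(C(0, 0, 1), C(1, 0, 1))
        assert preds == [p for p in ("spatialDisjoint", "spatialOverlap", "spatialMeet",
                                     "spatialEqual", "spatialInside", "spatialCoveredBy",
                                     "spatialCovers", "spatialContains", "spatialSurround")
                         if p in preds]

    def test_strict_mode_matches_textbook_semantics(self):
        cfg = SpatialConfig(strict=True)
        assert spatial_predicate("spatialDisjoint", C(0, 0, 1), C(5, 0, 1), cfg)
        assert spatial_predicate("spatialInside", C(0.5, 0, 1), C(0, 0, 3), cfg)
        assert not spatial_predicate("spatialOverlap", C(0, 0, 1), C(0, 0, 1), cfg)


class TestPointMembership:
    def test_three_way_classification(self):
        g = C(0.5, 0.5, 0.3)
        assert classify_point(g, (0.5, 0.5), eps=0.02) == "interior"
        assert classify_point(g, (0.8, 0.5), eps=0.02) == "boundary"
        assert classify_point(g, (0.95, 0.5), eps=0.02) == "exterior"

    def test_curve_boundary_is_its_endpoints(self):
        seg = SegmentGeom((0.2, 0.5), (0.8, 0.5))
        assert classify_point(seg, (0.2, 0.5), eps=0.02) == "boundary"
        assert classify_point(seg, (0.5, 0.5), eps=0.02) == "interior"
        assert classify_point(seg, (0.5, 0.6), eps=0.02) == "exterior"

    def test_closed_polyline_has_no_boundary(self):
        ring = PolylineGeom(((0.2, 0.2), (0.8, 0.2), (0.5, 0.8), (0.2, 0.2)))
        assert classify_point(ring, (0.2, 0.2), eps=0.02) == "interior"


class TestSceneFiles:
    def test_json_round_trip(self, tmp_path):
        scene = {
            "a": C(0.3, 0.3, 0.1),
            "b": PolygonGeom(((0.5, 0.5), (0.8, 0.5), (0.65, 0.8))),
            "c": SegmentGeom((0.1, 0.1), (0.9, 0.9)),
        }
        path = tmp_path / "scene.json"
        dump_scene_json(scene, path)
        loaded = load_scene_json(path)
        assert loaded == scene

    def test_dict_round_trip_all_forms(self):
        for g in (C(0, 0, 1), PolygonGeom(((0, 0), (1, 0), (0, 1))),
                  PolylineGeom(((0, 0), (1, 1))), SegmentGeom((0, 0), (1, 0))):
            assert geometry_from_dict(geometry_to_dict(g)) == g
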