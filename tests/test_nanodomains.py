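"""Tessellation, object segmentation, planted-cluster nanodomain recovery."""

import numpy as np
import pytest

from sptnano.nanodomains import (
    detect_nanodomains,
    find_nanodomains,
    nanodomain_geometry,
    nanodomains_per_roi,
    segment_objects,
    tessellate,
)
from sptnano.synthetic import planted_cluster_field, uniform_point_field

FIELD = (-2.0, -2.0, 12.0, 12.0)


def planted_fixture(seed, centres=((3, 3), (7, 7)), sizes=(100, 100), bg_density=20.0):
    """Uniform 10x10 um background plus planted 10x-density discs."""
    n_bg = int(100 * bg_density)
    r = np.sqrt(sizes[0] / (np.pi * 10.0 * bg_density))
    return planted_cluster_field(
        n_bg, 10, 10, list(centres), list(sizes), cluster_diameter_um=2 * r, seed=seed
    )


class TestTessellate:
    def test_square_grid_interior_cell_area(self):
        s = 0.5
        xx, yy = np.meshgrid(np.arange(9) * s, np.arange(9) * s)
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        tmap = tessellate(pts, field=(-1, -1, 5, 5))
        interior = ~tmap.unbounded
        # interior grid cells are s-by-s squares
        centre = np.argmin(np.sum((pts - [2.0, 2.0]) ** 2, axis=1))
        assert interior[centre]
        assert tmap.areas[centre] == pytest.approx(s**2, rel=1e-9)

    def test_hull_points_flagged_unbounded_and_excluded(self, rng):
        pts = rng.uniform(0, 5, (100, 2))
        tmap = tessellate(pts)
        from scipy.spatial import ConvexHull

        hull = ConvexHull(pts)
        assert tmap.unbounded[hull.vertices].all()
        assert np.all(tmap.density[tmap.unbounded] == 0.0)

    def test_cluster_points_rank_above_background(self, rng):
        pts, labels = planted_fixture(seed=1)
        tmap = tessellate(pts, field=FIELD)
        cluster = labels >= 0
        bg_density = np.median(tmap.density[~cluster & ~tmap.unbounded])
        frac = np.mean(tmap.density[cluster] > bg_density)
        assert frac >= 0.95

    def test_duplicate_points_jittered_with_warning(self, rng):
        pts = rng.uniform(0, 5, (50, 2))
        pts = np.vstack([pts, pts[:3]])
        with pytest.warns(UserWarning, match="duplicate"):
            tmap = tessellate(pts)
        assert len(tmap.points) == 53

    def test_collinear_input_rejected(self):
        pts = np.column_stack([np.arange(10.0), np.arange(10.0) * 2])
        with pytest.raises(ValueError, match="collinear"):
            tessellate(pts)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            tessellate(np.zeros((3, 2)))


class TestSegmentObjects:
    def test_uniform_region_recovered_as_one_object(self):
        pts = uniform_point_field(2000, 10, 10, seed=2)
        tmap = tessellate(pts, field=(-5, -5, 15, 15))
        objs = segment_objects(tmap)
        assert len(objs) >= 1
        assert objs[0].members.size / len(pts) >= 0.95

    def test_two_separated_regions_give_two_objects(self):
        a = uniform_point_field(500, 3, 3, seed=3)
        b = uniform_point_field(500, 3, 3, seed=4) + [7.0, 7.0]
        tmap = tessellate(np.vstack([a, b]), field=(-3, -3, 13, 13))
        objs = segment_objects(tmap)
        big = [o for o in objs if o.members.size > 100]
        assert len(big) == 2

    def test_empty_after_threshold_gives_empty_list(self):
        pts = uniform_point_field(200, 5, 5, seed=5)
        tmap = tessellate(pts, field=(0, 0, 5, 5))
        assert segment_objects(tmap, object_factor=100.0) == []


class TestDetectNanodomains:
    def test_planted_discs_recovered(self):
        """One domain per planted 100-detection disc; >=90% of planted points
        recovered on average; thresholds re-satisfied post hoc."""
        recalls = []
        for seed in (0, 1, 2):
            pts, labels = planted_fixture(seed, centres=((3, 3), (7, 7), (3, 7), (7, 3)), sizes=(100,) * 4)
            tmap, objs, doms = find_nanodomains(pts, field=FIELD)
            assert len(doms) == 4
            obj = objs[0]
            for d in doms:
                assert d.members.size >= 50
                assert d.mean_density >= 2.0 * obj.mean_density
            for ci in range(4):
                planted = set(np.nonzero(labels == ci)[0])
                best = max(len(planted & set(d.members)) for d in doms)
                recalls.append(best / len(planted))
        assert np.mean(recalls) >= 0.9

    def test_forty_detection_cluster_rejected(self):
        pts, _ = planted_fixture(11, centres=((5, 5),), sizes=(40,))
        _, _, doms = find_nanodomains(pts, field=FIELD)
        assert doms == []

    def test_csr_field_yields_no_domains(self):
        hits = 0
        for seed in range(10):
            pts = uniform_point_field(1000, 10, 10, seed=300 + seed)
            _, _, doms = find_nanodomains(pts, field=FIELD)
            hits += len(doms) > 0
        assert hits == 0

    def test_monotone_in_thresholds(self):
        pts, _ = planted_fixture(1, centres=((3, 3), (7, 7), (5, 5)), sizes=(150, 100, 70))
        tmap = tessellate(pts, field=FIELD)
        objs = segment_objects(tmap)
        obj = objs[0]
        n_base = len(detect_nanodomains(tmap, obj))
        assert len(detect_nanodomains(tmap, obj, min_detections=80)) <= n_base
        assert len(detect_nanodomains(tmap, obj, density_factor=3.5)) <= n_base

    def test_domains_disjoint_and_within_object(self):
        pts, _ = planted_fixture(2, centres=((3, 3), (7, 7)), sizes=(120, 120))
        tmap, objs, doms = find_nanodomains(pts, field=FIELD)
        obj_members = set(objs[0].members)
        seen = set()
        for d in doms:
            m = set(d.members)
            assert not (m & seen)
            assert m <= obj_members
            seen |= m

    def test_detection_invariant_under_rigid_motion(self):
        pts, _ = planted_fixture(3)
        th = 0.5
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = pts @ R.T + [4.0, -1.0]
        from shapely.geometry import Polygon

        corners = np.array([(-2, -2), (12, -2), (12, 12), (-2, 12)], dtype=float)
        field2 = Polygon(corners @ R.T + [4.0, -1.0])
        _, _, d1 = find_nanodomains(pts, field=FIELD)
        _, _, d2 = find_nanodomains(moved, field=field2)
        assert len(d1) == len(d2)
        s1 = sorted(tuple(sorted(d.members)) for d in d1)
        s2 = sorted(tuple(sorted(d.members)) for d in d2)
        assert s1 == s2
        for a, b in zip(sorted(d1, key=lambda d: d.members.min()), sorted(d2, key=lambda d: d.members.min())):
            assert a.diameter_nm == pytest.approx(b.diameter_nm, abs=1e-6)
            assert a.area_um2 == pytest.approx(b.area_um2, abs=1e-6)


class TestGeometryEstimates:
    def test_uniform_disc_diameter_calibration(self, rng):
        u = rng.uniform(0, 1, 2000)
        th = rng.uniform(0, 2 * np.pi, 2000)
        r = 0.1  # 200 nm diameter
        disc = np.column_stack([r * np.sqrt(u) * np.cos(th), r * np.sqrt(u) * np.sin(th)])
        diam, _ = nanodomain_geometry(disc)
        assert diam == pytest.approx(200.0, rel=0.15)

    def test_circle_is_isotropic(self):
        th = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        circle = np.column_stack([np.cos(th), np.sin(th)])
        lam = np.linalg.eigvalsh(np.cov(circle.T))
        assert lam[0] == pytest.approx(lam[1], rel=1e-9)

    def test_rigid_invariance_of_diameter_and_hull_area(self, rng):
        pts = rng.normal(0, 0.05, (200, 2))
        th = 1.2
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = pts @ R.T + [3.0, -2.0]
        d1, a1 = nanodomain_geometry(pts)
        d2, a2 = nanodomain_geometry(moved)
        assert d1 == pytest.approx(d2, abs=1e-9)
        assert a1 == pytest.approx(a2, abs=1e-9)

    def test_collinear_members_flagged_zero_area(self):
        pts = np.column_stack([np.linspace(0, 1, 10), np.zeros(10)])
        _, area = nanodomain_geometry(pts)
        assert area == 0.0


class TestPerRoiCounts:
    def _roi(self, roi_id, x0, y0):
        from shapely.geometry import Polygon
        from sptnano.compartments import CompartmentROI

        return CompartmentROI(
            roi_id=roi_id,
            label="spine",
            polygon=Polygon([(x0, y0), (x0 + 1, y0), (x0 + 1, y0 + 1), (x0, y0 + 1)]),
        )

    def _domain(self, x, y):
        from sptnano.nanodomains import Nanodomain

        return Nanodomain(
            members=np.arange(60),
            centroid=np.array([x, y]),
            diameter_nm=150.0,
            area_um2=0.02,
            mean_density=50.0,
        )

    def test_one_domain_per_spine(self):
        rois = [self._roi(f"s{i}", 2 * i, 0) for i in range(10)]
        doms = [self._domain(2 * i + 0.5, 0.5) for i in range(10)]
        table = nanodomains_per_roi(doms, rois)
        counts = table.set_index("roi_id")["n_nanodomains"]
        assert all(counts[f"s{i}"] == 1 for i in range(10))
        assert counts["unassigned"] == 0

    def test_no_domains_gives_zero_counts(self):
        rois = [self._roi("s0", 0, 0)]
        table = nanodomains_per_roi([], rois)
        assert (table["n_nanodomains"] == 0).all()

    def test_boundary_centroid_tie_breaks_to_lowest_roi_id(self):
        rois = [self._roi("b", 1, 0), self._roi("a", 0, 0)]  # share edge x=1
        dom = self._domain(1.0, 0.5)  # exactly on the shared boundary
        table = nanodomains_per_roi([dom], rois).set_index("roi_id")
        assert table.loc["a", "n_nanodomains"] == 1
        assert table.loc["b", "n_nanodomains"] == 0
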