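"""Perceptron, domain partition, pGSI and pSRI."""

import numpy as np
import pytest

from geostress import (
    ComplexityTrack,
    DomainPartition,
    GeometryConfig,
    build_perceptron,
    compute_pgsi,
    compute_psri,
    generate_separable_scenario,
    make_segmentation,
    partition_domain,
)
from geostress.io import DataError


def _track(values):
    values = np.asarray(values, dtype=float)
    seg = make_segmentation(0, len(values), len(values))
    return ComplexityTrack("SpO2", values, np.full(len(values), 100), seg)


def _manual_partition(pos_polys, neg_polys, bounds=(0.0, 1.0, 0.0, 1.0)):
    """Partition with explicit polygons for exact-geometry checks."""
    from shapely.geometry import Polygon

    pos = [Polygon(p) for p in pos_polys]
    neg = [Polygon(p) for p in neg_polys]
    return DomainPartition(
        bounds=bounds,
        positive_polygons=pos,
        negative_polygons=neg,
        mesh_points=np.empty((0, 2)),
        simplices=np.empty((0, 3), dtype=int),
        triangle_classes=np.empty(0, dtype=int),
        area_positive=sum(p.area for p in pos),
        area_negative=sum(p.area for p in neg),
    )


class TestPerceptron:
    def test_two_segment_hand_case(self):
        p = build_perceptron(_track([0.3, 0.7]))
        np.testing.assert_array_equal(p.labels, [-1, 1])
        assert p.threshold == pytest.approx(0.5)

    def test_three_segment_hand_case(self):
        p = build_perceptron(_track([0.2, 0.4, 0.9]))
        np.testing.assert_array_equal(p.labels, [-1, -1, 1])

    def test_constant_track_all_positive_with_warning(self):
        with pytest.warns(RuntimeWarning, match="constant"):
            p = build_perceptron(_track([0.5, 0.5, 0.5]))
        assert np.all(p.labels == 1)
        assert p.degenerate

    def test_flagged_segments_excluded_and_recorded(self):
        p = build_perceptron(_track([0.3, np.nan, 0.7]))
        np.testing.assert_array_equal(p.labels, [-1, 1])
        np.testing.assert_array_equal(p.excluded, [1])

    def test_labels_strictly_binary(self):
        pts = np.random.default_rng(0).uniform(0.2, 0.8, size=12)
        p = build_perceptron(_track(pts))
        assert set(np.unique(p.labels)) <= {-1, 1}


class TestPartitionDomain:
    def test_two_separated_blobs_one_subdomain_each(self):
        pts, lab = generate_separable_scenario("one-vs-one", 50, 0)
        part = partition_domain(pts, lab)
        assert part.meta["clusters_positive"] == 1
        assert part.meta["clusters_negative"] == 1
        # every point classified into its own class region
        pred = part.classify(pts)
        assert np.all(pred == lab)

    def test_all_positive_labels_cover_domain(self):
        pts, _ = generate_separable_scenario("one-vs-one", 30, 1)
        part = partition_domain(pts, np.ones(len(pts), dtype=int))
        assert part.negative_polygons == []
        assert compute_pgsi(part) == 1.0
        assert part.area_negative == 0.0

    def test_xor_layout_yields_multiple_positive_subdomains(self):
        pts, lab = generate_separable_scenario("xor", 40, 2)
        part = partition_domain(pts, lab)
        assert part.meta["clusters_positive"] >= 2

    def test_coincident_points_degenerate(self):
        pts = np.tile([[0.5, 0.5]], (10, 1))
        with pytest.raises(DataError):
            partition_domain(pts, np.ones(10, dtype=int))

    def test_class_areas_sum_to_domain_area(self):
        pts, lab = generate_separable_scenario("symmetric", 40, 3)
        part = partition_domain(pts, lab)
        total = part.area_positive + part.area_negative
        assert total == pytest.approx(part.meas_omega, rel=1e-9)

    def test_areas_match_monte_carlo_oracle(self, mc_class_areas):
        pts, lab = generate_separable_scenario("one-vs-one", 50, 4)
        part = partition_domain(pts, lab)
        mc_pos, mc_neg = mc_class_areas(part, n=100_000, seed=0)
        assert part.area_positive == pytest.approx(mc_pos, abs=0.01 * part.meas_omega)
        assert part.area_negative == pytest.approx(mc_neg, abs=0.01 * part.meas_omega)

    def test_label_swap_complements_tau(self):
        pts, lab = generate_separable_scenario("one-vs-one", 50, 5)
        t1 = compute_pgsi(partition_domain(pts, lab))
        t2 = compute_pgsi(partition_domain(pts, -lab))
        assert t1 + t2 == pytest.approx(1.0, abs=0.01)

    def test_every_point_inside_omega(self):
        pts, lab = generate_separable_scenario("xor", 30, 6)
        part = partition_domain(pts, lab)
        assert np.all(part.contains(pts))

    def test_logistic_classifier_path(self):
        pts, lab = generate_separable_scenario("one-vs-one", 50, 7)
        part = partition_domain(pts, lab, GeometryConfig(classifier="logistic"))
        tau = compute_pgsi(part)
        assert 0.2 <= tau <= 0.8  # balanced separable blobs

    def test_separation_layer_disconnects_slightly_overlapping_hulls(self):
        rng = np.random.default_rng(8)
        # blob tails close enough that the raw convex hulls overlap a little
        pos = rng.normal([0.40, 0.5], 0.06, (60, 2))
        neg = rng.normal([0.68, 0.5], 0.06, (60, 2))
        pts = np.clip(np.vstack([pos, neg]), 0.01, 0.99)
        lab = np.concatenate([np.ones(60), -np.ones(60)]).astype(int)
        part = partition_domain(pts, lab)
        assert part.meta["separation_iterations"] >= 1
        for p in part.positive_polygons:
            for q in part.negative_polygons:
                if p.geom_type == q.geom_type == "Polygon":
                    assert p.intersection(q).area <= 1e-9
        # the triangulated class areas still cover Ω exactly
        total = part.area_positive + part.area_negative
        assert total == pytest.approx(part.meas_omega, rel=1e-9)


class TestPGSI:
    def test_bounds_always_respected(self):
        for seed in range(5):
            for kind in ("one-vs-one", "xor", "symmetric"):
                pts, lab = generate_separable_scenario(kind, 25, seed)
                tau = compute_pgsi(partition_domain(pts, lab))
                assert 0.0 <= tau <= 1.0

    def test_no_positive_subdomains_gives_zero(self):
        pts, _ = generate_separable_scenario("one-vs-one", 30, 9)
        part = partition_domain(pts, -np.ones(len(pts), dtype=int))
        assert compute_pgsi(part) == 0.0

    def test_symmetric_blobs_near_half(self):
        pts, lab = generate_separable_scenario("symmetric", 40, 10)
        assert compute_pgsi(partition_domain(pts, lab)) == pytest.approx(0.5, abs=0.1)


class TestPSRI:
    def test_single_point_known_distance(self):
        part = _manual_partition(
            pos_polys=[[(0.5, 0), (1, 0), (1, 1), (0.5, 1)]],
            neg_polys=[[(0, 0), (0.4, 0), (0.4, 1), (0, 1)]],
        )
        res = compute_psri(np.array([[0.6, 0.5]]), np.array([1]), part)
        assert res.theta == pytest.approx(0.2, abs=1e-9)
        assert res.m_plus == 1

    def test_two_point_average(self):
        part = _manual_partition(
            pos_polys=[[(0.5, 0), (1, 0), (1, 1), (0.5, 1)]],
            neg_polys=[[(0, 0), (0.4, 0), (0.4, 1), (0, 1)]],
        )
        pts = np.array([[0.5, 0.3], [0.7, 0.8]])  # distances 0.1 and 0.3
        res = compute_psri(pts, np.array([1, 1]), part)
        assert res.theta == pytest.approx(0.2, abs=1e-9)
        assert res.m_plus == 2

    def test_rigid_translation_increases_theta_by_delta(self):
        part = _manual_partition(
            pos_polys=[[(0.5, 0), (5, 0), (5, 1), (0.5, 1)]],
            neg_polys=[[(0, 0), (0.4, 0), (0.4, 1), (0, 1)]],
            bounds=(0.0, 5.0, 0.0, 1.0),
        )
        pts = np.array([[0.6, 0.4], [0.9, 0.7]])
        lab = np.array([1, 1])
        base = compute_psri(pts, lab, part).theta
        delta = 0.35
        shifted = compute_psri(pts + [delta, 0.0], lab, part).theta
        assert shifted - base == pytest.approx(delta, abs=1e-9)

    def test_theta_invariant_under_common_rigid_translation(self):
        sq = [(0.5, 0), (1, 0), (1, 1), (0.5, 1)]
        ng = [(0, 0), (0.4, 0), (0.4, 1), (0, 1)]
        pts = np.array([[0.6, 0.5], [0.8, 0.2]])
        lab = np.array([1, 1])
        t0 = compute_psri(pts, lab, _manual_partition([sq], [ng])).theta
        shift = np.array([2.0, -3.0])
        t1 = compute_psri(
            pts + shift,
            lab,
            _manual_partition(
                [[(x + 2.0, y - 3.0) for x, y in sq]],
                [[(x + 2.0, y - 3.0) for x, y in ng]],
                bounds=(2.0, 3.0, -3.0, -2.0),
            ),
        ).theta
        assert t1 == pytest.approx(t0, abs=1e-9)

    def test_no_positive_points_flagged_undefined(self):
        part = _manual_partition(
            pos_polys=[[(0.5, 0), (1, 0), (1, 1), (0.5, 1)]],
            neg_polys=[[(0, 0), (0.4, 0), (0.4, 1), (0, 1)]],
        )
        res = compute_psri(np.array([[0.2, 0.5]]), np.array([-1]), part)
        assert res.m_plus == 0
        assert np.isnan(res.theta)
        assert res.theta_flag == "undefined"

    def test_no_negative_subdomain_measured_against_domain_boundary(self):
        part = _manual_partition(
            pos_polys=[[(0, 0), (1, 0), (1, 1), (0, 1)]], neg_polys=[]
        )
        res = compute_psri(np.array([[0.5, 0.6]]), np.array([1]), part)
        assert res.theta_flag == "no-negative-boundary"
        assert res.theta == pytest.approx(0.4, abs=1e-9)
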