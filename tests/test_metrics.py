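import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

import oracles as orc
from attspace import metrics as m
from attspace.metrics import (
    compute_all, dispersion, distance_between, entities, evenness,
    extremization, metrics_frame, originality, position, richness,
    scale_space, top_index,
)
from conftest import make_cloud, make_table


class TestScaleSpace:
    def test_minmax_formula(self):
        cloud = scale_space(np.array([[2.0], [4.0], [6.0]]))
        np.testing.assert_allclose(cloud.coordinates[:, 0], [0, 0.5, 1])

    def test_already_unit_span_unchanged(self):
        X = np.array([[0, 0], [1, 0.4], [0.2, 1]], dtype=float)
        np.testing.assert_allclose(scale_space(X).coordinates, X)

    def test_constant_axis_errors(self):
        with pytest.raises(ValueError, match="axis 2"):
            scale_space(np.array([[0, 5], [1, 5]], dtype=float))

    def test_observed_normalizer(self):
        X = np.array([[0, 0], [1, 1], [0.5, 0.5]])
        cloud = scale_space(X, normalize_by="observed")
        assert cloud.normalizer == pytest.approx(math.sqrt(2))

    def test_pooled_distances_bounded(self, rng):
        cloud = scale_space(rng.normal(size=(40, 3)))
        from scipy.spatial.distance import pdist
        assert pdist(cloud.coordinates).max() / cloud.normalizer <= 1.0


class TestPosition:
    def test_singleton(self):
        assert position(make_cloud([[0.3], [0.9]], "ga"), "g", 0) == 0.3

    def test_equal_weights_mean(self):
        cloud = make_cloud([[0.2], [0.4]], "gg")
        assert position(cloud, "g", 0) == pytest.approx(0.3)

    def test_weighted_mean(self):
        cloud = make_cloud([[0.2], [0.4]], "gg", weights=[3, 1])
        assert position(cloud, "g", 0) == pytest.approx(0.25)

    def test_unknown_group(self):
        with pytest.raises(KeyError):
            position(make_cloud([[0.1]]), "nope", 0)


class TestExtremization:
    def test_group_at_pooled_centroid_is_zero(self):
        cloud = make_cloud([[0.5, 0.5], [0.5, 0.5], [0, 0], [1, 1]], "ggab")
        assert extremization(cloud, "g") == 0

    def test_unit_square_corners(self, unit_square_cloud):
        assert extremization(unit_square_cloud, "g") == pytest.approx(0.5)

    def test_symmetric_groups_equal(self):
        cloud = make_cloud([[0.1, 0.1], [0.3, 0.3], [0.9, 0.9], [0.7, 0.7]], "aabb")
        assert extremization(cloud, "a") == pytest.approx(extremization(cloud, "b"))


class TestDispersion:
    def test_identical_members_zero(self):
        cloud = make_cloud([[0.2, 0.8]] * 3 + [[1, 1]], "gggh")
        assert dispersion(cloud, "g") == pytest.approx(0, abs=1e-15)

    def test_unit_square_corners(self, unit_square_cloud):
        assert dispersion(unit_square_cloud, "g") == pytest.approx(0.5)

    def test_duplication_invariant(self, rng):
        pts = rng.random((6, 2))
        one = dispersion(make_cloud(pts), "g")
        two = dispersion(make_cloud(np.vstack([pts, pts])), "g")
        assert one == pytest.approx(two, abs=1e-12)

    def test_singleton_is_zero(self):
        assert dispersion(make_cloud([[0.1, 0.2], [1, 1]], "gh"), "g") == 0


class TestRichness:
    def test_group_equals_pool(self, unit_square_cloud):
        assert richness(unit_square_cloud, "g") == pytest.approx(1.0)

    def test_right_triangle_half_of_square(self):
        cloud = make_cloud([[0, 0], [0, 1], [1, 0], [1, 1]], "gggh")
        assert richness(cloud, "g") == pytest.approx(0.5)

    def test_collinear_group_undefined(self):
        pts = [[0, 0], [0.25, 0.25], [0.5, 0.5], [0.75, 0.75], [1, 1],
               [0, 1], [1, 0]]
        cloud = make_cloud(pts, "gggggab")
        with pytest.warns(UserWarning, match="undefined"):
            assert math.isnan(richness(cloud, "g"))

    def test_degenerate_pooled_hull_errors(self):
        cloud = make_cloud([[0, 0], [0.5, 0.5], [1, 1]], "ggg")
        with pytest.raises(ValueError, match="pooled"):
            richness(cloud, "g")

    def test_monotone_in_added_points(self, rng):
        base = rng.random((8, 2))
        extra = rng.random((1, 2))
        pooled_pad = np.array([[-1, -1], [2, 2], [-1, 2], [2, -1]])
        small = make_cloud(np.vstack([base, pooled_pad]), ["g"] * 8 + ["h"] * 4)
        big = make_cloud(np.vstack([base, extra, pooled_pad]), ["g"] * 9 + ["h"] * 4)
        assert richness(big, "g") >= richness(small, "g") - 1e-12


class TestTopIndex:
    def test_two_points_zero_with_warning(self):
        cloud = make_cloud([[0, 0], [1, 1], [0.5, 0]], "ggh")
        with pytest.warns(UserWarning, match="fewer than 3"):
            assert top_index(cloud, "g") == 0

    def test_single_peel_unit_square(self, unit_square_cloud):
        assert top_index(unit_square_cloud, "g") == pytest.approx(1.0)

    def test_two_peels_nested_squares(self):
        outer = [[0, 0], [0, 1], [1, 0], [1, 1]]
        inner = [[0.25, 0.25], [0.25, 0.75], [0.75, 0.25], [0.75, 0.75]]
        cloud = make_cloud(outer + inner)
        assert top_index(cloud, "g") == pytest.approx(1.25)

    def test_requires_two_dimensions(self):
        with pytest.raises(ValueError, match="2-dimensional"):
            top_index(make_cloud([[0.0], [1.0], [0.5]]), "g")


class TestOriginality:
    def test_coincident_pair_zero(self):
        assert originality(make_cloud([[0.5, 0.5], [0.5, 0.5]]), "g") == 0

    def test_three_collinear_equally_spaced(self):
        s = 0.4
        cloud = make_cloud([[0, 0], [s, 0], [2 * s, 0]])
        assert originality(cloud, "g") == pytest.approx(s / math.sqrt(2))

    def test_duplicating_all_points_collapses(self, rng):
        pts = rng.random((5, 2))
        assert originality(make_cloud(np.vstack([pts, pts])), "g") == 0

    def test_singleton_errors(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            originality(make_cloud([[0, 0], [1, 1]], "gh"), "g")


class TestDistanceBetween:
    def test_identical_groups_zero(self):
        cloud = make_cloud([[0.2, 0.4], [0.6, 0.8]] * 2, "aabb")
        assert distance_between(cloud, "a", "b") == pytest.approx(0.0)

    def test_opposite_corners(self):
        cloud = make_cloud([[0, 0], [1, 1]], "ab")
        assert distance_between(cloud, "a", "b") == pytest.approx(1.0)

    def test_symmetry(self, rng):
        cloud = make_cloud(rng.random((10, 3)), ["a", "b"] * 5)
        assert distance_between(cloud, "a", "b") == distance_between(cloud, "b", "a")


class TestEntities:
    def test_all_identical(self):
        t = make_table(np.tile([1, 2, 1], (5, 1)), ["g"] * 5)
        assert entities(t, "g") == (1, 125)

    def test_all_distinct(self):
        t = make_table(np.arange(1, 5).reshape(4, 1) % 5 + 1, ["g"] * 4)
        assert entities(t, "g")[0] == 4

    def test_binary_enumeration(self):
        vecs = [[1, 1, 1], [1, 1, 1], [1, 2, 1], [2, 2, 2], [2, 2, 2]]
        t = make_table(np.array(vecs, dtype=float), ["g"] * 5, n_levels=2)
        assert entities(t, "g") == (3, 8)

    def test_continuous_items_excluded(self):
        codes = np.array([[1, 55.0], [1, 70.0], [2, 55.0]])
        t = make_table(codes, ["g"] * 3, n_levels=2,
                       item_kinds=["ordinal", "continuous"])
        with pytest.warns(UserWarning, match="excluded"):
            assert entities(t, "g") == (2, 2)


class TestEvenness:
    def test_equally_spaced_collinear_is_one(self):
        cloud = make_cloud([[0.2 * k, 0.1] for k in range(5)] + [[1, 1]],
                           "ggggg" + "h")
        assert evenness(cloud, "g") == pytest.approx(1.0)

    def test_tight_cluster_plus_outlier(self):
        cloud = make_cloud([[0, 0], [0.01, 0], [0.02, 0], [1, 0.2]])
        # MST branches 0.01, 0.01, ~0.9998 -> hand-computed truncated shares
        lengths = np.array([0.01, 0.01, math.dist([0.02, 0], [1, 0.2])])
        share = lengths / lengths.sum()
        eq = 1 / 3
        expected = (np.minimum(share, eq).sum() - eq) / (1 - eq)
        assert evenness(cloud, "g") == pytest.approx(expected, abs=1e-12)
        assert evenness(cloud, "g") < 1

    def test_scale_invariant(self, rng):
        pts = rng.random((8, 2))
        a = evenness(make_cloud(pts), "g")
        b = evenness(make_cloud(pts * 7.3), "g")
        assert a == pytest.approx(b, abs=1e-12)

    def test_needs_three_members(self):
        with pytest.raises(ValueError, match="at least 3"):
            evenness(make_cloud([[0, 0], [1, 1], [0, 1]], "ggh"), "g")

    def test_coincident_points_convention(self):
        cloud = make_cloud([[0.5, 0.5]] * 4 + [[0, 0]], "gggg" + "h")
        with pytest.warns(UserWarning, match="zero-length"):
            assert evenness(cloud, "g") == 1.0


class TestComputeAll:
    def test_single_group_extremization_equals_dispersion(self, rng):
        cloud = make_cloud(rng.random((12, 2)))
        gm = compute_all(cloud)[0]
        assert gm.extremization == pytest.approx(gm.dispersion, abs=1e-12)

    def test_matches_bruteforce_on_two_group_cloud(self):
        pts = np.array([[0, 0], [0.2, 0.1], [0.1, 0.6], [0.4, 0.3],
                        [1, 1], [0.8, 0.9], [0.9, 0.4], [0.6, 0.7]])
        groups = ["a"] * 4 + ["b"] * 4
        cloud = make_cloud(pts, groups)
        t = make_table(np.array([[1, 1], [1, 2], [2, 1], [2, 2]] * 2, float),
                       groups, n_levels=2)
        norm = math.sqrt(2)
        for gm in compute_all(cloud, t):
            sel = pts[np.array(groups) == gm.group]
            assert gm.extremization == pytest.approx(
                orc.bf_extremization(sel, pts, norm), abs=1e-10)
            assert gm.dispersion == pytest.approx(
                orc.bf_dispersion(sel, norm), abs=1e-10)
            assert gm.originality == pytest.approx(
                orc.bf_originality(sel, norm), abs=1e-10)
            assert gm.richness == pytest.approx(
                orc.bf_hull_area_2d(sel) / orc.bf_hull_area_2d(pts), abs=1e-10)
            assert gm.evenness == pytest.approx(orc.bf_evenness(sel), abs=1e-10)
            assert gm.entities == 4 and gm.entities_max == 4

    def test_weights_scaling_invariance(self, rng):
        pts = rng.random((10, 2))
        groups = ["a", "b"] * 5
        plain = metrics_frame(compute_all(make_cloud(pts, groups)))
        doubled = metrics_frame(compute_all(
            make_cloud(pts, groups, weights=np.full(10, 2.0))))
        for col in plain.columns:
            np.testing.assert_allclose(plain[col], doubled[col], atol=1e-12)

    def test_flags_for_undefined_metrics(self):
        cloud = make_cloud([[0, 0], [1, 1], [0.5, 0.2], [0.2, 0.5]], "abbb")
        gm = {g.group: g for g in compute_all(cloud)}
        assert math.isnan(gm["a"].originality)
        assert "originality" in gm["a"].flags


class TestGeometricInvariances:
    def test_axis_permutation_and_reflection(self, rng):
        pts = rng.random((14, 3))
        groups = ["a", "b"] * 7
        ref = metrics_frame(compute_all(make_cloud(pts, groups)))
        flipped = pts[:, [2, 0, 1]].copy()
        flipped[:, 1] = 1 - flipped[:, 1]
        out = metrics_frame(compute_all(make_cloud(flipped, groups)))
        for col in ref.columns:
            if col.startswith("position"):
                continue
            np.testing.assert_allclose(out[col], ref[col], atol=1e-10,
                                       err_msg=col)

    def test_centroid_conservation(self, rng):
        pts = rng.random((20, 2))
        w = rng.uniform(0.5, 2.0, 20)
        groups = np.array(["a"] * 8 + ["b"] * 12)
        cloud = make_cloud(pts, groups, weights=w)
        agg = np.zeros(2)
        for g in ("a", "b"):
            mask = groups == g
            c = np.average(pts[mask], axis=0, weights=w[mask])
            agg += w[mask].sum() * c
        np.testing.assert_allclose(agg / w.sum(), cloud.pooled_centroid(),
                                   atol=1e-12)

    def test_dispersion_below_max_member_distance(self, rng):
        for _ in range(25):
            pts = rng.random((9, 2))
            cloud = make_cloud(pts)
            c = pts.mean(axis=0)
            bound = np.linalg.norm(pts - c, axis=1).max() / math.sqrt(2)
            assert dispersion(cloud, "g") <= bound + 1e-12

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(pts=arrays(np.float64, (8, 2),
                      elements=st.floats(0, 1, allow_nan=False)),
           k=st.integers(2, 6))
    def test_property_bounds_and_symmetry(self, pts, k):
        groups = np.array(["a"] * k + ["b"] * (8 - k))
        cloud = make_cloud(pts, groups)
        for g in ("a", "b"):
            assert 0 <= extremization(cloud, g) <= 1
            assert 0 <= dispersion(cloud, g) <= 1
        assert distance_between(cloud, "a", "b") == \
            distance_between(cloud, "b", "a") <= 1

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(pts=arrays(np.float64, (6, 2),
                      elements=st.floats(0, 1, allow_nan=False)),
           scale=st.floats(0.1, 50))
    def test_property_evenness_scale_free(self, pts, scale):
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            a = evenness(make_cloud(pts), "g")
            b = evenness(make_cloud(pts * scale), "g")
        assert a == pytest.approx(b, abs=1e-9)

    def test_bounded_metrics_on_random_clouds(self, rng):
        for _ in range(200):
            n = rng.integers(4, 15)
            d = rng.integers(1, 4)
            pts = rng.random((n, d))
            k = int(rng.integers(2, n))
            groups = np.array(["a"] * k + ["b"] * (n - k))
            cloud = make_cloud(pts, groups)
            for g in ("a", "b"):
                assert 0 <= extremization(cloud, g) <= 1
                assert 0 <= dispersion(cloud, g) <= 1
                if (groups == g).sum() >= 2:
                    assert 0 <= originality(cloud, g) <= 1
                if (groups == g).sum() >= 3:
                    assert 0 <= evenness(cloud, g) <= 1 + 1e-12
            assert 0 <= distance_between(cloud, "a", "b") <= 1
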